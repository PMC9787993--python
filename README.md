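# prsdelta

Polygenic risk scores versus five-year changes in metabolic traits in a
prediabetic cohort — as a tested, reusable analysis pipeline.

## The problem

Prediabetes (impaired fasting glucose 100–125 mg/dL, HbA1c 5.7–6.4 %, or
impaired glucose tolerance 140–199 mg/dL two hours post-OGTT) marks people
at high risk of progressing to type 2 diabetes (T2D). A natural question
for a two-visit cohort is whether *genetic* risk — summarized as a
polygenic risk score — predicts how metabolic traits drift over the
follow-up interval. `prsdelta` implements that analysis end to end for two
overlapping scores (a T2D score and an obesity score) against a 17-trait
panel (anthropometry and bioimpedance, physical activity, glycemia,
lipids) measured at baseline (T1) and follow-up (T2).

The score for individual *i* is the weighted sum of risk-allele dosages

```
PRS_i = Σ_j β_j · K_ij
```

with `β_j` the published per-allele log odds ratio for the effect allele of
SNP *j* and `K_ij ∈ {0, 1, 2}` the individual's dosage of that allele.
Scores enter the models standardized (zPRS), so coefficients read as trait
units per SD of the score. The statistical battery around Eq. above:

* per-SNP Hardy–Weinberg equilibrium checks (χ², 1 df; exact option);
* trait changes Δ = T2 − T1 and the paired baseline-vs-follow-up
  comparison (Wilcoxon signed-rank, Shapiro–Wilk logged as a diagnostic);
* covariate-adjusted linear association: `trait_T1 ~ zPRS + age + sex`
  at baseline, `Δtrait ~ zPRS + age + sex + BMI_T1` for changes, with
  Wald 95 % CIs, adjusted R², Benjamini–Hochberg FDR per trait family,
  and a sex-stratified re-run;
* per-SNP genotype stratification of every Δ trait (Kruskal–Wallis
  omnibus + pairwise rank-sum post hoc, FDR over the SNP × trait family).

Because cohort genotype/phenotype data of this kind are not public, the
package ships a first-class synthetic-cohort generator
(`prsdelta.simulate`) that emulates the study design — 68-SNP and 21-SNP
weight tables sharing 20 SNPs (69 unique), Hardy–Weinberg genotypes,
prediabetic-range baseline glycemia, and configurable per-SD effects on
trait changes — so every stage is testable against known ground truth.

## Worked example

```python
import pandas as pd
from prsdelta import (SimulationConfig, simulate_cohort, harmonize,
                      impute_missing, score, summarize_prs,
                      compute_deltas, associate_deltas)

cfg = SimulationConfig(n_individuals=446, seed=1, trait_effects={"FM": 0.005})
cohort = simulate_cohort(cfg)

oriented, excluded = harmonize(cohort.weights_t2d, cohort.genotypes)
sc = score(impute_missing(oriented), cohort.weights_t2d, label="T2D")
s = summarize_prs(sc.raw)
print(f"T2D score: {sc.n_snps_used} SNPs, mean={s.mean:.3f}, "
      f"sd={s.sd:.3f}, range=({s.min:.3f}, {s.max:.3f})")

deltas = compute_deltas(cohort.phenotypes)
covars = pd.DataFrame({"age": cohort.phenotypes["age"],
                       "sex": cohort.phenotypes["sex"],
                       "bmi": cohort.phenotypes["BMI_T1"]})
table = associate_deltas(sc.z, deltas, covars, score_label="T2D")
print(table.set_index("trait").loc["FM",
      ["beta", "ci_low", "ci_high", "p", "p_adj", "n"]])
```

prints

```
T2D score: 68 SNPs, mean=3.527, sd=0.496, range=(2.076, 5.012)
beta       0.005735
ci_low     0.001117
ci_high    0.010353
p          0.015053
p_adj      0.240855
n               446
```

The simulated cohort carries an injected per-SD effect of 0.005 kg on
Δ fat mass; the fitted per-SD coefficient (0.0057, 95 % CI 0.0011–0.0104)
recovers it, the raw p is nominally significant, and the BH-adjusted p
shows what surviving a 16-trait family costs a borderline effect in a
single cohort of this size.

The same run from a shell, producing the full report bundle (eligibility
flags, score TSVs and histograms, HWE report, paired-comparison table,
association tables per score and per sex stratum, genotype-stratification
table, log):

```bash
prsdelta run --simulate --n 446 --seed 1 --out run1/
```

Stages also compose from persisted files: `prsdelta simulate`, `score`,
`hwe`, `paired`, `associate`, `stratify` each read/write plain TSV/VCF.

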