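"""Synthetic prediabetic cohort generator.

Emulates the structure of a two-visit prediabetes study: a SNP panel
genotyped as hard calls, two overlapping GWAS weight tables (a type 2
diabetes score and an obesity score sharing part of their SNPs), and a
17-trait phenotype table at baseline and five-year follow-up.

Model
-----
* Genotypes: dosage of the ALT (minor) allele drawn Binomial(2, p_j) per
  SNP — Hardy-Weinberg proportions, no linkage disequilibrium.
* Baseline traits: uniform over configurable ranges; glycemic traits are
  constrained to the prediabetic diagnostic ranges for a configurable
  fraction of the cohort and sampled just below threshold for the rest.
* Follow-up: ``T2 = T1 + shift + gamma * zPRS + covariate terms + noise``
  — injected effects act on the change scale, matching the downstream
  change-association analyses.
* Sex ~ Bernoulli(0.549) (1 = female); age uniform over the configured
  interquartile-style span.

All randomness derives from the single config seed through named
sub-streams, so the same config is byte-reproducible and
:func:`simulate_weight_tables` returns exactly the tables embedded in a
full :func:`simulate_cohort` run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .genotype_io import GenotypeMatrix, make_variants_frame, harmonize
from .traits import TRAITS, SUBTHRESHOLD_RANGES

# Non-ambiguous REF/ALT pairs (never A/T or C/G, which are strand-ambiguous
# and would be dropped at harmonization).
_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))

_STREAMS = ("panel", "genotypes", "phenotypes", "missing")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    genotypes: GenotypeMatrix
    weights_t2d: pd.DataFrame
    weights_obesity: pd.DataFrame
    phenotypes: pd.DataFrame
    #: Ground truth: the SNP panel and the standardized score that drove
    #: the injected effects.
    panel: pd.DataFrame
    true_z: pd.Series


def _build_panel(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the SNP panel: rsIDs, positions, alleles, MAFs, score weights.

    The union panel has ``n_t2d + n_obesity - n_overlap`` SNPs; the first
    ``n_t2d`` belong to the T2D score and the last ``n_obesity`` to the
    obesity score, so the middle block of ``n_overlap`` SNPs is shared.
    """
    n_t2d, n_ob, n_ov = config.n_t2d_snps, config.n_obesity_snps, config.n_overlap_snps
    n_total = n_t2d + n_ob - n_ov

    if config.snp_specs is not None:
        specs = config.snp_specs
        rows = []
        for i, s in enumerate(specs):
            ref, alt = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
            rows.append(
                {
                    "rsid": s.rsid,
                    "chrom": "1",
                    "pos": 10_000 + 5_000 * i,
                    "ref": ref,
                    "alt": alt,
                    "maf": s.maf,
                    "beta_t2d": s.beta_t2d,
                    "beta_obesity": s.beta_obesity,
                    "effect_allele": alt,
                    "other_allele": ref,
                }
            )
        return pd.DataFrame(rows)

    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=n_total)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_total)
    blo, bhi = config.beta_range
    beta_t2d = rng.uniform(blo, bhi, size=n_total)
    beta_ob = rng.uniform(blo, bhi, size=n_total)
    # Effect allele is ALT for most SNPs; flipped to REF for a random
    # subset so harmonization is exercised on realistic input.
    effect_is_alt = rng.random(n_total) < 0.8

    rows = []
    for i in range(n_total):
        ref, alt = _ALLELE_PAIRS[pair_idx[i]]
        in_t2d = i < n_t2d
        in_ob = i >= n_t2d - n_ov
        rows.append(
            {
                "rsid": f"rs{1_000_000 + i}",
                "chrom": "1",
                "pos": 10_000 + 5_000 * i,
                "ref": ref,
                "alt": alt,
                "maf": mafs[i],
                "beta_t2d": beta_t2d[i] if in_t2d else None,
                "beta_obesity": beta_ob[i] if in_ob else None,
                "effect_allele": alt if effect_is_alt[i] else ref,
                "other_allele": ref if effect_is_alt[i] else alt,
            }
        )
    return pd.DataFrame(rows)


def _weight_tables(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    out = []
    for col in ("beta_t2d", "beta_obesity"):
        sub = panel[panel[col].notna()]
        out.append(
            pd.DataFrame(
                {
                    "rsid": sub["rsid"].to_numpy(),
                    "effect_allele": sub["effect_allele"].to_numpy(),
                    "other_allele": sub["other_allele"].to_numpy(),
                    "beta": sub[col].to_numpy(dtype=float),
                }
            )
        )
    return out[0], out[1]


def simulate_weight_tables(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the two overlapping weight tables for the configured panel.

    Deterministic in ``config.seed`` and identical to the tables returned
    by :func:`simulate_cohort` for the same config.
    """
    config.validate()
    panel = _build_panel(config, _rngs(config.seed)["panel"])
    return _weight_tables(panel)


def simulate_genotypes(
    config: SimulationConfig, panel: pd.DataFrame, rng: np.random.Generator
) -> GenotypeMatrix:
    """HWE genotypes: ALT dosage ~ Binomial(2, maf) per SNP."""
    n = config.n_individuals
    dosage = rng.binomial(2, panel["maf"].to_numpy(), size=(n, len(panel))).astype(float)
    individuals = pd.Index([f"ind{i:05d}" for i in range(n)], name="individual_id")
    dosages = pd.DataFrame(dosage, index=individuals, columns=panel["rsid"].to_numpy())
    variants = make_variants_frame(
        panel[["rsid", "chrom", "pos", "ref", "alt"]].to_dict("records")
    )
    return GenotypeMatrix(dosages, variants)


def _true_standardized_score(
    genotypes: GenotypeMatrix, weights: pd.DataFrame
) -> pd.Series:
    """Effect-oriented weighted dosage sum, standardized (ddof=1)."""
    oriented, _ = harmonize(weights, genotypes)
    w = weights.set_index("rsid").loc[oriented.rsids, "beta"].to_numpy()
    raw = oriented.dosages.to_numpy() @ w
    sd = raw.std(ddof=1)
    if sd == 0:  # degenerate draw; only possible for tiny panels
        z = np.zeros_like(raw)
    else:
        z = (raw - raw.mean()) / sd
    return pd.Series(z, index=genotypes.individuals, name="true_z")


def simulate_phenotypes(
    config: SimulationConfig,
    true_z: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Two-visit phenotype table driven by the standardized score."""
    n = config.n_individuals
    sex = (rng.random(n) < config.sex_female_prob).astype(int)  # 1 = female
    age = rng.uniform(*config.age_range, size=n)
    in_range = rng.random(n) < config.prediabetic_fraction

    z = true_z.to_numpy()
    data: dict[str, np.ndarray] = {"sex": sex, "age": age}

    baseline: dict[str, np.ndarray] = {}
    for trait in TRAITS:
        lo, hi = config.baseline_ranges[trait]
        t1 = rng.uniform(lo, hi, size=n)
        if trait in SUBTHRESHOLD_RANGES:
            slo, shi = SUBTHRESHOLD_RANGES[trait]
            t1 = np.where(in_range, t1, rng.uniform(slo, shi, size=n))
        t1 = t1 + config.baseline_effect_for(trait) * z
        baseline[trait] = t1

    for trait in TRAITS:
        t1 = baseline[trait]
        cov = config.covariate_for(trait)
        delta = (
            config.shift_for(trait)
            + config.effect_for(trait) * z
            + cov["age"] * age
            + cov["sex"] * sex
            + cov["bmi"] * baseline["BMI"]
            + rng.normal(0.0, config.noise_for(trait), size=n)
        )
        data[f"{trait}_T1"] = t1
        data[f"{trait}_T2"] = t1 + delta

    return pd.DataFrame(data, index=true_z.index)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a complete synthetic cohort from a validated config."""
    config.validate()
    rngs = _rngs(config.seed)
    panel = _build_panel(config, rngs["panel"])
    wt_t2d, wt_ob = _weight_tables(panel)
    genotypes = simulate_genotypes(config, panel, rngs["genotypes"])

    effect_weights = wt_t2d if config.effect_score == "t2d" else wt_ob
    true_z = _true_standardized_score(genotypes, effect_weights)
    phenotypes = simulate_phenotypes(config, true_z, rngs["phenotypes"])

    if config.missing_rate > 0:
        mask = rngs["missing"].random(genotypes.dosages.shape) < config.missing_rate
        dosages = genotypes.dosages.mask(mask)
        genotypes = GenotypeMatrix(dosages, genotypes.variants)

    return SimulatedCohort(genotypes, wt_t2d, wt_ob, phenotypes, panel, true_z)


def expected_mean_prs(panel: pd.DataFrame, score: str = "t2d") -> float:
    """Population expectation of the raw effect-oriented score.

    For each scoring SNP the expected oriented dosage is ``2 p_eff`` where
    ``p_eff`` is the effect-allele frequency (the MAF if the effect allele
    is ALT, else ``1 - MAF``); the score expectation is the weighted sum.
    """
    col = "beta_t2d" if score == "t2d" else "beta_obesity"
    sub = panel[panel[col].notna()]
    p_eff = np.where(
        sub["effect_allele"] == sub["alt"], sub["maf"], 1.0 - sub["maf"]
    )
    return float(np.sum(2.0 * p_eff * sub[col].to_numpy(dtype=float)))
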