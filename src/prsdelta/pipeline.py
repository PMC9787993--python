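"""End-to-end pipeline: I/O -> harmonize -> score -> HWE -> deltas ->
paired comparison -> association -> genotype stratification.

A run consumes either files on disk (VCF + weight TSVs + phenotype TSV)
or a simulation config, executes the enabled stages in order, and writes
every result table as TSV plus score histograms and a plain-text log to
the output directory.  All numerical outputs are deterministic in the
config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import scipy
import statsmodels
import yaml

from . import __version__
from .association import associate_baseline, associate_deltas, stratify_by_sex
from .cohort import classify_prediabetes, compute_deltas, criteria_overlap, paired_compare_all
from .config import SimulationConfig
from .errors import ConfigError
from .genotype_io import (
    harmonize,
    impute_missing,
    read_phenotypes,
    read_vcf_dosages,
    read_weight_table,
    write_phenotypes,
    write_vcf,
    write_weight_table,
)
from .scoring import hwe_report, score, summarize_prs
from .simulate import simulate_cohort
from .strata import stratify_all

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (paths or simulation + toggles)."""

    output_dir: str = "prsdelta_run"
    vcf: str | None = None
    weights_t2d: str | None = None
    weights_obesity: str | None = None
    phenotypes: str | None = None
    simulation: SimulationConfig | None = None
    run_baseline: bool = True
    run_deltas: bool = True
    run_stratification: bool = True
    run_sex_stratification: bool = True
    fdr_alpha: float = 0.05
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ConfigError("fdr_alpha", "must lie in (0, 1)")
        if self.simulation is None:
            for name in ("vcf", "weights_t2d", "weights_obesity", "phenotypes"):
                value = getattr(self, name)
                if value is None:
                    raise ConfigError(name, "required when simulation is disabled")
                if not Path(value).exists():
                    raise ConfigError(name, f"path does not exist: {value}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = data.pop("simulation", None)
        cfg = cls(**data)
        if sim is not None:
            cfg.simulation = SimulationConfig.from_dict(sim)
        return cfg.validate()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def _score_histogram(raw, label: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(raw, bins=20, color="steelblue", edgecolor="white")
    ax.set_xlabel(f"{label} PRS")
    ax.set_ylabel("individuals")
    ax.set_title(f"{label} score distribution")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; returns the result tables in memory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("prsdelta")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    results: dict = {}
    try:
        logger.info(
            "prsdelta %s (numpy %s, scipy %s, pandas %s, statsmodels %s), seed=%d",
            __version__,
            np.__version__,
            scipy.__version__,
            pd.__version__,
            statsmodels.__version__,
            config.seed,
        )

        # ---- stage: inputs --------------------------------------------
        if config.simulation is not None:
            sim_cfg = config.simulation
            cohort = simulate_cohort(sim_cfg)
            genotypes, phenotypes = cohort.genotypes, cohort.phenotypes
            wt_t2d, wt_ob = cohort.weights_t2d, cohort.weights_obesity
            write_vcf(genotypes, out / "genotypes.vcf")
            write_weight_table(wt_t2d, out / "weights_t2d.tsv")
            write_weight_table(wt_ob, out / "weights_obesity.tsv")
            write_phenotypes(phenotypes, out / "phenotypes.tsv")
            sim_cfg.to_yaml(out / "simulation_config.yaml")
            logger.info("simulated cohort: n=%d, %d SNPs", len(phenotypes), genotypes.n_variants)
        else:
            genotypes = read_vcf_dosages(config.vcf)
            wt_t2d = read_weight_table(config.weights_t2d)
            wt_ob = read_weight_table(config.weights_obesity)
            phenotypes = read_phenotypes(config.phenotypes)

        # ---- stage: eligibility ---------------------------------------
        flags = classify_prediabetes(
            phenotypes["fasting_glucose_T1"],
            phenotypes["HbA1c_T1"],
            phenotypes["glucose_2h_T1"],
        )
        overlap = criteria_overlap(flags)
        results["eligibility"] = flags
        results["criteria_overlap"] = overlap
        _write(flags, out / "eligibility.tsv", index=True)
        logger.info(
            "eligibility: %d/%d eligible; IFG=%d HbA1c=%d both=%d (%.1f%%)",
            int(flags["eligible"].sum()),
            overlap.n,
            overlap.n_ifg,
            overlap.n_hba1c,
            overlap.n_both,
            overlap.pct_both,
        )

        # ---- stage: harmonize + scores + HWE --------------------------
        scores = {}
        hwe_tables = []
        strat_matrices = {}
        for label, wt in (("T2D", wt_t2d), ("obesity", wt_ob)):
            oriented, report = harmonize(wt, genotypes)
            _write(report, out / f"exclusions_{label.lower()}.tsv")
            hwe = hwe_report(oriented)
            hwe_tables.append(hwe.assign(score_label=label))
            strat_matrices[label] = oriented
            imputed = impute_missing(oriented)
            sc = score(imputed, wt, label=label)
            scores[label] = sc
            summary = summarize_prs(sc.raw)
            logger.info(
                "%s score: %d SNPs used, mean=%.4f sd=%s range=(%.4f, %.4f)",
                label,
                sc.n_snps_used,
                summary.mean,
                f"{summary.sd:.4f}" if summary.sd is not None else "NA",
                summary.min,
                summary.max,
            )
            _score_histogram(sc.raw, label, out / f"hist_{label.lower()}.png")
        score_table = pd.concat([s.to_frame() for s in scores.values()])
        _write(score_table, out / "scores.tsv", index=True)
        hwe_all = pd.concat(hwe_tables)
        _write(hwe_all, out / "hwe.tsv", index=True)
        results["scores"] = scores
        results["hwe"] = hwe_all

        # ---- stage: deltas + paired comparison ------------------------
        deltas = compute_deltas(phenotypes)
        table1 = paired_compare_all(phenotypes)
        _write(table1, out / "table1_paired.tsv")
        results["paired"] = table1
        results["deltas"] = deltas

        covars = pd.DataFrame(
            {
                "age": phenotypes["age"],
                "sex": phenotypes["sex"],
                "bmi": phenotypes["BMI_T1"],
            }
        )

        # ---- stage: associations --------------------------------------
        assoc_tables = []
        for label, sc in scores.items():
            if config.run_baseline:
                assoc_tables.append(
                    associate_baseline(sc.z, phenotypes, score_label=label)
                    .assign(analysis="baseline")
                )
            if config.run_deltas:
                assoc_tables.append(
                    associate_deltas(sc.z, deltas, covars, score_label=label)
                    .assign(analysis="delta")
                )
                if config.run_sex_stratification:
                    strat = stratify_by_sex(sc.z, deltas, covars, score_label=label)
                    if len(strat):
                        assoc_tables.append(strat.assign(analysis="delta_by_sex"))
        if assoc_tables:
            assoc = pd.concat(assoc_tables, ignore_index=True)
            results["associations"] = assoc
            for label in scores:
                sub = assoc[(assoc["score_label"] == label) & (assoc["analysis"] == "delta")]
                name = "table2_t2d_delta.tsv" if label == "T2D" else "table3_obesity_delta.tsv"
                _write(sub.drop(columns="analysis"), out / name)
            _write(assoc, out / "associations_all.tsv")

        # ---- stage: genotype stratification ---------------------------
        if config.run_stratification:
            union = stratify_matrix_union(strat_matrices["T2D"], strat_matrices["obesity"])
            strata = stratify_all(
                union, deltas, [wt_t2d, wt_ob], alpha=config.fdr_alpha
            )
            _write(strata.omnibus, out / "strata_omnibus.tsv")
            _write(strata.records, out / "table4_strata.tsv")
            results["strata"] = strata
            logger.info("stratification: %d SNPs analyzed", strata.n_snps)

        logger.info("run complete; outputs in %s", out)
    finally:
        root.removeHandler(handler)
        handler.close()
    return results


def stratify_matrix_union(a, b):
    """Column-union of two harmonized matrices over the same individuals."""
    from .genotype_io import GenotypeMatrix

    new = [r for r in b.rsids if r not in a.variants.index]
    dosages = pd.concat([a.dosages, b.dosages[new]], axis=1)
    variants = pd.concat([a.variants, b.variants.loc[new]])
    return GenotypeMatrix(dosages, variants)
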