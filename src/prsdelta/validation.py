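"""Calibration experiments for the simulation-plus-analysis stack.

These functions run the full pipeline path (simulate -> harmonize ->
score -> deltas -> association) over replicate synthetic cohorts and
measure its frequentist operating characteristics: type-I error of the
change-association stage under a global null, confidence-interval
coverage and sign recovery for an injected per-SD effect, Hardy-Weinberg
consistency of the generator, and convergence of the mean raw score to
its population expectation sum_j 2 p_j beta_j.

Every experiment takes a single master seed; per-replicate seeds are
derived from it deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .association import associate_deltas
from .cohort import compute_deltas
from .config import SimulationConfig
from .genotype_io import harmonize, impute_missing
from .scoring import score
from .simulate import expected_mean_prs, simulate_cohort

_SEED_MOD = 2**31


def _replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n, dtype=np.uint32) % _SEED_MOD


def _run_delta_association(
    config: SimulationConfig, traits=None
) -> pd.DataFrame:
    """Simulate one cohort and run the change-association stage on it."""
    cohort = simulate_cohort(config)
    weights = (
        cohort.weights_t2d if config.effect_score == "t2d" else cohort.weights_obesity
    )
    oriented, _ = harmonize(weights, cohort.genotypes)
    sc = score(impute_missing(oriented), weights, label=config.effect_score)
    deltas = compute_deltas(cohort.phenotypes)
    covars = pd.DataFrame(
        {
            "age": cohort.phenotypes["age"],
            "sex": cohort.phenotypes["sex"],
            "bmi": cohort.phenotypes["BMI_T1"],
        }
    )
    kwargs = {} if traits is None else {"traits": traits}
    return associate_deltas(sc.z, deltas, covars, score_label=config.effect_score, **kwargs)


@dataclass
class NullCalibration:
    n_replicates: int
    n_tests: int
    #: fraction of raw per-trait p-values below alpha
    rejection_rate: float
    #: mean number of FDR-significant traits per replicate family
    mean_fdr_discoveries: float
    family_size: int
    alpha: float


def null_rejection_rate(
    n_replicates: int = 1000,
    n_individuals: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> NullCalibration:
    """Type-I error of the change-association stage under a global null.

    Every replicate draws a fresh cohort with all per-SD effects zero and
    runs the full 16-trait change association; the per-trait raw
    rejection rate should sit at the nominal level and the FDR-significant
    count per family near zero.
    """
    base = config or SimulationConfig()
    base = replace(base, n_individuals=n_individuals, trait_effects={})
    raw_p = []
    discoveries = []
    family = None
    for rep_seed in _replicate_seeds(seed, n_replicates):
        table = _run_delta_association(replace(base, seed=int(rep_seed)))
        raw_p.append(table["p"].to_numpy())
        discoveries.append(int((table["p_adj"] < alpha).sum()))
        family = len(table)
    p = np.concatenate(raw_p)
    return NullCalibration(
        n_replicates=n_replicates,
        n_tests=len(p),
        rejection_rate=float((p < alpha).mean()),
        mean_fdr_discoveries=float(np.mean(discoveries)),
        family_size=family,
        alpha=alpha,
    )


@dataclass
class RecoveryCalibration:
    n_replicates: int
    gamma: float
    trait: str
    #: fraction of replicates whose 95 % CI covers gamma
    coverage: float
    #: fraction of replicates with sign(beta_hat) == sign(gamma)
    sign_agreement: float
    mean_beta: float


def effect_recovery(
    gamma: float = 0.005,
    trait: str = "FM",
    n_replicates: int = 500,
    n_individuals: int = 400,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> RecoveryCalibration:
    """Coverage and sign recovery for an injected per-SD change effect."""
    base = config or SimulationConfig()
    base = replace(base, n_individuals=n_individuals, trait_effects={trait: gamma})
    covered = 0
    sign_ok = 0
    betas = []
    for rep_seed in _replicate_seeds(seed, n_replicates):
        table = _run_delta_association(replace(base, seed=int(rep_seed)), traits=[trait])
        row = table.iloc[0]
        covered += int(row["ci_low"] <= gamma <= row["ci_high"])
        sign_ok += int(np.sign(row["beta"]) == np.sign(gamma))
        betas.append(row["beta"])
    return RecoveryCalibration(
        n_replicates=n_replicates,
        gamma=gamma,
        trait=trait,
        coverage=covered / n_replicates,
        sign_agreement=sign_ok / n_replicates,
        mean_beta=float(np.mean(betas)),
    )


@dataclass
class HweCalibration:
    n_snp_draws: int
    #: fraction of testable SNP draws with HWE p above alpha
    pass_rate: float
    alpha: float


def hwe_pass_rate(
    n_cohorts: int = 30,
    n_individuals: int = 446,
    alpha: float = 0.001,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> HweCalibration:
    """Fraction of simulated SNP draws consistent with their own HWE null."""
    from .scoring import hwe_report

    base = config or SimulationConfig()
    base = replace(base, n_individuals=n_individuals)
    n_draws = 0
    n_pass = 0
    for rep_seed in _replicate_seeds(seed, n_cohorts):
        cohort = simulate_cohort(replace(base, seed=int(rep_seed)))
        report = hwe_report(cohort.genotypes)
        testable = report[~report["untestable"]]
        n_draws += len(testable)
        n_pass += int((testable["p"] > alpha).sum())
    return HweCalibration(n_snp_draws=n_draws, pass_rate=n_pass / n_draws, alpha=alpha)


@dataclass
class PrsMeanCheck:
    n_individuals: int
    observed_mean: float
    expected_mean: float
    #: deviation in Monte-Carlo standard errors
    z: float


def prs_mean_convergence(
    n_individuals: int = 10_000,
    seed: int = 0,
    score_name: str = "t2d",
    config: SimulationConfig | None = None,
) -> PrsMeanCheck:
    """Mean raw score at large n versus its expectation sum_j 2 p_j beta_j."""
    base = config or SimulationConfig()
    base = replace(base, n_individuals=n_individuals, seed=seed)
    cohort = simulate_cohort(base)
    weights = cohort.weights_t2d if score_name == "t2d" else cohort.weights_obesity
    oriented, _ = harmonize(weights, cohort.genotypes)
    sc = score(impute_missing(oriented), weights, label=score_name)
    observed = float(sc.raw.mean())
    expected = expected_mean_prs(cohort.panel, score=score_name)
    se = float(sc.raw.std(ddof=1)) / np.sqrt(n_individuals)
    return PrsMeanCheck(
        n_individuals=n_individuals,
        observed_mean=observed,
        expected_mean=expected,
        z=(observed - expected) / se,
    )
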