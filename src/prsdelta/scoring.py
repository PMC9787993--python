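"""Polygenic score arithmetic, standardization, summaries, and HWE tests.

A polygenic risk score is the weighted sum of effect-allele dosages,

    PRS_i = sum_j beta_j * K_ij,

with ``beta_j`` the published per-allele log odds ratio and ``K_ij`` the
individual's dosage (0, 1, 2 — possibly fractional after mean imputation)
of the effect allele at scoring SNP j.  Association analyses use the
cohort-standardized score (zPRS), so regression coefficients read as trait
units per SD of the score.

Hardy-Weinberg equilibrium is checked per SNP with the 1-df chi-square
goodness-of-fit test on genotype counts (expected p^2 N, 2pq N, q^2 N);
an exact test conditional on the allele count is available for small
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateScoreError, NoScoringSnpsError
from .genotype_io import GenotypeMatrix


@dataclass
class ScoreResult:
    """Per-individual raw and standardized score for one weight table."""

    label: str
    raw: pd.Series
    z: pd.Series | None
    n_snps_used: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"raw_prs": self.raw})
        if self.z is not None:
            df["z_prs"] = self.z
        df["score_label"] = self.label
        return df


def compute_prs(
    genotypes: GenotypeMatrix, weights: pd.DataFrame, label: str = "PRS"
) -> ScoreResult:
    """Weighted dosage sum over the weight table's matched SNPs.

    Requires a harmonized, imputed matrix: every matched SNP must count
    the weight row's effect allele and carry no missing dosage.
    """
    matched = [r for r in weights["rsid"] if r in genotypes.variants.index]
    if not matched:
        raise NoScoringSnpsError(f"{label}: no scoring SNPs matched the genotypes")
    counted = genotypes.variants.loc[matched, "counted_allele"]
    eff = weights.set_index("rsid").loc[matched, "effect_allele"]
    misoriented = [r for r in matched if counted[r] != eff[r]]
    if misoriented:
        raise ValueError(
            f"{label}: dosages not oriented to effect allele for "
            f"{', '.join(misoriented)}; run harmonize() first"
        )
    sub = genotypes.dosages[matched]
    if sub.isna().any().any():
        raise ValueError(f"{label}: missing dosages present; impute or drop first")
    w = weights.set_index("rsid").loc[matched, "beta"].to_numpy(dtype=float)
    raw = pd.Series(sub.to_numpy() @ w, index=genotypes.individuals, name="raw_prs")
    return ScoreResult(label=label, raw=raw, z=None, n_snps_used=len(matched))


def standardize_prs(raw: pd.Series) -> pd.Series:
    """Cohort z-score: (PRS - mean) / sample SD (ddof=1)."""
    if len(raw) < 2:
        raise DegenerateScoreError("need >= 2 individuals to standardize")
    sd = float(raw.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateScoreError("degenerate score distribution (zero variance)")
    z = (raw - raw.mean()) / sd
    z.name = "z_prs"
    return z


def score(
    genotypes: GenotypeMatrix, weights: pd.DataFrame, label: str = "PRS"
) -> ScoreResult:
    """Convenience: compute and standardize in one call."""
    res = compute_prs(genotypes, weights, label)
    res.z = standardize_prs(res.raw)
    return res


@dataclass
class PrsSummary:
    n: int
    mean: float
    sd: float | None  # None (undefined) for a single observation
    min: float
    max: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def summarize_prs(raw: pd.Series, bins: int = 20) -> PrsSummary:
    """Distribution summary of a score vector (mean, SD, range, histogram)."""
    if len(raw) == 0:
        raise DegenerateScoreError("cannot summarize an empty score vector")
    x = raw.to_numpy(dtype=float)
    counts, edges = np.histogram(x, bins=bins)
    return PrsSummary(
        n=len(x),
        mean=float(x.mean()),
        sd=float(np.std(x, ddof=1)) if len(x) > 1 else None,
        min=float(x.min()),
        max=float(x.max()),
        hist_counts=counts,
        hist_edges=edges,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------


@dataclass
class HweResult:
    rsid: str
    n_hom_effect: int
    n_het: int
    n_hom_other: int
    chi2: float
    p: float
    untestable: bool  # monomorphic SNP: HWE not defined
    method: str


def hwe_test(
    n_hom_effect: int,
    n_het: int,
    n_hom_other: int,
    rsid: str = "",
    method: str = "chisq",
) -> HweResult:
    """Test genotype counts against Hardy-Weinberg proportions.

    ``chisq``: 1-df goodness of fit against expected counts
    (p^2 N, 2pq N, q^2 N) with p the observed effect-allele frequency.
    ``exact``: exact conditional test on the heterozygote count given the
    allele count (two-sided by probability ordering); preferred for small N.
    Monomorphic SNPs are flagged untestable (chi2 = 0, p = 1), not errors.
    """
    counts = (n_hom_effect, n_het, n_hom_other)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    p_hat = (2 * n_hom_effect + n_het) / (2 * n)
    if p_hat in (0.0, 1.0):
        return HweResult(rsid, *counts, chi2=0.0, p=1.0, untestable=True, method=method)
    if method == "chisq":
        q_hat = 1.0 - p_hat
        expected = np.array([p_hat**2 * n, 2 * p_hat * q_hat * n, q_hat**2 * n])
        observed = np.array(counts, dtype=float)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(chi2, df=1))
    elif method == "exact":
        chi2 = math.nan
        p = _hwe_exact_p(n_hom_effect, n_het, n_hom_other)
    else:
        raise ValueError(f"unknown HWE method {method!r}")
    return HweResult(rsid, *counts, chi2=chi2, p=p, untestable=False, method=method)


def _hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p: sum of conditional probabilities of heterozygote
    counts no more probable than the observed one, given N and the allele
    count (Levene's conditional distribution)."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab  # copies of allele a
    log_probs = {}
    for het in range(na % 2, min(na, 2 * n - na) + 1, 2):
        aa = (na - het) // 2
        bb = n - aa - het
        lp = (
            math.lgamma(n + 1)
            - math.lgamma(aa + 1)
            - math.lgamma(het + 1)
            - math.lgamma(bb + 1)
            + het * math.log(2)
            + math.lgamma(na + 1)
            + math.lgamma(2 * n - na + 1)
            - math.lgamma(2 * n + 1)
        )
        log_probs[het] = lp
    obs = log_probs[n_ab]
    total = sum(math.exp(lp) for lp in log_probs.values())
    tail = sum(math.exp(lp) for lp in log_probs.values() if lp <= obs + 1e-12)
    return min(1.0, tail / total)


def genotype_counts(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Hard-call genotype counts per variant (counted-allele orientation).

    Only exact dosages 0/1/2 are counted; fractional (imputed) and missing
    entries are ignored, so HWE should be checked before imputation.
    """
    rows = []
    for rsid in genotypes.rsids:
        k = genotypes.dosages[rsid].to_numpy(dtype=float)
        rows.append(
            {
                "rsid": rsid,
                "n_hom_effect": int((k == 2.0).sum()),
                "n_het": int((k == 1.0).sum()),
                "n_hom_other": int((k == 0.0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("rsid")


def hwe_report(genotypes: GenotypeMatrix, method: str = "chisq") -> pd.DataFrame:
    """Per-variant HWE test results as a tidy frame."""
    counts = genotype_counts(genotypes)
    rows = []
    for rsid, row in counts.iterrows():
        res = hwe_test(
            row["n_hom_effect"], row["n_het"], row["n_hom_other"], rsid, method
        )
        rows.append(
            {
                "rsid": rsid,
                "n_hom_effect": res.n_hom_effect,
                "n_het": res.n_het,
                "n_hom_other": res.n_hom_other,
                "chi2": res.chi2,
                "p": res.p,
                "untestable": res.untestable,
            }
        )
    return pd.DataFrame(rows).set_index("rsid")
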