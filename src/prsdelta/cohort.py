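"""Prediabetes eligibility, trait changes, and paired visit comparisons.

Eligibility follows the standard diagnostic ranges: impaired fasting
glucose (IFG) 100-125 mg/dL, HbA1c 5.7-6.4 %, impaired glucose tolerance
(IGT, 2 h post-OGTT glucose) 140-199 mg/dL; an individual is eligible if
any criterion holds.  Bounds are inclusive.

The change (delta) of a trait is follow-up minus baseline (T2 - T1).
Baseline-vs-follow-up comparisons use the Wilcoxon signed-rank test with
Benjamini-Hochberg FDR adjustment across the trait panel; a Shapiro-Wilk
normality p-value is logged per trait as a diagnostic but the
nonparametric path is always taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust
from .traits import TRAITS


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

IFG_RANGE = (100.0, 125.0)  # fasting glucose, mg/dL
HBA1C_RANGE = (5.7, 6.4)  # %
IGT_RANGE = (140.0, 199.0)  # 2 h glucose, mg/dL


def classify_prediabetes(
    fasting_glucose: pd.Series,
    hba1c: pd.Series,
    two_h_glucose: pd.Series,
) -> pd.DataFrame:
    """Flag IFG, HbA1c-range, IGT and overall eligibility per individual.

    Missing measurements yield a False flag for that criterion; an
    individual with all three missing is an error.
    """
    fg, hb, g2 = (
        pd.Series(x, dtype=float) for x in (fasting_glucose, hba1c, two_h_glucose)
    )
    all_missing = fg.isna() & hb.isna() & g2.isna()
    if all_missing.any():
        bad = list(all_missing.index[all_missing])
        raise ValueError(f"all three glycemic criteria missing for: {bad}")

    def in_range(x: pd.Series, lo: float, hi: float) -> pd.Series:
        return x.ge(lo) & x.le(hi)

    flags = pd.DataFrame(
        {
            "ifg": in_range(fg, *IFG_RANGE),
            "hba1c_range": in_range(hb, *HBA1C_RANGE),
            "igt": in_range(g2, *IGT_RANGE),
        }
    ).fillna(False)
    flags["eligible"] = flags.any(axis=1)
    return flags


@dataclass
class CriteriaOverlap:
    n: int
    n_ifg: int
    n_hba1c: int
    n_both: int
    n_ifg_only: int
    n_hba1c_only: int
    #: |IFG and HbA1c| as a percentage of the cohort, one decimal.
    pct_both: float


def criteria_overlap(flags: pd.DataFrame) -> CriteriaOverlap:
    """Count IFG / HbA1c-range overlap and report it as % of the cohort."""
    if len(flags) == 0:
        raise ValueError("empty cohort")
    ifg = flags["ifg"].to_numpy(dtype=bool)
    hb = flags["hba1c_range"].to_numpy(dtype=bool)
    both = int((ifg & hb).sum())
    return CriteriaOverlap(
        n=len(flags),
        n_ifg=int(ifg.sum()),
        n_hba1c=int(hb.sum()),
        n_both=both,
        n_ifg_only=int((ifg & ~hb).sum()),
        n_hba1c_only=int((hb & ~ifg).sum()),
        pct_both=round(100.0 * both / len(flags), 1),
    )


# ---------------------------------------------------------------------------
# Trait changes
# ---------------------------------------------------------------------------


def compute_deltas(phenotypes: pd.DataFrame, traits=TRAITS) -> pd.DataFrame:
    """Per-individual trait change T2 - T1; missing visits propagate NaN."""
    out = {}
    for trait in traits:
        t1, t2 = f"{trait}_T1", f"{trait}_T2"
        if t1 in phenotypes.columns and t2 in phenotypes.columns:
            out[trait] = phenotypes[t2] - phenotypes[t1]
    return pd.DataFrame(out, index=phenotypes.index)


# ---------------------------------------------------------------------------
# Paired comparison
# ---------------------------------------------------------------------------


@dataclass
class PairedResult:
    statistic: float
    p: float
    n_pairs: int
    n_nonzero: int
    degenerate: bool


def paired_wilcoxon(x_t1, x_t2, exact_max_n: int = 25) -> PairedResult:
    """Two-sided Wilcoxon signed-rank test on paired visit values.

    Zero differences are dropped; the exact null distribution is used for
    up to ``exact_max_n`` tie-free nonzero differences, the tie-corrected
    normal approximation otherwise.  All-zero differences are flagged
    degenerate with p = 1.
    """
    a = np.asarray(x_t1, dtype=float)
    b = np.asarray(x_t2, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    d = b[keep] - a[keep]
    nz = d[d != 0]
    if len(nz) == 0:
        return PairedResult(0.0, 1.0, len(d), 0, degenerate=True)
    ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= exact_max_n and not ties) else "approx"
    res = stats.wilcoxon(nz, zero_method="wilcox", alternative="two-sided", method=method)
    return PairedResult(
        float(res.statistic), float(res.pvalue), len(d), len(nz), degenerate=False
    )


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation quantiles."""
    return (
        float(np.percentile(x, 50)),
        float(np.percentile(x, 25)),
        float(np.percentile(x, 75)),
    )


def paired_compare_all(phenotypes: pd.DataFrame, traits=TRAITS) -> pd.DataFrame:
    """Baseline-vs-follow-up comparison across the trait panel.

    Returns one row per trait: median (Q1, Q3) at both visits, the
    Shapiro-Wilk p of the change (diagnostic), the signed-rank p and its
    BH-adjusted value across the panel.  Traits with fewer than two
    complete pairs are excluded with a warning.
    """
    rows = []
    for trait in traits:
        t1c, t2c = f"{trait}_T1", f"{trait}_T2"
        if t1c not in phenotypes.columns or t2c not in phenotypes.columns:
            continue
        sub = phenotypes[[t1c, t2c]].dropna()
        if len(sub) < 2:
            warnings.warn(f"trait {trait}: fewer than 2 paired observations; excluded")
            continue
        t1 = sub[t1c].to_numpy()
        t2 = sub[t2c].to_numpy()
        med1, q1_1, q3_1 = _quartiles(t1)
        med2, q1_2, q3_2 = _quartiles(t2)
        d = t2 - t1
        if len(d) >= 3 and np.ptp(d) > 0:
            shapiro_p = float(stats.shapiro(d).pvalue)
        else:
            shapiro_p = np.nan
        res = paired_wilcoxon(t1, t2)
        rows.append(
            {
                "trait": trait,
                "n": len(sub),
                "median_T1": med1,
                "q1_T1": q1_1,
                "q3_T1": q3_1,
                "median_T2": med2,
                "q1_T2": q1_2,
                "q3_T2": q3_2,
                "shapiro_p": shapiro_p,
                "p": res.p,
                "degenerate": res.degenerate,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table
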