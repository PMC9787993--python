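"""Covariate-adjusted association of standardized scores with traits.

Baseline models:  trait_T1 ~ zPRS + age + sex.
Change models:    delta_trait ~ zPRS + age + sex + baseline BMI.

The score enters standardized, so the coefficient of interest reads as
trait units per SD of the score.  Inference is ordinary least squares
with Wald t intervals; p-values are Benjamini-Hochberg adjusted within
each analysis family (the trait panel of one table).  Sex is coded
1 = female, 0 = male; the per-SD score coefficient is invariant to that
choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import CollinearityError
from .traits import DELTA_TRAITS, TRAITS

SCORE_COL = "z_prs"


# ---------------------------------------------------------------------------
# OLS core
# ---------------------------------------------------------------------------


@dataclass
class OlsFit:
    """Least-squares fit with t-based inference.

    ``params``/``bse``/``pvalues`` are indexed by term (including
    ``const``); ``conf_int`` has columns ``lower``/``upper`` (95 %).
    """

    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    r2: float
    r2_adj: float
    n: int
    df_resid: int


def fit_ols(y, X: pd.DataFrame) -> OlsFit:
    """OLS of ``y`` on the named predictors in ``X`` plus an intercept.

    Raises :class:`CollinearityError` naming the involved columns when the
    design (with intercept) is rank deficient.
    """
    y = np.asarray(y, dtype=float)
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    if len(y) <= Xc.shape[1]:
        raise ValueError(
            f"need n > number of design columns ({len(y)} <= {Xc.shape[1]})"
        )
    arr = Xc.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, s, vt = np.linalg.svd(arr)
        null_vecs = vt[rank:]
        involved = [
            col
            for j, col in enumerate(Xc.columns)
            if np.abs(null_vecs[:, j]).max() > 1e-8 and col != "const"
        ]
        raise CollinearityError(involved or list(Xc.columns))
    res = sm.OLS(y, Xc).fit()
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["lower", "upper"]
    return OlsFit(
        params=res.params,
        bse=res.bse,
        conf_int=ci,
        pvalues=res.pvalues,
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        n=int(res.nobs),
        df_resid=int(res.df_resid),
    )


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    adj_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Association tables
# ---------------------------------------------------------------------------


def _associate(
    z: pd.Series,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    traits,
    score_label: str,
    stratum: str,
) -> pd.DataFrame:
    """One OLS per trait; BH adjustment across the supplied trait family."""
    rows = []
    base = pd.concat([z.rename(SCORE_COL), covariates], axis=1)
    for trait in traits:
        if trait not in outcomes.columns:
            continue
        df = pd.concat([outcomes[trait].rename("_y"), base], axis=1).dropna()
        fit = fit_ols(df["_y"], df.drop(columns="_y"))
        rows.append(
            {
                "trait": trait,
                "beta": float(fit.params[SCORE_COL]),
                "ci_low": float(fit.conf_int.loc[SCORE_COL, "lower"]),
                "ci_high": float(fit.conf_int.loc[SCORE_COL, "upper"]),
                "p": float(fit.pvalues[SCORE_COL]),
                "r2_adj": fit.r2_adj,
                "n": fit.n,
                "stratum": stratum,
                "score_label": score_label,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table = table[
            [
                "trait",
                "beta",
                "ci_low",
                "ci_high",
                "p",
                "p_adj",
                "r2_adj",
                "n",
                "stratum",
                "score_label",
            ]
        ]
    return table


def associate_baseline(
    z: pd.Series,
    phenotypes: pd.DataFrame,
    score_label: str = "PRS",
    traits=TRAITS,
) -> pd.DataFrame:
    """Score vs baseline trait values, adjusted for age and sex."""
    outcomes = pd.DataFrame(
        {t: phenotypes[f"{t}_T1"] for t in traits if f"{t}_T1" in phenotypes.columns}
    )
    covars = phenotypes[["age", "sex"]]
    return _associate(z, outcomes, covars, traits, score_label, stratum="all")


def associate_deltas(
    z: pd.Series,
    deltas: pd.DataFrame,
    covariates: pd.DataFrame,
    score_label: str = "PRS",
    traits=DELTA_TRAITS,
    stratum: str = "all",
) -> pd.DataFrame:
    """Score vs trait changes, adjusted for age, sex and baseline BMI.

    ``covariates`` must carry ``age``, ``sex`` and ``bmi`` (baseline BMI)
    columns; for sex strata the caller drops the constant ``sex`` column.
    """
    return _associate(z, deltas, covariates, traits, score_label, stratum)


def stratify_by_sex(
    z: pd.Series,
    deltas: pd.DataFrame,
    covariates: pd.DataFrame,
    score_label: str = "PRS",
    traits=DELTA_TRAITS,
    min_n: int = 10,
) -> pd.DataFrame:
    """Re-run the change association within each sex stratum.

    Sex is dropped from the covariates (constant within stratum).  Strata
    below ``min_n`` individuals are skipped with a warning.
    """
    tables = []
    for value, label in ((1, "female"), (0, "male")):
        mask = covariates["sex"] == value
        n = int(mask.sum())
        if n < min_n:
            warnings.warn(
                f"sex stratum '{label}' has n={n} < {min_n}; skipped"
            )
            continue
        covs = covariates.loc[mask, [c for c in covariates.columns if c != "sex"]]
        tables.append(
            _associate(z[mask], deltas[mask], covs, traits, score_label, label)
        )
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)
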