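"""Genotype-stratified analysis of trait changes.

For every scoring SNP, individuals are partitioned by effect-allele
dosage (0/1/2 hard calls) and each trait change is compared across the
genotype classes with the Kruskal-Wallis omnibus test (midranks, tie
correction, chi-square reference with k-1 df).  Pairwise Wilcoxon
rank-sum tests locate the genotype classes driving a significant
omnibus result.  P-values are BH-adjusted over the SNP x trait family,
and records are reported when adjusted p falls below the significance
level or raw p below a "tendency" band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust
from .genotype_io import GenotypeMatrix
from .traits import DELTA_TRAITS

logger = logging.getLogger(__name__)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with k-1 df.

    H = 12 / (N (N+1)) * sum n_i Rbar_i^2 - 3 (N+1), divided by the tie
    correction factor.  Identical pooled values make H undefined; that
    case returns (nan, 1.0).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("groups must be nonempty")
    if sum(len(a) for a in arrays) < 3:
        raise ValueError("need total n >= 3")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return float("nan"), 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def rank_sum_test(x, y, exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both groups have at most ``exact_max_n``
    observations and the pooled values are tie-free; tie-corrected normal
    approximation (no continuity correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    use_exact = (len(x) <= exact_max_n and len(y) <= exact_max_n) and not ties
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=False,
    )
    return float(res.pvalue)


def posthoc_pairwise(
    groups: dict[str, np.ndarray], adjust: bool = False
) -> pd.DataFrame:
    """All pairwise rank-sum comparisons between labeled groups.

    Empty groups are skipped with a warning.  ``adjust=True`` adds a BH
    column across the comparisons; by default the raw p-values stand.
    """
    labels = list(groups)
    rows = []
    for a, b in combinations(labels, 2):
        ga, gb = np.asarray(groups[a]), np.asarray(groups[b])
        if len(ga) == 0 or len(gb) == 0:
            warnings.warn(f"posthoc comparison {a} vs {b} skipped: empty group")
            continue
        rows.append({"group1": a, "group2": b, "p": rank_sum_test(ga, gb)})
    table = pd.DataFrame(rows, columns=["group1", "group2", "p"])
    if adjust and len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table


@dataclass
class StrataResults:
    """Omnibus results for every SNP x trait pair plus reportable records."""

    #: all pairs: rsid, trait, H, p, p_adj, genotype ns
    omnibus: pd.DataFrame
    #: Table-style rows for reportable pairs: per-genotype n/median/IQR
    #: and pairwise post-hoc p-values
    records: pd.DataFrame
    n_snps: int


def _genotype_label(counted: str, other: str, dosage: int) -> str:
    return {0: other + other, 1: counted + other, 2: counted + counted}[dosage]


def stratify_all(
    genotypes: GenotypeMatrix,
    deltas: pd.DataFrame,
    weight_tables: list[pd.DataFrame],
    traits=DELTA_TRAITS,
    alpha: float = 0.05,
    tendency_p: float = 0.1,
    adjust_posthoc: bool = False,
) -> StrataResults:
    """Genotype-stratified change comparison over the union of scoring SNPs.

    ``genotypes`` must be harmonized (dosage = effect-allele copies, hard
    calls; missing calls excluded per SNP).  The omnibus family for BH
    adjustment is every SNP x trait pair; records are emitted for pairs
    with adjusted p < ``alpha`` or raw p < ``tendency_p``.
    """
    rsids = []
    for wt in weight_tables:
        rsids.extend(r for r in wt["rsid"] if r in genotypes.variants.index)
    rsids = list(dict.fromkeys(rsids))  # unique, stable order

    omnibus_rows = []
    warned: set[str] = set()
    group_cache: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for rsid in rsids:
        k = genotypes.dosages[rsid]
        counted = genotypes.variants.loc[rsid, "counted_allele"]
        other = genotypes.variants.loc[rsid, "other_allele"]
        for trait in traits:
            if trait not in deltas.columns:
                continue
            df = pd.DataFrame({"k": k, "d": deltas[trait]}).dropna()
            groups: dict[str, np.ndarray] = {}
            ns = {0: 0, 1: 0, 2: 0}
            for dosage in (0, 1, 2):
                vals = df.loc[df["k"] == dosage, "d"].to_numpy()
                ns[dosage] = len(vals)
                if len(vals):
                    groups[_genotype_label(counted, other, dosage)] = vals
            if len(groups) < 3 and rsid not in warned:
                warned.add(rsid)
                logger.warning(
                    "%s: empty genotype class; analyzed on %d classes",
                    rsid,
                    len(groups),
                )
            if len(groups) < 2 or sum(ns.values()) < 3:
                continue
            H, p = kruskal_wallis(list(groups.values()))
            group_cache[(rsid, trait)] = groups
            omnibus_rows.append(
                {
                    "rsid": rsid,
                    "trait": trait,
                    "H": H,
                    "p": p,
                    "n_hom_other": ns[0],
                    "n_het": ns[1],
                    "n_hom_effect": ns[2],
                }
            )

    omnibus = pd.DataFrame(omnibus_rows)
    if len(omnibus):
        omnibus["p_adj"] = bh_adjust(omnibus["p"].to_numpy())

    record_rows = []
    if len(omnibus):
        keep = omnibus[(omnibus["p_adj"] < alpha) | (omnibus["p"] < tendency_p)]
        for row in keep.itertuples(index=False):
            groups = group_cache[(row.rsid, row.trait)]
            posthoc = posthoc_pairwise(groups, adjust=adjust_posthoc)
            posthoc_str = "; ".join(
                f"{r.group1}|{r.group2}={r.p:.4g}" for r in posthoc.itertuples()
            )
            for label, vals in groups.items():
                record_rows.append(
                    {
                        "rsid": row.rsid,
                        "trait": row.trait,
                        "genotype": label,
                        "n": len(vals),
                        "median": float(np.percentile(vals, 50)),
                        "q1": float(np.percentile(vals, 25)),
                        "q3": float(np.percentile(vals, 75)),
                        "p": row.p,
                        "p_adj": row.p_adj,
                        "posthoc": posthoc_str,
                    }
                )
    records = pd.DataFrame(
        record_rows,
        columns=[
            "rsid",
            "trait",
            "genotype",
            "n",
            "median",
            "q1",
            "q3",
            "p",
            "p_adj",
            "posthoc",
        ],
    )
    return StrataResults(omnibus=omnibus, records=records, n_snps=len(rsids))
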