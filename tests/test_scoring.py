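"""Score arithmetic, standardization, summaries, Hardy-Weinberg tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from prsdelta.errors import DegenerateScoreError, NoScoringSnpsError
from prsdelta.genotype_io import GenotypeMatrix, harmonize, make_variants_frame
from prsdelta.scoring import (
    compute_prs,
    genotype_counts,
    hwe_report,
    hwe_test,
    score,
    standardize_prs,
    summarize_prs,
)


def matrix(dosage_rows: list[list[float]], rsids: list[str]) -> GenotypeMatrix:
    n = len(dosage_rows)
    df = pd.DataFrame(
        np.asarray(dosage_rows, dtype=float),
        index=pd.Index([f"s{i}" for i in range(n)], name="individual_id"),
        columns=rsids,
    )
    variants = make_variants_frame(
        [
            {"rsid": r, "chrom": "1", "pos": j + 1, "ref": "A", "alt": "G"}
            for j, r in enumerate(rsids)
        ]
    )
    return GenotypeMatrix(df, variants)


def weight_table(rsids, betas, effect="G", other="A") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rsid": rsids,
            "effect_allele": effect,
            "other_allele": other,
            "beta": betas,
        }
    )


class TestComputePrs:
    def test_forced_arithmetic(self):
        gm = matrix([[2, 1, 0]], ["r1", "r2", "r3"])
        w = weight_table(["r1", "r2", "r3"], [0.1, 0.2, 0.3])
        res = compute_prs(gm, w)
        assert res.raw.iloc[0] == pytest.approx(0.4)
        assert res.n_snps_used == 3

    def test_zero_dosages_zero_score(self):
        gm = matrix([[0, 0], [0, 0]], ["r1", "r2"])
        w = weight_table(["r1", "r2"], [0.5, 0.7])
        assert (compute_prs(gm, w).raw == 0).all()

    def test_linearity_in_weights(self, rng):
        k = rng.integers(0, 3, size=(20, 5)).astype(float)
        gm = matrix(k.tolist(), [f"r{j}" for j in range(5)])
        betas = rng.uniform(0.01, 0.2, 5)
        w1 = weight_table(list(gm.rsids), betas)
        w2 = weight_table(list(gm.rsids), 2 * betas)
        assert np.allclose(2 * compute_prs(gm, w1).raw, compute_prs(gm, w2).raw)

    def test_additivity_of_concatenated_tables(self, rng):
        k = rng.integers(0, 3, size=(15, 6)).astype(float)
        gm = matrix(k.tolist(), [f"r{j}" for j in range(6)])
        wa = weight_table(["r0", "r1", "r2"], [0.1, 0.2, 0.3])
        wb = weight_table(["r3", "r4", "r5"], [0.05, 0.15, 0.25])
        combined = pd.concat([wa, wb], ignore_index=True)
        total = compute_prs(gm, combined).raw
        assert np.allclose(total, compute_prs(gm, wa).raw + compute_prs(gm, wb).raw)

    def test_no_matching_snps_raises(self):
        gm = matrix([[0, 1]], ["r1", "r2"])
        with pytest.raises(NoScoringSnpsError):
            compute_prs(gm, weight_table(["rX"], [0.1]))

    def test_misoriented_matrix_rejected(self):
        gm = matrix([[0, 1]], ["r1", "r2"])  # counts ALT = G
        w = weight_table(["r1"], [0.1], effect="A", other="G")
        with pytest.raises(ValueError, match="harmonize"):
            compute_prs(gm, w)

    def test_missing_dosage_rejected(self):
        gm = matrix([[np.nan], [1.0]], ["r1"])
        with pytest.raises(ValueError, match="missing"):
            compute_prs(gm, weight_table(["r1"], [0.1]))

    def test_population_mean_matches_expectation(self, small_cohort):
        # mean raw PRS ~ sum_j 2 p_eff_j beta_j within 3 Monte-Carlo SEs
        from prsdelta.simulate import expected_mean_prs

        wt = small_cohort.weights_t2d
        oriented, _ = harmonize(wt, small_cohort.genotypes)
        res = compute_prs(oriented, wt)
        expected = expected_mean_prs(small_cohort.panel, "t2d")
        se = res.raw.std(ddof=1) / np.sqrt(len(res.raw))
        assert abs(res.raw.mean() - expected) < 3 * se


class TestStandardize:
    def test_three_point_example(self):
        z = standardize_prs(pd.Series([1.0, 2.0, 3.0]))
        assert np.allclose(z, [-1.0, 0.0, 1.0])

    @given(
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
    )
    def test_affine_invariance(self, a, b):
        raw = pd.Series([0.2, 0.9, 1.4, 0.1, 0.7])
        z1 = standardize_prs(raw)
        z2 = standardize_prs(a * raw + b)
        assert np.allclose(z1, z2, atol=1e-9)

    def test_mean_zero_sd_one(self, rng):
        z = standardize_prs(pd.Series(rng.normal(3, 2, 100)))
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1) < 1e-10

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateScoreError, match="degenerate"):
            standardize_prs(pd.Series([1.0, 1.0, 1.0]))

    def test_too_few_raises(self):
        with pytest.raises(DegenerateScoreError):
            standardize_prs(pd.Series([1.0]))


class TestSummarize:
    def test_single_score_sd_undefined(self):
        s = summarize_prs(pd.Series([1.5]))
        assert s.mean == 1.5 and s.sd is None

    def test_two_point_range(self):
        s = summarize_prs(pd.Series([0.0, 2.0]))
        assert (s.mean, s.min, s.max) == (1.0, 0.0, 2.0)

    def test_summary_of_standardized_scores(self, rng):
        z = standardize_prs(pd.Series(rng.normal(size=200)))
        s = summarize_prs(z)
        assert abs(s.mean) < 1e-10 and abs(s.sd - 1) < 1e-10

    def test_empty_raises(self):
        with pytest.raises(DegenerateScoreError):
            summarize_prs(pd.Series([], dtype=float))


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------


def chi2_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Expected-count goodness-of-fit statistic, written out longhand."""
    n = n_aa + n_ab + n_bb
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    exp = [p * p * n, 2 * p * q * n, q * q * n]
    obs = [n_aa, n_ab, n_bb]
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp))


class TestHweChiSquare:
    def test_perfect_proportions_give_zero(self):
        res = hwe_test(25, 50, 25)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_cohort_scale_counts(self):
        # counts (143, 229, 83): chi-square ~ 0.27, p ~ 0.60
        res = hwe_test(143, 229, 83)
        assert res.chi2 == pytest.approx(chi2_oracle(143, 229, 83), rel=1e-12)
        assert res.chi2 == pytest.approx(0.27, abs=0.01)
        assert res.p == pytest.approx(0.60, abs=0.01)

    def test_no_heterozygotes_statistic_equals_n(self):
        res = hwe_test(50, 0, 50)
        assert res.chi2 == pytest.approx(100.0)
        assert res.p < 1e-10

    def test_monomorphic_flagged_untestable(self):
        res = hwe_test(0, 0, 30)
        assert res.untestable and res.p == 1.0

    @pytest.mark.parametrize("counts", [(10, 21, 12), (3, 9, 8), (140, 60, 10)])
    def test_matches_oracle(self, counts):
        res = hwe_test(*counts)
        assert res.chi2 == pytest.approx(chi2_oracle(*counts), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 2, 3)


def exact_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Brute-force exact HWE p: enumerate every assignment of the pooled
    allele copies to ordered genotype slots (equally likely under the
    null), tabulate the heterozygote-count distribution, and sum the
    probabilities of outcomes no more probable than the observed one."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    slots = 2 * n
    counts: dict[int, int] = {}
    for positions in itertools.combinations(range(slots), na):
        alleles = ["b"] * slots
        for pos in positions:
            alleles[pos] = "a"
        het = sum(
            1 for i in range(n) if alleles[2 * i] != alleles[2 * i + 1]
        )
        counts[het] = counts.get(het, 0) + 1
    total = sum(counts.values())
    p_obs = counts[n_ab] / total
    return sum(c / total for c in counts.values() if c / total <= p_obs * (1 + 1e-12))


class TestHweExact:
    @pytest.mark.parametrize(
        "counts",
        [(1, 2, 3), (0, 4, 2), (2, 2, 2), (3, 1, 4), (0, 1, 5), (4, 0, 4)],
    )
    def test_matches_enumeration_oracle(self, counts):
        res = hwe_test(*counts, method="exact")
        assert res.p == pytest.approx(exact_oracle(*counts), rel=1e-9)

    def test_exact_and_chisq_agree_at_scale(self):
        a = hwe_test(143, 229, 83, method="exact")
        b = hwe_test(143, 229, 83, method="chisq")
        assert a.p == pytest.approx(b.p, abs=0.1)


class TestHweReport:
    def test_counts_and_report_shape(self, small_cohort):
        gm = small_cohort.genotypes
        counts = genotype_counts(gm)
        assert (counts.sum(axis=1) == gm.n_individuals).all()
        report = hwe_report(gm)
        assert len(report) == gm.n_variants
        assert report["p"].between(0, 1).all()


def test_score_convenience_standardizes(small_cohort):
    wt = small_cohort.weights_t2d
    oriented, _ = harmonize(wt, small_cohort.genotypes)
    res = score(oriented, wt, label="T2D")
    assert abs(res.z.mean()) < 1e-10
    assert abs(res.z.std(ddof=1) - 1) < 1e-10
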