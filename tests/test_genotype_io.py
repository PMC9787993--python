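"""VCF round trips, effect-allele harmonization, mean imputation."""

import numpy as np
import pandas as pd
import pytest

from prsdelta.errors import MissingVariantError, VcfParseError
from prsdelta.genotype_io import (
    GenotypeMatrix,
    harmonize,
    impute_missing,
    make_variants_frame,
    read_vcf_dosages,
    read_weight_table,
    write_vcf,
    write_weight_table,
)


def matrix_from(dosages: dict, variants: list[dict], individuals=None) -> GenotypeMatrix:
    individuals = individuals or [f"s{i}" for i in range(len(next(iter(dosages.values()))))]
    df = pd.DataFrame(dosages, index=pd.Index(individuals, name="individual_id"), dtype=float)
    return GenotypeMatrix(df, make_variants_frame(variants))


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    return matrix_from(
        {"rs1": [0, 1, 2, np.nan], "rs2": [2, 2, 0, 1]},
        [
            {"rsid": "rs1", "chrom": "1", "pos": 100, "ref": "A", "alt": "G"},
            {"rsid": "rs2", "chrom": "1", "pos": 200, "ref": "C", "alt": "T"},
        ],
    )


class TestVcf:
    def test_gt_parsing_conventions(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\t./.\n"
        )
        gm = read_vcf_dosages(vcf)
        got = gm.dosages["rs1"].tolist()
        assert got[:3] == [0.0, 1.0, 2.0]
        assert np.isnan(got[3])

    def test_non_snp_and_multiallelic_skipped(self, tmp_path):
        vcf = tmp_path / "mixed.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\n"
            "1\t200\trs2\tA\tG,T\t.\t.\t.\tGT\t0/1\n"
            "1\t300\trs3\tAT\tA\t.\t.\t.\tGT\t0/1\n"
        )
        gm = read_vcf_dosages(vcf)
        assert list(gm.rsids) == ["rs1"]

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(VcfParseError):
            read_vcf_dosages(tmp_path / "nope.vcf")

    def test_round_trip_preserves_dosages(self, tmp_path, toy_matrix):
        path = tmp_path / "rt.vcf"
        write_vcf(toy_matrix, path)
        back = read_vcf_dosages(path)
        pd.testing.assert_frame_equal(back.dosages, toy_matrix.dosages)
        assert list(back.variants["ref"]) == list(toy_matrix.variants["ref"])

    def test_round_trip_synthetic_cohort(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.vcf"
        write_vcf(small_cohort.genotypes, path)
        back = read_vcf_dosages(path)
        pd.testing.assert_frame_equal(back.dosages, small_cohort.genotypes.dosages)


class TestWeightTableIO:
    def test_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "w.tsv"
        write_weight_table(small_cohort.weights_t2d, path)
        back = read_weight_table(path)
        pd.testing.assert_frame_equal(back, small_cohort.weights_t2d)

    def test_duplicate_rsids_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "rsid\teffect_allele\tother_allele\tbeta\nrs1\tA\tG\t0.1\nrs1\tA\tG\t0.2\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_weight_table(path)


def weights(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["rsid", "effect_allele", "other_allele", "beta"])


class TestHarmonize:
    def test_effect_equals_alt_is_identity(self, toy_matrix):
        w = weights([("rs1", "G", "A", 0.1)])
        oriented, report = harmonize(w, toy_matrix)
        pd.testing.assert_series_equal(
            oriented.dosages["rs1"], toy_matrix.dosages["rs1"]
        )
        assert report.empty

    def test_effect_equals_ref_flips_dosage(self, toy_matrix):
        # effect allele A on a REF=A/ALT=G record: K_ALT = 0 -> oriented 2
        w = weights([("rs1", "A", "G", 0.1)])
        oriented, _ = harmonize(w, toy_matrix)
        got = oriented.dosages["rs1"].tolist()
        assert got[:3] == [2.0, 1.0, 0.0]
        assert np.isnan(got[3])
        assert oriented.variants.loc["rs1", "counted_allele"] == "A"

    def test_strand_ambiguous_excluded(self):
        gm = matrix_from(
            {"rs9": [0, 1]},
            [{"rsid": "rs9", "chrom": "1", "pos": 5, "ref": "A", "alt": "T"}],
        )
        w = weights([("rs9", "A", "T", 0.2)])
        oriented, report = harmonize(w, gm)
        assert oriented.n_variants == 0
        assert report["reason"].tolist() == ["strand_ambiguous"]

    def test_strand_ambiguous_kept_when_allowed(self):
        gm = matrix_from(
            {"rs9": [0, 1]},
            [{"rsid": "rs9", "chrom": "1", "pos": 5, "ref": "A", "alt": "T"}],
        )
        w = weights([("rs9", "T", "A", 0.2)])
        oriented, report = harmonize(w, gm, allow_ambiguous=True)
        assert oriented.n_variants == 1 and report.empty

    def test_allele_mismatch_and_missing_rsid(self, toy_matrix):
        w = weights([("rs1", "C", "T", 0.1), ("rsX", "A", "G", 0.1)])
        oriented, report = harmonize(w, toy_matrix)
        assert oriented.n_variants == 0
        assert dict(zip(report["rsid"], report["reason"])) == {
            "rs1": "allele_mismatch",
            "rsX": "missing_genotype",
        }

    def test_involution_safe(self, toy_matrix):
        w = weights([("rs1", "A", "G", 0.1), ("rs2", "T", "C", 0.2)])
        once, _ = harmonize(w, toy_matrix)
        twice, report = harmonize(w, once)
        pd.testing.assert_frame_equal(once.dosages, twice.dosages)
        assert report.empty

    def test_oriented_plus_complement_is_two(self, small_cohort):
        wt = small_cohort.weights_t2d
        oriented, _ = harmonize(wt, small_cohort.genotypes)
        flipped = wt.rename(
            columns={"effect_allele": "other_allele", "other_allele": "effect_allele"}
        )
        complement, _ = harmonize(flipped, small_cohort.genotypes)
        total = oriented.dosages + complement.dosages
        assert np.allclose(total.to_numpy(), 2.0)


class TestImpute:
    def test_mean_imputation_value(self):
        gm = matrix_from(
            {"rs1": [0, 1, 1, 2, np.nan]},
            [{"rsid": "rs1", "chrom": "1", "pos": 1, "ref": "A", "alt": "G"}],
        )
        out = impute_missing(gm)
        assert out.dosages["rs1"].iloc[4] == pytest.approx(1.0)

    def test_homozygote_only_imputes_two(self):
        gm = matrix_from(
            {"rs1": [2, 2, np.nan]},
            [{"rsid": "rs1", "chrom": "1", "pos": 1, "ref": "A", "alt": "G"}],
        )
        assert impute_missing(gm).dosages["rs1"].iloc[2] == pytest.approx(2.0)

    def test_no_missing_is_identity(self, small_cohort):
        out = impute_missing(small_cohort.genotypes)
        pd.testing.assert_frame_equal(out.dosages, small_cohort.genotypes.dosages)

    def test_fully_missing_variant_named_in_error(self):
        gm = matrix_from(
            {"rs1": [0, 1], "rsBAD": [np.nan, np.nan]},
            [
                {"rsid": "rs1", "chrom": "1", "pos": 1, "ref": "A", "alt": "G"},
                {"rsid": "rsBAD", "chrom": "1", "pos": 2, "ref": "C", "alt": "T"},
            ],
        )
        with pytest.raises(MissingVariantError, match="rsBAD"):
            impute_missing(gm)

    def test_imputation_preserves_variant_means(self):
        rng = np.random.default_rng(0)
        k = rng.integers(0, 3, size=(50, 4)).astype(float)
        k[rng.random(k.shape) < 0.2] = np.nan
        gm = matrix_from(
            {f"rs{j}": k[:, j] for j in range(4)},
            [
                {"rsid": f"rs{j}", "chrom": "1", "pos": j + 1, "ref": "A", "alt": "G"}
                for j in range(4)
            ],
        )
        out = impute_missing(gm)
        before = gm.dosages.mean(axis=0)
        after = out.dosages.mean(axis=0)
        assert np.allclose(before.to_numpy(), after.to_numpy())
        assert not out.has_missing()
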