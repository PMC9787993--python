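"""Genotype and weight-table I/O, effect-allele harmonization, imputation.

Genotypes live in a :class:`GenotypeMatrix`: an individuals x SNPs table of
allele dosages (0, 1, 2 copies of a counted allele; ``NaN`` = missing call)
plus per-variant metadata.  Dosages read from VCF count ALT copies; after
:func:`harmonize` they count the effect allele of a GWAS weight table, which
is the orientation required for score arithmetic.

Weight tables are tab-separated with columns
``rsid effect_allele other_allele beta`` where ``beta`` is the per-allele
log odds ratio published for the effect allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import MissingVariantError, VcfParseError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
#: Allele pairs that are their own reverse complement; indistinguishable
#: across strand flips and therefore excluded by default.
AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))

WEIGHT_COLUMNS = ["rsid", "effect_allele", "other_allele", "beta"]


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix with variant metadata.

    Attributes
    ----------
    dosages
        DataFrame indexed by individual id, one float column per rsID,
        values in {0, 1, 2} or NaN (missing).  After mean imputation the
        values may be fractional.
    variants
        DataFrame indexed by rsID with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``, ``counted_allele``, ``other_allele``.  Fresh
        matrices count ALT; harmonized matrices count the effect allele.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.variants.index):
            raise ValueError("dosage columns and variant index disagree")

    @property
    def individuals(self) -> pd.Index:
        return self.dosages.index

    @property
    def rsids(self) -> pd.Index:
        return self.variants.index

    @property
    def n_individuals(self) -> int:
        return len(self.dosages)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def has_missing(self) -> bool:
        return bool(self.dosages.isna().any().any())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), self.variants.copy())


def make_variants_frame(records: list[dict]) -> pd.DataFrame:
    """Build the variant-metadata frame, defaulting the counted allele to ALT."""
    df = pd.DataFrame.from_records(records)
    if "counted_allele" not in df:
        df["counted_allele"] = df["alt"]
        df["other_allele"] = df["ref"]
    return df.set_index("rsid")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

# cyvcf2 gt_types codes: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_GT_TO_DOSAGE = {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Read hard GT calls from a VCF 4.x file into ALT-allele dosages.

    Only biallelic single-base substitutions are kept; multi-allelic or
    non-SNP records are skipped and the skip count logged.  Missing calls
    (``./.``) become NaN.
    """
    path = Path(path)
    if not path.exists():
        raise VcfParseError(f"{path}: no such file")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"{path}: {exc}") from exc

    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    records: list[dict] = []
    skipped = 0
    for i, v in enumerate(vcf):
        ref, alts = v.REF, v.ALT
        if (
            len(alts) != 1
            or len(ref) != 1
            or len(alts[0]) != 1
            or ref not in VALID_BASES
            or alts[0] not in VALID_BASES
        ):
            skipped += 1
            continue
        rsid = v.ID or f"{v.CHROM}:{v.POS}"
        if rsid in columns:
            raise VcfParseError(f"{path}: duplicate variant id {rsid} (record {i + 1})")
        try:
            dosage = np.array([_GT_TO_DOSAGE[g] for g in v.gt_types], dtype=float)
        except KeyError as exc:
            raise VcfParseError(
                f"{path}: unparseable genotype in record {i + 1} ({rsid})"
            ) from exc
        columns[rsid] = dosage
        records.append(
            {"rsid": rsid, "chrom": v.CHROM, "pos": v.POS, "ref": ref, "alt": alts[0]}
        )
    if skipped:
        logger.info("read_vcf_dosages: skipped %d non-biallelic/non-SNP records", skipped)
    if not records:
        raise VcfParseError(f"{path}: no usable SNP records")
    dosages = pd.DataFrame(columns, index=pd.Index(samples, name="individual_id"))
    return GenotypeMatrix(dosages, make_variants_frame(records))


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 (GT only, one ALT per record)."""
    var = genotypes.variants
    dos = genotypes.dosages
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in dict.fromkeys(var["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += [str(s) for s in dos.index]
    lines.append("\t".join(header))
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for rsid, row in var.iterrows():
        calls = [
            "./." if np.isnan(k) else gt_map[float(k)] for k in dos[rsid].to_numpy()
        ]
        rec = [
            str(row["chrom"]),
            str(int(row["pos"])),
            str(rsid),
            row["ref"],
            row["alt"],
            ".",
            ".",
            ".",
            "GT",
        ] + calls
        lines.append("\t".join(rec))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Weight tables
# ---------------------------------------------------------------------------


def read_weight_table(path: str | Path) -> pd.DataFrame:
    """Read a GWAS weight table (TSV with header ``rsid effect_allele
    other_allele beta``)."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str})
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise VcfParseError(f"{path}: weight table missing columns {missing}")
    if df["rsid"].duplicated().any():
        dups = df.loc[df["rsid"].duplicated(), "rsid"].tolist()
        raise ValueError(f"weight table has duplicate rsIDs: {dups}")
    if not np.isfinite(df["beta"].to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: non-finite beta in weight table")
    return df[WEIGHT_COLUMNS]


def write_weight_table(weights: pd.DataFrame, path: str | Path) -> None:
    weights[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in AMBIGUOUS_PAIRS


def harmonize(
    weights: pd.DataFrame,
    genotypes: GenotypeMatrix,
    allow_ambiguous: bool = False,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Orient dosages to the weight table's effect alleles.

    For each weight row matched by rsID: if the effect allele is the
    matrix's counted allele the dosage is kept; if it is the other allele
    the dosage is flipped to ``2 - K``; anything else is excluded.
    Strand-ambiguous SNPs (A/T, C/G) are excluded unless
    ``allow_ambiguous``.  Harmonizing an already-oriented matrix is a
    no-op for the retained SNPs.

    Returns the oriented matrix (weight-table SNP order) and an exclusion
    report with columns ``rsid`` and ``reason``.
    """
    var = genotypes.variants
    kept_cols: dict[str, np.ndarray] = {}
    kept_records: list[dict] = []
    exclusions: list[dict] = []

    for row in weights.itertuples(index=False):
        rsid, eff, oth = row.rsid, row.effect_allele, row.other_allele
        if rsid not in var.index:
            exclusions.append({"rsid": rsid, "reason": "missing_genotype"})
            continue
        if is_strand_ambiguous(eff, oth) and not allow_ambiguous:
            exclusions.append({"rsid": rsid, "reason": "strand_ambiguous"})
            continue
        v = var.loc[rsid]
        counted, other = v["counted_allele"], v["other_allele"]
        k = genotypes.dosages[rsid].to_numpy(dtype=float)
        if eff == counted and oth == other:
            oriented = k
        elif eff == other and oth == counted:
            oriented = 2.0 - k
        else:
            exclusions.append({"rsid": rsid, "reason": "allele_mismatch"})
            continue
        kept_cols[rsid] = oriented
        kept_records.append(
            {
                "rsid": rsid,
                "chrom": v["chrom"],
                "pos": v["pos"],
                "ref": v["ref"],
                "alt": v["alt"],
                "counted_allele": eff,
                "other_allele": oth,
            }
        )

    report = pd.DataFrame(exclusions, columns=["rsid", "reason"])
    if not kept_records:
        empty = GenotypeMatrix(
            pd.DataFrame(index=genotypes.individuals),
            pd.DataFrame(
                columns=["chrom", "pos", "ref", "alt", "counted_allele", "other_allele"],
                index=pd.Index([], name="rsid"),
            ),
        )
        return empty, report
    dosages = pd.DataFrame(kept_cols, index=genotypes.individuals)
    variants = pd.DataFrame.from_records(kept_records).set_index("rsid")
    if len(report):
        logger.info(
            "harmonize: excluded %d of %d weight rows (%s)",
            len(report),
            len(weights),
            report["reason"].value_counts().to_dict(),
        )
    return GenotypeMatrix(dosages, variants), report


# ---------------------------------------------------------------------------
# Missing-data policy
# ---------------------------------------------------------------------------


def impute_missing(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-variant mean of observed calls.

    The per-variant mean equals twice the counted-allele frequency, the
    standard mean-imputation policy for score arithmetic; it preserves
    each variant's mean dosage.  A fully missing variant is an error.
    """
    dos = genotypes.dosages
    fully_missing = dos.columns[dos.isna().all(axis=0)]
    if len(fully_missing):
        raise MissingVariantError(
            f"variant(s) with no observed calls: {', '.join(fully_missing)}"
        )
    if not genotypes.has_missing():
        return genotypes
    filled = dos.fillna(dos.mean(axis=0))
    return replace(genotypes, dosages=filled)


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a two-visit phenotype TSV (``individual_id sex age <trait>_T1
    <trait>_T2 ...``) indexed by individual id."""
    df = pd.read_csv(path, sep="\t")
    if "individual_id" not in df.columns:
        raise ValueError(f"{path}: phenotype table lacks 'individual_id'")
    return df.set_index("individual_id")


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index=True, index_label="individual_id")
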