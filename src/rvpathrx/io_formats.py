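"""Readers, writers and in-memory containers for every external format the pipeline touches.

The pipeline consumes four inputs — a cohort VCF (v4.2 subset, ``GT:DP:GQ:AD``), a
per-variant functional annotation table (TSV; the contract with VEP/dbNSFP/LOFTEE,
which are *not* executed here), a pathway database in GMT format, and a phenotype/
covariate table — and emits TSV result tables.

Conventions
-----------
* Coordinates are 1-based as in VCF. The variant identity key is
  ``(chrom, pos, ref, alt)`` after biallelic normalization.
* Sex is encoded for modeling as female=0 / male=1 (recorded in output headers).
* Absent values in result TSVs are written as ``'.'``, never as an empty string.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VcfParseError",
    "GmtParseError",
    "TableParseError",
    "GT_HOM_REF",
    "GT_HET",
    "GT_HOM_ALT",
    "GT_MISSING",
    "CohortVariants",
    "AnnotationRecord",
    "PathwayDB",
    "CohortDesign",
    "read_vcf",
    "write_vcf",
    "read_gmt",
    "write_gmt",
    "read_phenotypes",
    "write_phenotypes",
    "read_annotations",
    "write_annotations",
    "write_results",
    "read_results",
]


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed (message names the offending line)."""


class GmtParseError(ValueError):
    """Raised for malformed GMT gene-set files."""


class TableParseError(ValueError):
    """Raised for malformed TSV tables (missing columns, unknown samples...)."""


# Biallelic genotype codes (dominance/dosage coding derives from these).
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1

_GT_LABELS = {GT_HOM_REF: "hom_ref", GT_HET: "het", GT_HOM_ALT: "hom_alt", GT_MISSING: "missing"}

#: Sentinel for absent integer FORMAT fields (DP/GQ/AD).
ABSENT = -1


@dataclass
class CohortVariants:
    """Per-variant, per-sample genotype calls with QC fields.

    Genotypes are stored as allele-index pairs ``(a1, a2)`` so that multiallelic
    records survive until :func:`rvpathrx.genotype_qc.split_and_trim_alleles`
    recodes them. ``-1`` marks a missing allele; DP/GQ/AD use ``-1`` for
    *absent* (field not present in the VCF record), which QC treats as
    "leave this sub-filter alone".

    Attributes
    ----------
    samples : list of str
        Sample ids, in VCF column order.
    variants : pandas.DataFrame
        Columns ``chrom`` (str), ``pos`` (int, 1-based), ``id`` (str or None),
        ``ref`` (str), ``alts`` (tuple of str).
    a1, a2 : int16 arrays, shape (n_variants, n_samples)
        Allele indexes (0 = REF, k = k-th ALT), -1 = missing.
    dp, gq : int32 arrays, shape (n_variants, n_samples)
        Read depth / genotype quality, -1 = absent.
    ad : int32 array, shape (n_variants, n_samples, max_alleles)
        Per-allele read depths, -1 = absent.
    """

    samples: list
    variants: pd.DataFrame
    a1: np.ndarray
    a2: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    ad: np.ndarray

    def __post_init__(self):
        n_v, n_s = len(self.variants), len(self.samples)
        for name in ("a1", "a2", "dp", "gq"):
            arr = getattr(self, name)
            if arr.shape != (n_v, n_s):
                raise ValueError(
                    f"calls matrix {name!r} has shape {arr.shape}, expected {(n_v, n_s)}"
                )
        if self.ad.ndim != 3 or self.ad.shape[:2] != (n_v, n_s):
            raise ValueError(f"ad has shape {self.ad.shape}, expected ({n_v}, {n_s}, k)")
        if n_v:
            if (self.variants["pos"] < 1).any():
                raise ValueError("variant pos must be >= 1")
            for ref, alts in zip(self.variants["ref"], self.variants["alts"]):
                if any(a == ref for a in alts):
                    raise ValueError(f"ref == alt ({ref}) is not a variant")

    # -- basic introspection -------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def is_biallelic(self) -> bool:
        return bool(all(len(a) == 1 for a in self.variants["alts"]))

    def variant_keys(self) -> list:
        """``(chrom, pos, ref, alt)`` keys; requires biallelic records."""
        self._require_biallelic()
        return [
            (c, int(p), r, a[0])
            for c, p, r, a in zip(
                self.variants["chrom"], self.variants["pos"],
                self.variants["ref"], self.variants["alts"],
            )
        ]

    def _require_biallelic(self):
        if not self.is_biallelic:
            raise ValueError("operation requires biallelic records; run split_and_trim_alleles")

    def gt_codes(self) -> np.ndarray:
        """Biallelic genotype code matrix: 0 hom_ref / 1 het / 2 hom_alt / -1 missing."""
        self._require_biallelic()
        miss = (self.a1 < 0) | (self.a2 < 0)
        codes = (self.a1 > 0).astype(np.int8) + (self.a2 > 0).astype(np.int8)
        codes[miss] = GT_MISSING
        return codes

    def gt_labels(self) -> np.ndarray:
        """Genotype codes as string labels (``hom_ref``/``het``/``hom_alt``/``missing``)."""
        codes = self.gt_codes()
        out = np.empty(codes.shape, dtype=object)
        for code, label in _GT_LABELS.items():
            out[codes == code] = label
        return out

    def copy(self) -> "CohortVariants":
        return CohortVariants(
            samples=list(self.samples),
            variants=self.variants.copy(),
            a1=self.a1.copy(), a2=self.a2.copy(),
            dp=self.dp.copy(), gq=self.gq.copy(), ad=self.ad.copy(),
        )


@dataclass(frozen=True)
class AnnotationRecord:
    """One functional annotation row: a (variant, gene, transcript) triple.

    Scores and allele frequencies are ``None`` when the annotation source left
    them blank. ``consequences`` holds the Sequence-Ontology terms of a possibly
    compound consequence (``missense_variant&splice_region_variant`` arrives as
    two terms).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    canonical: bool
    consequences: tuple
    revel: Optional[float] = None
    metarnn: Optional[float] = None
    loftee: Optional[str] = None  # 'HC', 'LC' or None
    af_gnomad_exomes: Optional[float] = None
    af_gnomad_genomes: Optional[float] = None

    def __post_init__(self):
        if not self.consequences:
            raise ValueError("consequences must be non-empty")
        for name in ("revel", "metarnn", "af_gnomad_exomes", "af_gnomad_genomes"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.loftee is not None and self.loftee not in ("HC", "LC"):
            raise ValueError(f"loftee must be 'HC', 'LC' or absent, got {self.loftee!r}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PathwayDB:
    """Named gene-sets plus the gene universe (union of all sets unless overridden)."""

    pathways: dict  # name -> frozenset of gene symbols
    descriptions: dict = field(default_factory=dict)
    universe: frozenset = None

    def __post_init__(self):
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")
        union = frozenset().union(*self.pathways.values()) if self.pathways else frozenset()
        if self.universe is None:
            self.universe = union
        elif not union <= frozenset(self.universe):
            missing = sorted(union - frozenset(self.universe))[:5]
            raise ValueError(f"pathway genes missing from universe, e.g. {missing}")

    def __len__(self):
        return len(self.pathways)

    def __contains__(self, name):
        return name in self.pathways

    def __getitem__(self, name):
        return self.pathways[name]


@dataclass
class CohortDesign:
    """Phenotype/covariate table: response group (SR/OR), age in years, sex.

    SR (suboptimal responder) is the case group, coded 1 in the binary
    phenotype; sex is coded female=0 / male=1 for modeling.
    """

    samples: list
    group: np.ndarray  # object array of 'SR'/'OR'
    age: np.ndarray    # float
    sex: np.ndarray    # object array of 'male'/'female'

    def __post_init__(self):
        n = len(self.samples)
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample ids in phenotype table")
        for name in ("group", "age", "sex"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of samples")
        bad = set(self.group) - {"SR", "OR"}
        if bad:
            raise ValueError(f"unknown response group labels: {sorted(bad)}")
        if not ((self.group == "SR").any() and (self.group == "OR").any()):
            raise ValueError("both response groups must be non-empty")
        bad = set(self.sex) - {"male", "female"}
        if bad:
            raise ValueError(f"unknown sex labels: {sorted(bad)}")

    @property
    def y(self) -> np.ndarray:
        """Binary phenotype: SR=1, OR=0."""
        return (self.group == "SR").astype(float)

    @property
    def sex_code(self) -> np.ndarray:
        """female=0, male=1."""
        return (self.sex == "male").astype(float)

    def covariates(self) -> np.ndarray:
        """Covariate matrix (age, sex) without intercept, shape (n, 2)."""
        return np.column_stack([self.age.astype(float), self.sex_code])

    def aligned_to(self, vcf_samples: Sequence[str]) -> "CohortDesign":
        """Reorder to VCF sample order; every phenotype sample must be in the VCF."""
        extra = [s for s in self.samples if s not in set(vcf_samples)]
        if extra:
            raise TableParseError(
                f"phenotype samples absent from VCF: {extra[:5]}"
            )
        idx = {s: i for i, s in enumerate(self.samples)}
        order = [idx[s] for s in vcf_samples if s in idx]
        if len(order) != len(vcf_samples):
            missing = [s for s in vcf_samples if s not in idx]
            raise TableParseError(f"VCF samples absent from phenotype table: {missing[:5]}")
        return CohortDesign(
            samples=[self.samples[i] for i in order],
            group=self.group[order], age=self.age[order], sex=self.sex[order],
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> CohortVariants:
    """Read a VCF v4.2 (subset) into a :class:`CohortVariants`.

    One record is kept per VCF line with its full ALT tuple; multiallelic lines
    are split downstream by ``genotype_qc.split_and_trim_alleles``. FORMAT must
    contain at least GT; DP/GQ/AD are optional per record and stored as ``-1``
    (absent) when not present. Sample order is preserved.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
        samples = list(vcf.samples)
    except Exception as exc:  # htslib reports its own line context
        raise VcfParseError(f"{path}: malformed VCF header ({exc})") from exc

    chroms, poss, ids, refs, altss = [], [], [], [], []
    rows_a1, rows_a2, rows_dp, rows_gq, rows_ad = [], [], [], [], []
    n_s = len(samples)
    max_alleles = 2
    line_no = 0
    try:
        for v in vcf:
            line_no += 1
            alts = tuple(v.ALT)
            if not alts:
                continue  # monomorphic record: nothing to model
            chroms.append(v.CHROM)
            poss.append(v.POS)
            ids.append(v.ID)
            refs.append(v.REF)
            altss.append(alts)
            max_alleles = max(max_alleles, 1 + len(alts))

            gts = v.genotypes
            if gts is None or len(gts) != n_s:
                raise VcfParseError(
                    f"{path}: record {line_no} ({v.CHROM}:{v.POS}) has ragged genotype columns"
                )
            a1 = np.full(n_s, -1, dtype=np.int16)
            a2 = np.full(n_s, -1, dtype=np.int16)
            for i, g in enumerate(gts):
                alleles = g[:-1]  # last element is the phased flag
                if len(alleles) >= 1 and alleles[0] is not None and alleles[0] >= 0:
                    a1[i] = alleles[0]
                if len(alleles) >= 2 and alleles[1] is not None and alleles[1] >= 0:
                    a2[i] = alleles[1]
                elif len(alleles) == 1:
                    a2[i] = a1[i]  # haploid call treated as homozygous
            rows_a1.append(a1)
            rows_a2.append(a2)

            rows_dp.append(_format_int_vector(v, "DP", n_s))
            rows_gq.append(_format_int_vector(v, "GQ", n_s))
            rows_ad.append(_format_ad(v, n_s, 1 + len(alts)))
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"{path}: parse error at record {line_no + 1}: {exc}") from exc

    n_v = len(chroms)
    ad = np.full((n_v, n_s, max_alleles), ABSENT, dtype=np.int32)
    for i, block in enumerate(rows_ad):
        ad[i, :, : block.shape[1]] = block

    variants = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64), "id": ids,
         "ref": refs, "alts": altss}
    )
    return CohortVariants(
        samples=samples,
        variants=variants,
        a1=np.vstack(rows_a1) if n_v else np.empty((0, n_s), np.int16),
        a2=np.vstack(rows_a2) if n_v else np.empty((0, n_s), np.int16),
        dp=np.vstack(rows_dp) if n_v else np.empty((0, n_s), np.int32),
        gq=np.vstack(rows_gq) if n_v else np.empty((0, n_s), np.int32),
        ad=ad,
    )


def _format_int_vector(v, tag: str, n_s: int) -> np.ndarray:
    arr = None
    try:
        arr = v.format(tag)
    except KeyError:
        arr = None
    if arr is None:
        return np.full(n_s, ABSENT, dtype=np.int32)
    out = np.asarray(arr, dtype=np.int64).reshape(n_s, -1)[:, 0]
    out = out.astype(np.int32)
    out[out < 0] = ABSENT  # htslib missing sentinel is a large negative int
    return out


def _format_ad(v, n_s: int, n_alleles: int) -> np.ndarray:
    try:
        arr = v.format("AD")
    except KeyError:
        arr = None
    if arr is None:
        return np.full((n_s, n_alleles), ABSENT, dtype=np.int32)
    out = np.asarray(arr, dtype=np.int64).reshape(n_s, -1)
    if out.shape[1] < n_alleles:
        pad = np.full((n_s, n_alleles - out.shape[1]), ABSENT, dtype=np.int64)
        out = np.hstack([out, pad])
    out = out[:, :n_alleles].astype(np.int32)
    out[out < 0] = ABSENT
    return out


def write_vcf(cv: CohortVariants, path) -> None:
    """Write a :class:`CohortVariants` as VCF v4.2 with FORMAT ``GT:DP:GQ:AD``.

    Fields stored as absent are emitted as ``'.'``. Round-trips through
    :func:`read_vcf` on all modeled fields.
    """
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    for chrom in dict.fromkeys(cv.variants["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cv.samples)
    )
    for i in range(cv.n_variants):
        row = cv.variants.iloc[i]
        n_alleles = 1 + len(row["alts"])
        fields = [
            str(row["chrom"]), str(int(row["pos"])),
            row["id"] if row["id"] else ".",
            row["ref"], ",".join(row["alts"]), ".", ".", ".", "GT:DP:GQ:AD",
        ]
        for j in range(cv.n_samples):
            a1, a2 = int(cv.a1[i, j]), int(cv.a2[i, j])
            gt = f"{a1 if a1 >= 0 else '.'}/{a2 if a2 >= 0 else '.'}"
            dp = cv.dp[i, j]
            gq = cv.gq[i, j]
            ad_vec = cv.ad[i, j, :n_alleles]
            ad = "." if (ad_vec < 0).all() else ",".join(
                str(int(x)) if x >= 0 else "." for x in ad_vec
            )
            fields.append(
                f"{gt}:{dp if dp >= 0 else '.'}:{gq if gq >= 0 else '.'}:{ad}"
            )
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> PathwayDB:
    """Read a GMT gene-set file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are deduplicated; the universe is the union
    of all pathway genes.
    """
    pathways, descriptions = {}, {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtParseError(
                    f"{path}: line {line_no}: expected >=3 tab-separated fields, got {len(parts)}"
                )
            name, desc = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise GmtParseError(f"{path}: line {line_no}: pathway {name!r} has no genes")
            pathways[name] = genes
            descriptions[name] = desc
    if not pathways:
        raise GmtParseError(f"{path}: no pathways")
    return PathwayDB(pathways=pathways, descriptions=descriptions)


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for name, genes in db.pathways.items():
            desc = db.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Phenotype / annotation / result tables
# ---------------------------------------------------------------------------

_PHENO_COLUMNS = ["sample_id", "group", "age", "sex"]


def read_phenotypes(path) -> CohortDesign:
    """Read the TSV phenotype table (``sample_id``, ``group``, ``age``, ``sex``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, _PHENO_COLUMNS, path)
    return CohortDesign(
        samples=df["sample_id"].tolist(),
        group=df["group"].to_numpy(dtype=object),
        age=pd.to_numeric(df["age"], errors="coerce").to_numpy(dtype=float),
        sex=df["sex"].to_numpy(dtype=object),
    )


def write_phenotypes(design: CohortDesign, path) -> None:
    pd.DataFrame(
        {"sample_id": design.samples, "group": design.group,
         "age": design.age, "sex": design.sex}
    ).to_csv(path, sep="\t", index=False)


_ANNOT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "transcript", "canonical", "consequence"]
_ANNOT_OPTIONAL = ["revel", "metarnn", "loftee", "af_gnomad_exomes", "af_gnomad_genomes"]


def read_annotations(path) -> list:
    """Read the VEP-style annotation TSV; several rows per variant are expected
    (one per transcript/gene). Unknown columns are ignored; empty cells in the
    optional score/AF/LOFTEE columns become absent (``None``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", na_values=["."], keep_default_na=True)
    _require_columns(df, _ANNOT_COLUMNS, path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AnnotationRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                gene=str(row.gene),
                transcript=str(row.transcript),
                canonical=_parse_bool(row.canonical),
                consequences=tuple(str(row.consequence).split("&")),
                revel=_opt_float(getattr(row, "revel", None)),
                metarnn=_opt_float(getattr(row, "metarnn", None)),
                loftee=_opt_str(getattr(row, "loftee", None)),
                af_gnomad_exomes=_opt_float(getattr(row, "af_gnomad_exomes", None)),
                af_gnomad_genomes=_opt_float(getattr(row, "af_gnomad_genomes", None)),
            )
        )
    return records


def write_annotations(records: Iterable[AnnotationRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
             "gene": r.gene, "transcript": r.transcript,
             "canonical": "1" if r.canonical else "0",
             "consequence": "&".join(r.consequences),
             "revel": _fmt_opt(r.revel), "metarnn": _fmt_opt(r.metarnn),
             "loftee": r.loftee if r.loftee is not None else ".",
             "af_gnomad_exomes": _fmt_opt(r.af_gnomad_exomes),
             "af_gnomad_genomes": _fmt_opt(r.af_gnomad_genomes)}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_results(table: pd.DataFrame, path, params: Optional[Mapping] = None,
                  seed: Optional[int] = None) -> None:
    """Write a result table as TSV with a ``#``-comment header recording the
    parameters and seed that produced it. Missing values become ``'.'``."""
    with open(path, "w") as fh:
        fh.write("# rvpathrx result table\n")
        fh.write("# sex coding: female=0, male=1; group coding: SR=1, OR=0\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        for k, v in (params or {}).items():
            fh.write(f"# param {k}: {v}\n")
        table.to_csv(fh, sep="\t", index=False, na_rep=".")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["."])


# -- small helpers ----------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing mandatory column(s): {missing}")


def _parse_bool(x) -> bool:
    return str(x).strip().lower() in ("1", "true", "yes", "y")


def _opt_float(x) -> Optional[float]:
    if x is None or (isinstance(x, float) and np.isnan(x)) or str(x).strip() in ("", "."):
        return None
    return float(x)


def _opt_str(x) -> Optional[str]:
    if x is None or (isinstance(x, float) and np.isnan(x)) or str(x).strip() in ("", "."):
        return None
    return str(x)


def _fmt_opt(x) -> str:
    return "." if x is None else repr(float(x))
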