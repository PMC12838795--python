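"""Genotype- and variant-level quality control.

Filter chain (fixed order, recorded in the report): per-genotype masking →
biallelic split with allele trimming → per-variant missingness exclusion.

* A genotype is set to missing iff DP < ``min_dp``, or GQ < ``min_gq``, or the
  call is heterozygous with allelic balance AB = alt/(ref+alt) < ``min_het_ab``.
  Every threshold is a strict ``<``; calls lacking the relevant field are left
  unchanged for that sub-filter.
* A variant is excluded iff its fraction of missing genotypes is strictly
  greater than ``max_missing_fraction`` (default 5%).

Trimming here is reference-free: shared REF/ALT suffix then prefix are removed
with the position adjusted. Full left-alignment against a FASTA is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ABSENT, CohortVariants

__all__ = [
    "QcThresholds",
    "QcReport",
    "mask_low_quality_genotypes",
    "split_and_trim_alleles",
    "drop_high_missingness_variants",
    "run_qc",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    """Genotype-level and variant-level QC thresholds.

    Defaults follow the usual WES cohort practice of masking calls with
    sequencing depth < 20 reads, genotype quality < 20, heterozygous allelic
    balance < 0.2, and excluding variants missing in more than 5% of samples.
    """

    min_dp: int = 20
    min_gq: int = 20
    min_het_ab: float = 0.2
    max_missing_fraction: float = 0.05

    def __post_init__(self):
        if self.min_dp < 0 or self.min_gq < 0:
            raise ValueError("min_dp and min_gq must be >= 0")
        if not (0.0 <= self.min_het_ab <= 0.5):
            raise ValueError("min_het_ab must be in [0, 0.5]")
        if not (0.0 <= self.max_missing_fraction <= 1.0):
            raise ValueError("max_missing_fraction must be in [0, 1]")


@dataclass
class QcReport:
    """Bookkeeping for the QC funnel; counts never increase along the chain."""

    n_input_variants: int = 0
    n_after_split: int = 0
    n_after_missingness: int = 0
    n_genotypes_masked_dp: int = 0
    n_genotypes_masked_gq: int = 0
    n_genotypes_masked_ab: int = 0
    filter_order: tuple = ("mask", "split_trim", "missingness")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metric": ["n_input_variants", "n_after_split", "n_after_missingness",
                        "n_genotypes_masked_dp", "n_genotypes_masked_gq",
                        "n_genotypes_masked_ab", "filter_order"],
             "value": [self.n_input_variants, self.n_after_split,
                       self.n_after_missingness, self.n_genotypes_masked_dp,
                       self.n_genotypes_masked_gq, self.n_genotypes_masked_ab,
                       ">".join(self.filter_order)]}
        )


def mask_low_quality_genotypes(cv: CohortVariants, t: QcThresholds = QcThresholds(),
                               report: QcReport | None = None) -> CohortVariants:
    """Set low-quality genotypes to missing; all other fields are untouched.

    The AB sub-filter applies to heterozygous calls only (any call whose two
    allele indexes differ), with AB computed from AD as the fraction of reads
    supporting non-reference alleles. A heterozygote whose AD sums to zero is
    treated as AB = 0 and masked (logged). Masking is idempotent.
    """
    out = cv.copy()
    called = (out.a1 >= 0) & (out.a2 >= 0)

    mask_dp = called & (out.dp != ABSENT) & (out.dp < t.min_dp)
    mask_gq = called & (out.gq != ABSENT) & (out.gq < t.min_gq)

    het = called & (out.a1 != out.a2)
    ad_present = (out.ad >= 0).any(axis=2)
    ad = np.where(out.ad >= 0, out.ad, 0)
    total = ad.sum(axis=2)
    alt_reads = total - ad[:, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(total > 0, alt_reads / np.maximum(total, 1), 0.0)
    zero_total_het = het & ad_present & (total == 0)
    if zero_total_het.any():
        logger.warning(
            "%d heterozygous call(s) with zero total AD reads treated as AB=0 and masked",
            int(zero_total_het.sum()),
        )
    mask_ab = het & ad_present & (ab < t.min_het_ab)

    if report is not None:
        report.n_genotypes_masked_dp += int(mask_dp.sum())
        report.n_genotypes_masked_gq += int(mask_gq.sum())
        report.n_genotypes_masked_ab += int(mask_ab.sum())

    mask = mask_dp | mask_gq | mask_ab
    out.a1[mask] = -1
    out.a2[mask] = -1
    return out


def _trim_alleles(pos: int, ref: str, alt: str) -> tuple:
    """Remove shared suffix then prefix, keeping at least one base of each
    allele; the position advances by the number of prefix bases removed."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def split_and_trim_alleles(cv: CohortVariants) -> CohortVariants:
    """Decompose multiallelic records into one biallelic record per ALT.

    Per-sample genotypes are recoded against each ALT: alleles equal to that
    ALT's index count as alternate, any other called allele (reference or a
    different ALT) counts as reference for that record; a call with a missing
    allele stays missing. AD collapses to the (ref, alt) pair for that ALT.
    Already-biallelic SNVs pass through unchanged (up to trimming).
    """
    rows = []
    a1_out, a2_out, dp_out, gq_out, ad_out = [], [], [], [], []
    n_s = cv.n_samples
    for i in range(cv.n_variants):
        row = cv.variants.iloc[i]
        alts = row["alts"]
        called = (cv.a1[i] >= 0) & (cv.a2[i] >= 0)
        for k, alt in enumerate(alts, start=1):
            pos, ref_t, alt_t = _trim_alleles(int(row["pos"]), row["ref"], alt)
            rows.append((row["chrom"], pos, row["id"], ref_t, (alt_t,)))
            n_alt = (cv.a1[i] == k).astype(np.int16) + (cv.a2[i] == k).astype(np.int16)
            new_a1 = np.where(called, (n_alt >= 1).astype(np.int16), -1).astype(np.int16)
            new_a2 = np.where(called, (n_alt == 2).astype(np.int16), -1).astype(np.int16)
            a1_out.append(new_a1)
            a2_out.append(new_a2)
            dp_out.append(cv.dp[i].copy())
            gq_out.append(cv.gq[i].copy())
            pair = np.full((n_s, 2), ABSENT, dtype=np.int32)
            if cv.ad.shape[2] > k:
                pair[:, 0] = cv.ad[i, :, 0]
                pair[:, 1] = cv.ad[i, :, k]
            ad_out.append(pair)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alts"])
    n_v = len(rows)
    ad = (np.stack(ad_out) if n_v else np.empty((0, n_s, 2), np.int32))
    return CohortVariants(
        samples=list(cv.samples),
        variants=variants,
        a1=np.vstack(a1_out) if n_v else np.empty((0, n_s), np.int16),
        a2=np.vstack(a2_out) if n_v else np.empty((0, n_s), np.int16),
        dp=np.vstack(dp_out) if n_v else np.empty((0, n_s), np.int32),
        gq=np.vstack(gq_out) if n_v else np.empty((0, n_s), np.int32),
        ad=ad,
    )


def drop_high_missingness_variants(cv: CohortVariants, t: QcThresholds = QcThresholds(),
                                   report: QcReport | None = None):
    """Remove variants whose missing-genotype fraction exceeds the bound.

    Strict ``>``: at n=63 samples, 4 missing (6.35%) is dropped while
    3 missing (4.76%) is kept. Returns ``(filtered, report)``.
    """
    if cv.n_samples == 0:
        raise ValueError("cohort has zero samples")
    if report is None:
        report = QcReport(n_input_variants=cv.n_variants, n_after_split=cv.n_variants)
    missing_frac = ((cv.a1 < 0) | (cv.a2 < 0)).mean(axis=1)
    keep = missing_frac <= t.max_missing_fraction
    out = CohortVariants(
        samples=list(cv.samples),
        variants=cv.variants.loc[keep].reset_index(drop=True),
        a1=cv.a1[keep].copy(), a2=cv.a2[keep].copy(),
        dp=cv.dp[keep].copy(), gq=cv.gq[keep].copy(), ad=cv.ad[keep].copy(),
    )
    report.n_after_missingness = out.n_variants
    return out, report


def run_qc(cv: CohortVariants, t: QcThresholds = QcThresholds()):
    """Full QC chain: mask → split/trim → missingness. Returns ``(cv, QcReport)``."""
    report = QcReport(n_input_variants=cv.n_variants)
    masked = mask_low_quality_genotypes(cv, t, report=report)
    split = split_and_trim_alleles(masked)
    report.n_after_split = split.n_variants
    return drop_high_missingness_variants(split, t, report=report)
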