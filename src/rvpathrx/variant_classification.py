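"""Reduce VEP-style annotations to one record per variant–gene pair and decide
damaging-missense / pLoF / rare status.

Classification rules
--------------------
* One annotation is *picked* per (variant, gene): canonical-transcript records
  are preferred; among several canonical records the one whose most-severe
  consequence ranks highest wins (``missense_variant&splice_region_variant``
  beats plain ``missense_variant``); remaining ties break deterministically on
  transcript id.
* Missense deleteriousness is a *consensus score*: the mean of whichever of
  REVEL and MetaRNN are present. A variant is damaging missense iff its picked
  consequence is missense and the consensus score is strictly > 0.5.
* A variant is pLoF iff LOFTEE called it high-confidence (HC) and the picked
  consequence is in the pLoF set (frameshift, start/stop lost, stop gained,
  essential splice). pLoF takes precedence when both rules fire, so a variant
  is never double-counted.
* Rarity: the gnomAD allele frequency used is the max of the available exomes/
  genomes columns (0 when both absent — a novel variant is rare); rare iff
  strictly < 0.05. ``af_rule='min'`` switches to min-of-available, the other
  admissible reading of "found in either resource".
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import AnnotationRecord, CohortVariants

__all__ = [
    "PLOF_CONSEQUENCES",
    "SeverityOrder",
    "ClassifiedVariant",
    "pick_annotation",
    "consensus_missense_score",
    "classify",
    "is_rare",
    "max_gnomad_af",
    "classify_annotations",
    "build_rare_damaging_set",
]

#: Consequences eligible for pLoF status (with LOFTEE HC).
PLOF_CONSEQUENCES = frozenset(
    {"frameshift_variant", "start_lost", "stop_lost", "stop_gained",
     "splice_donor_variant", "splice_acceptor_variant"}
)

RARE_AF_THRESHOLD = 0.05
DAMAGING_SCORE_THRESHOLD = 0.5


class SeverityOrder:
    """Total order over Sequence-Ontology consequence terms, most severe first.

    The default ranking ships as package data (``data/consequence_severity.txt``)
    and can be overridden with any total order covering the terms in use.
    Unlisted terms rank below all listed ones, ordered lexicographically so the
    order stays total and deterministic.
    """

    def __init__(self, terms: Optional[Sequence[str]] = None):
        if terms is None:
            text = resources.files("rvpathrx.data").joinpath(
                "consequence_severity.txt").read_text()
            terms = [ln.strip() for ln in text.splitlines()
                     if ln.strip() and not ln.startswith("#")]
        if len(set(terms)) != len(terms):
            raise ValueError("severity order contains duplicate terms")
        self.terms = list(terms)
        self._rank = {t: i for i, t in enumerate(self.terms)}

    def rank(self, term: str):
        """Smaller = more severe; unknown terms sort after all known ones."""
        r = self._rank.get(term)
        if r is None:
            return (1, term)
        return (0, r)

    def most_severe(self, terms: Iterable[str]) -> str:
        return min(terms, key=self.rank)

    def compound_key(self, terms: Iterable[str], pad_to: int = 0):
        """Sort key for a (possibly compound) consequence: the sorted tuple of
        component ranks, padded so that a compound outranks its own prefix
        (``missense_variant&splice_region_variant`` is more severe than plain
        ``missense_variant``)."""
        ranks = sorted(self.rank(t) for t in terms)
        pad = ((2, ""),) * max(0, pad_to - len(ranks))  # sorts after any real rank
        return tuple(ranks) + pad

    def reversed(self) -> "SeverityOrder":
        return SeverityOrder(list(reversed(self.terms)))


DEFAULT_SEVERITY = SeverityOrder()


@dataclass(frozen=True)
class ClassifiedVariant:
    """The damaging/rare decision for one variant–gene pair."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence_picked: str
    consensus_score: Optional[float]
    damage_class: str  # 'damaging_missense' | 'plof' | 'none'
    is_rare: bool
    max_gnomad_af: float

    def __post_init__(self):
        if self.damage_class not in ("damaging_missense", "plof", "none"):
            raise ValueError(f"unknown damage_class {self.damage_class!r}")
        if self.damage_class == "damaging_missense":
            if self.consensus_score is None or not self.consensus_score > 0.5:
                raise ValueError("damaging_missense requires consensus_score > 0.5")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_damaging(self) -> bool:
        return self.damage_class != "none"


def pick_annotation(records: Sequence[AnnotationRecord],
                    severity: SeverityOrder = DEFAULT_SEVERITY) -> AnnotationRecord:
    """Pick the representative annotation for one (variant, gene).

    Canonical records are preferred outright; within the preferred stratum the
    record whose most-severe consequence ranks highest wins, ties broken by
    transcript id lexicographic order. Pure function of its inputs — permuting
    ``records`` never changes the winner.
    """
    if not records:
        raise ValueError("pick_annotation requires at least one record")
    keys = {(r.key, r.gene) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple variant–gene pairs: {sorted(keys)}")
    canonical = [r for r in records if r.canonical]
    pool = canonical if canonical else list(records)
    width = max(len(r.consequences) for r in pool)
    return min(pool, key=lambda r: (severity.compound_key(r.consequences, width),
                                    r.transcript))


def consensus_missense_score(revel: Optional[float],
                             metarnn: Optional[float]) -> Optional[float]:
    """Mean of the deleteriousness scores that are present; None if both absent."""
    present = [s for s in (revel, metarnn) if s is not None]
    if not present:
        return None
    return float(np.mean(present))


def max_gnomad_af(af_exomes: Optional[float], af_genomes: Optional[float],
                  af_rule: str = "max") -> float:
    """Collapse the two gnomAD AF columns to a single frequency.

    ``'max'`` (default): a variant common in *either* resource is not rare.
    ``'min'``: the other admissible reading. Both absent → 0 (novel variant).
    """
    present = [a for a in (af_exomes, af_genomes) if a is not None]
    if not present:
        return 0.0
    if af_rule == "max":
        return float(max(present))
    if af_rule == "min":
        return float(min(present))
    raise ValueError(f"af_rule must be 'max' or 'min', got {af_rule!r}")


def is_rare(af_exomes: Optional[float], af_genomes: Optional[float],
            threshold: float = RARE_AF_THRESHOLD, af_rule: str = "max") -> bool:
    """Rare iff the collapsed gnomAD AF is strictly below the threshold."""
    return max_gnomad_af(af_exomes, af_genomes, af_rule=af_rule) < threshold


def classify(ann: AnnotationRecord, severity: SeverityOrder = DEFAULT_SEVERITY,
             af_rule: str = "max") -> ClassifiedVariant:
    """Classify one picked annotation record.

    pLoF requires LOFTEE HC *and* a pLoF consequence; damaging missense
    requires a missense picked consequence and consensus score strictly > 0.5.
    pLoF wins when both could apply.
    """
    picked_term = severity.most_severe(ann.consequences)
    score = consensus_missense_score(ann.revel, ann.metarnn)

    is_plof = ann.loftee == "HC" and picked_term in PLOF_CONSEQUENCES
    is_missense = picked_term == "missense_variant"
    is_dmg_missense = (is_missense and score is not None
                       and score > DAMAGING_SCORE_THRESHOLD)

    if is_plof:
        damage_class = "plof"
    elif is_dmg_missense:
        damage_class = "damaging_missense"
    else:
        damage_class = "none"

    af = max_gnomad_af(ann.af_gnomad_exomes, ann.af_gnomad_genomes, af_rule=af_rule)
    return ClassifiedVariant(
        chrom=ann.chrom, pos=ann.pos, ref=ann.ref, alt=ann.alt, gene=ann.gene,
        consequence_picked="&".join(ann.consequences),
        consensus_score=score,
        damage_class=damage_class,
        is_rare=af < RARE_AF_THRESHOLD,
        max_gnomad_af=af,
    )


def classify_annotations(records: Iterable[AnnotationRecord],
                         severity: SeverityOrder = DEFAULT_SEVERITY,
                         af_rule: str = "max") -> list:
    """Group annotation rows by (variant, gene), pick one record per group and
    classify it. Output order follows the first appearance of each group, so
    parsing is order-stable."""
    groups: dict = {}
    for r in records:
        groups.setdefault((r.key, r.gene), []).append(r)
    out = []
    for recs in groups.values():
        out.append(classify(pick_annotation(recs, severity=severity),
                            severity=severity, af_rule=af_rule))
    return out


def build_rare_damaging_set(classified: Iterable[ClassifiedVariant],
                            cv: CohortVariants) -> list:
    """Keep variants that are damaging, rare, and *carried* in the QC'd cohort
    (at least one non-missing het or hom_alt genotype).

    Classified variants whose key is absent from the cohort (e.g. removed by
    QC) are dropped — they cannot be carried.
    """
    codes = cv.gt_codes()
    carried_by_key = {
        key: bool((codes[i] >= 1).any()) for i, key in enumerate(cv.variant_keys())
    }
    return [
        c for c in classified
        if c.is_damaging and c.is_rare and carried_by_key.get(c.key, False)
    ]


def classified_to_frame(classified: Iterable[ClassifiedVariant]) -> pd.DataFrame:
    """Tabular view of classification output (one row per variant–gene)."""
    rows = [
        {"chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt, "gene": c.gene,
         "consequence_picked": c.consequence_picked,
         "consensus_score": c.consensus_score, "damage_class": c.damage_class,
         "is_rare": c.is_rare, "max_gnomad_af": c.max_gnomad_af}
        for c in classified
    ]
    return pd.DataFrame(rows)
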