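"""Per-pathway carrier burden: 2×2 Fisher exact comparison of the number of
individuals carrying at least one qualifying (rare damaging, carried) variant
in any pathway gene, between response groups.

Conventions: carriers are counted once per person regardless of variant count;
individuals whose genotypes are entirely missing across the pathway's variants
count as non-carriers; the reported odds ratio is the unconditional sample
odds ratio (a·d)/(b·c); the p-value is the two-sided Fisher exact probability
under the point-probability rule (sum over tables with the observed margins
whose probability does not exceed the observed table's).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import CohortDesign, CohortVariants, PathwayDB
from .geneset_mapping import gene_carrier_matrix
from .variant_classification import ClassifiedVariant

__all__ = ["BurdenResult", "count_pathway_carriers", "fisher_2x2", "run_burden",
           "burden_to_frame"]


@dataclass(frozen=True)
class BurdenResult:
    """One pathway's carrier-count table and Fisher exact comparison.

    ``odds_ratio`` is +inf when b·c = 0 with a·d > 0 and NaN (reported as '.')
    when a·d = b·c = 0.
    """

    pathway: str
    carriers_sr: int
    noncarriers_sr: int
    carriers_or: int
    noncarriers_or: int
    odds_ratio: float
    p: float

    @property
    def pct_sr(self) -> float:
        n = self.carriers_sr + self.noncarriers_sr
        return 100.0 * self.carriers_sr / n if n else float("nan")

    @property
    def pct_or(self) -> float:
        n = self.carriers_or + self.noncarriers_or
        return 100.0 * self.carriers_or / n if n else float("nan")


def fisher_2x2(a: int, b: int, c: int, d: int):
    """Two-sided Fisher exact test of the 2×2 table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)`` with the sample odds ratio (a·d)/(b·c).
    The p-value sums, over the hypergeometric support with the observed
    margins, every table whose point probability does not exceed the observed
    table's (with a 1e-7 relative slack absorbing floating-point ties, the
    convention of standard exact-test implementations). Margins a+b and c+d
    must be positive.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    if a + b == 0 or c + d == 0:
        raise ValueError("each row of the 2x2 table must have a positive total")
    ad, bc = a * d, b * c
    if bc > 0:
        odds = ad / bc
    elif ad > 0:
        odds = math.inf
    else:
        odds = math.nan

    n1, n2, k = a + b, c + d, a + c
    xs = np.arange(max(0, k - n2), min(k, n1) + 1)
    log_pmf = (gammaln(n1 + 1) - gammaln(xs + 1) - gammaln(n1 - xs + 1)
               + gammaln(n2 + 1) - gammaln(k - xs + 1) - gammaln(n2 - k + xs + 1))
    log_pmf -= gammaln(n1 + n2 + 1) - gammaln(k + 1) - gammaln(n1 + n2 - k + 1)
    pmf = np.exp(log_pmf)
    obs = pmf[np.searchsorted(xs, a)]
    p = float(pmf[pmf <= obs * (1 + 1e-7)].sum())
    return odds, min(p, 1.0)


def count_pathway_carriers(pathway_genes: frozenset,
                           rare_damaging: Iterable[ClassifiedVariant],
                           cv: CohortVariants, design: CohortDesign):
    """Carrier counts ``(a, b, c, d)``: SR carriers / SR non-carriers /
    OR carriers / OR non-carriers, at the person level."""
    design = design.aligned_to(cv.samples)
    qualifying = [v for v in rare_damaging if v.gene in pathway_genes]
    is_sr = design.group == "SR"
    n_sr, n_or = int(is_sr.sum()), int((~is_sr).sum())
    if not qualifying:
        return 0, n_sr, 0, n_or
    mat = gene_carrier_matrix(qualifying, cv)
    carrier = mat.to_numpy(dtype=bool).any(axis=0)
    a = int((carrier & is_sr).sum())
    c = int((carrier & ~is_sr).sum())
    return a, n_sr - a, c, n_or - c


def run_burden(pathways: Sequence[str], db: PathwayDB,
               rare_damaging: Iterable[ClassifiedVariant],
               cv: CohortVariants, design: CohortDesign) -> list:
    """Carrier-burden Fisher test for each named pathway, sorted by p.

    ``pathways`` is typically the ORA-significant list but may be any subset
    of the database. Results are independent across pathways, so processing
    order never changes any row.
    """
    unknown = [p for p in pathways if p not in db]
    if unknown:
        raise KeyError(f"unknown pathway name(s): {unknown}")
    rare_damaging = list(rare_damaging)
    results = []
    for name in pathways:
        a, b, c, d = count_pathway_carriers(db[name], rare_damaging, cv, design)
        odds, p = fisher_2x2(a, b, c, d)
        results.append(BurdenResult(
            pathway=name, carriers_sr=a, noncarriers_sr=b,
            carriers_or=c, noncarriers_or=d, odds_ratio=odds, p=p,
        ))
    return sorted(results, key=lambda r: (r.p, r.pathway))


def burden_to_frame(results: Sequence[BurdenResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "pathway": r.pathway, "carriers_sr": r.carriers_sr,
            "noncarriers_sr": r.noncarriers_sr, "carriers_or": r.carriers_or,
            "noncarriers_or": r.noncarriers_or,
            "pct_sr": r.pct_sr, "pct_or": r.pct_or,
            "odds_ratio": (np.nan if math.isnan(r.odds_ratio) else r.odds_ratio),
            "p": r.p,
        })
    return pd.DataFrame(rows)
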