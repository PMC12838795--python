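"""Pathway over-representation analysis with combined scores and the
between-group ΔCombined Score volcano table.

For each pathway the overlap of a query gene-set with the pathway is tested
one-sided against the hypergeometric null (Fisher over-representation), BH
adjustment is applied across pathways, and an Enrichr-style combined score

    c = −ln(p) · |z|

is formed, where z measures how far the pathway's observed rank (by Fisher p)
deviates from its expected rank under random queries of the same size. The
expected-rank distribution is estimated by seeded Monte Carlo (random gene
sets drawn uniformly from the universe), since no precomputed lookup exists
for an arbitrary pathway database. By default p is the BH-adjusted p-value;
``combined_p='raw'`` switches to the unadjusted Fisher p.

The volcano table contrasts two runs: ΔCombined = combined_OR − combined_SR,
so pathways specific to suboptimal responders land on the negative axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PathwayDB

__all__ = [
    "OraResult", "VolcanoRow", "fisher_enrichment", "bh_adjust",
    "rank_deviation_z", "combined_score", "run_ora", "volcano",
    "ora_to_frame", "volcano_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OraResult:
    """Per-pathway over-representation statistics."""

    pathway: str
    k: int          # overlap
    n_query: int
    n_pathway: int
    n_universe: int
    p: float
    p_adj: float
    z: float
    combined: float

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n_query, self.n_pathway)):
            raise ValueError("overlap k outside [0, min(n_query, n_pathway)]")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must be in (0, 1]")
        if self.p_adj + 1e-12 < self.p:
            raise ValueError("adjusted p cannot be below raw p")


@dataclass(frozen=True)
class VolcanoRow:
    pathway: str
    combined_sr: float
    combined_or: float
    delta_combined: float     # combined_OR − combined_SR
    min_p_adj: float
    significant_in: str       # 'SR' | 'OR' | 'both' | 'neither'


def fisher_enrichment(query: frozenset, pathway: frozenset, universe: frozenset):
    """One-sided over-representation test.

    Returns ``(k, p)`` with ``p = P[X >= k]`` for X hypergeometric with
    ``n_universe`` genes, ``n_pathway`` marked, ``n_query`` drawn. The query is
    intersected with the universe before testing.
    """
    if not universe:
        raise ValueError("empty universe")
    if not pathway <= universe:
        raise ValueError("pathway must be a subset of the universe")
    q = frozenset(query) & universe
    k = len(q & pathway)
    N, n_p, n_q = len(universe), len(pathway), len(q)
    # survival function is P[X > k-1] = P[X >= k]
    p = float(stats.hypergeom.sf(k - 1, N, n_p, n_q))
    return k, min(max(p, np.finfo(float).tiny), 1.0)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return stats.false_discovery_control(pvals, method="bh")


def _observed_ranks(pvals: np.ndarray) -> np.ndarray:
    """Rank pathways by Fisher p ascending; ties share their average rank."""
    return stats.rankdata(pvals, method="average")


def rank_deviation_z(query_size: int, db: PathwayDB, observed_p: np.ndarray,
                     B: int = 2000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo z-score of rank deviation from the expected rank.

    ``B`` random gene sets of ``query_size`` are drawn uniformly (without
    replacement) from the universe; each draw ranks all pathways by Fisher p.
    For each pathway, z = (observed rank − null mean rank) / null rank sd.
    A degenerate null sd of 0 yields z = 0 (logged). Deterministic given
    ``seed`` and ``B``.
    """
    rng = np.random.default_rng(seed)
    names = list(db.pathways)
    universe = sorted(db.universe)
    N = len(universe)
    gene_index = {g: i for i, g in enumerate(universe)}
    # pathway membership matrix (n_pathways × N)
    member = np.zeros((len(names), N), dtype=bool)
    for r, name in enumerate(names):
        for g in db.pathways[name]:
            member[r, gene_index[g]] = True
    n_p = member.sum(axis=1)
    query_size = min(query_size, N)

    null_ranks = np.empty((B, len(names)))
    for b in range(B):
        draw = rng.choice(N, size=query_size, replace=False)
        k = member[:, draw].sum(axis=1)
        p = stats.hypergeom.sf(k - 1, N, n_p, query_size)
        null_ranks[b] = _observed_ranks(p)

    mean = null_ranks.mean(axis=0)
    sd = null_ranks.std(axis=0, ddof=1)
    obs = _observed_ranks(np.asarray(observed_p, dtype=float))
    z = np.zeros(len(names))
    nonzero = sd > 0
    z[nonzero] = (obs[nonzero] - mean[nonzero]) / sd[nonzero]
    if (~nonzero).any():
        logger.info("rank_deviation_z: %d pathway(s) with degenerate null sd -> z=0",
                    int((~nonzero).sum()))
    return z


def combined_score(p_used: float, z: float) -> float:
    """Enrichr-style combined score c = −ln(p) · |z| (non-negative)."""
    if not (0.0 < p_used <= 1.0):
        raise ValueError("p_used must be in (0, 1]")
    return float(-np.log(p_used) * abs(z))


def run_ora(query: Iterable[str], db: PathwayDB, alpha: float = 0.05,
            B: int = 2000, seed: int = 0, combined_p: str = "adjusted") -> list:
    """Over-representation analysis of one group's gene-set against every
    pathway. Returns one :class:`OraResult` per pathway, in database order.

    ``combined_p`` selects which p-value feeds the combined score:
    ``'adjusted'`` (BH) or ``'raw'``.
    """
    if combined_p not in ("adjusted", "raw"):
        raise ValueError("combined_p must be 'adjusted' or 'raw'")
    query = frozenset(query)
    dropped = query - db.universe
    if dropped:
        logger.info("run_ora: %d query gene(s) absent from universe dropped", len(dropped))
    query_in = query & db.universe

    names = list(db.pathways)
    ks, ps = [], []
    for name in names:
        k, p = fisher_enrichment(query_in, db.pathways[name], db.universe)
        ks.append(k)
        ps.append(p)
    ps = np.asarray(ps)
    p_adj = bh_adjust(ps)
    z = rank_deviation_z(len(query_in), db, ps, B=B, seed=seed)
    p_for_score = p_adj if combined_p == "adjusted" else ps

    results = []
    for i, name in enumerate(names):
        results.append(OraResult(
            pathway=name, k=int(ks[i]), n_query=len(query_in),
            n_pathway=len(db.pathways[name]), n_universe=len(db.universe),
            p=float(ps[i]), p_adj=float(p_adj[i]), z=float(z[i]),
            combined=combined_score(float(p_for_score[i]), float(z[i])),
        ))
    return results


def volcano(ora_sr: Sequence[OraResult], ora_or: Sequence[OraResult],
            alpha: float = 0.05) -> list:
    """ΔCombined Score table over all pathways appearing in either run.

    Pathways absent from one run contribute combined = 0 (and p_adj = 1) for
    that group. Sign convention: SR-specific enrichment is negative.
    """
    sr = {r.pathway: r for r in ora_sr}
    or_ = {r.pathway: r for r in ora_or}
    rows = []
    for name in dict.fromkeys(list(sr) + list(or_)):
        c_sr = sr[name].combined if name in sr else 0.0
        c_or = or_[name].combined if name in or_ else 0.0
        p_sr = sr[name].p_adj if name in sr else 1.0
        p_or = or_[name].p_adj if name in or_ else 1.0
        sig_sr, sig_or = p_sr < alpha, p_or < alpha
        sig = ("both" if sig_sr and sig_or else
               "SR" if sig_sr else "OR" if sig_or else "neither")
        rows.append(VolcanoRow(
            pathway=name, combined_sr=c_sr, combined_or=c_or,
            delta_combined=c_or - c_sr, min_p_adj=min(p_sr, p_or),
            significant_in=sig,
        ))
    return rows


def ora_to_frame(results: Sequence[OraResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def volcano_to_frame(rows: Sequence[VolcanoRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
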