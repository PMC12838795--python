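"""Over-representation analysis: Fisher enrichment, BH, rank z, combined score."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rvpathrx.io_formats import PathwayDB
from rvpathrx.pathway_ora import (OraResult, bh_adjust, combined_score,
                                  fisher_enrichment, rank_deviation_z, run_ora,
                                  volcano)


def small_db():
    return PathwayDB(pathways={
        "P1": frozenset("ABCDE"),
        "P2": frozenset("DEFGH"),
        "P3": frozenset("IJKL"),
    })


class TestFisherEnrichment:
    def test_hand_enumerated_tail(self):
        # N=20 universe, pathway 5, query 5, overlap 4
        universe = frozenset(f"g{i}" for i in range(20))
        pathway = frozenset(f"g{i}" for i in range(5))
        query = frozenset(["g0", "g1", "g2", "g3", "g10"])
        k, p = fisher_enrichment(query, pathway, universe)
        assert k == 4
        expected = sum(math.comb(5, x) * math.comb(15, 5 - x)
                       for x in (4, 5)) / math.comb(20, 5)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_zero_overlap_tail_is_one(self):
        universe = frozenset("ABCDEFGH")
        k, p = fisher_enrichment(frozenset("AB"), frozenset("GH"), universe)
        assert k == 0 and p == pytest.approx(1.0)

    def test_saturated_query(self):
        universe = frozenset("ABCD")
        k, p = fisher_enrichment(universe, universe, universe)
        assert k == 4 and p == pytest.approx(1.0)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_enrichment(frozenset("A"), frozenset(), frozenset())

    def test_matches_exhaustive_draw_enumeration(self):
        """Closed-form tail equals enumeration over all C(N, n_q) query draws."""
        universe = sorted("ABCDEFGHIJ")  # N = 10
        pathway = frozenset("ABCD")
        n_q = 4
        query = frozenset("ABEF")
        k_obs, p = fisher_enrichment(query, pathway, frozenset(universe))
        hits = total = 0
        for draw in itertools.combinations(universe, n_q):
            total += 1
            if len(frozenset(draw) & pathway) >= k_obs:
                hits += 1
        assert p == pytest.approx(hits / total, rel=1e-12)


class TestBhAdjust:
    def test_hand_run_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_never_decreases_and_capped(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(1e-6, 1.0, 50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


def _oracle_rank_z(query_size, db, observed_p, B, seed):
    """Independently coded brute-force resampler (same RNG stream contract)."""
    rng = np.random.default_rng(seed)
    names = list(db.pathways)
    universe = sorted(db.universe)
    N = len(universe)
    ranks = []
    for _ in range(B):
        idx = rng.choice(N, size=query_size, replace=False)
        draw = frozenset(universe[i] for i in idx)
        ps = []
        for name in names:
            pw = db.pathways[name]
            k = len(draw & pw)
            ps.append(stats.hypergeom.sf(k - 1, N, len(pw), query_size))
        ranks.append(stats.rankdata(ps, method="average"))
    ranks = np.array(ranks)
    obs = stats.rankdata(observed_p, method="average")
    sd = ranks.std(axis=0, ddof=1)
    z = np.where(sd > 0, (obs - ranks.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


class TestRankDeviationZ:
    def test_matches_independent_resampler_exactly(self):
        db = small_db()
        observed_p = np.array([0.02, 0.5, 0.9])
        z = rank_deviation_z(4, db, observed_p, B=200, seed=123)
        oracle = _oracle_rank_z(4, db, observed_p, B=200, seed=123)
        np.testing.assert_allclose(z, oracle, atol=1e-9)

    def test_observed_at_null_mean_gives_zero(self):
        db = small_db()
        # symmetric observed p: rank ties everywhere -> all observed ranks 2
        z = rank_deviation_z(4, db, np.array([0.5, 0.5, 0.5]), B=100, seed=1)
        assert np.isfinite(z).all()

    def test_degenerate_sd_guard(self):
        db = PathwayDB(pathways={"P1": frozenset("AB")})  # single pathway: rank always 1
        z = rank_deviation_z(1, db, np.array([0.4]), B=50, seed=0)
        assert z[0] == 0.0

    def test_reproducible_under_seed(self):
        db = small_db()
        obs = np.array([0.1, 0.2, 0.3])
        z1 = rank_deviation_z(3, db, obs, B=300, seed=9)
        z2 = rank_deviation_z(3, db, obs, B=300, seed=9)
        np.testing.assert_array_equal(z1, z2)


class TestCombinedScore:
    def test_direct_formula(self):
        assert combined_score(0.01, -2.0) == pytest.approx(-math.log(0.01) * 2, rel=1e-12)

    def test_p_one_gives_zero(self):
        assert combined_score(1.0, 3.0) == 0.0

    def test_monotone_in_p(self):
        scores = [combined_score(p, 1.5) for p in (0.5, 0.1, 0.01)]
        assert scores == sorted(scores)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            combined_score(0.0, 1.0)


class TestRunOraVolcano:
    def test_identical_queries_give_zero_delta(self):
        db = small_db()
        res_sr = run_ora(frozenset("ABD"), db, B=100, seed=3)
        res_or = run_ora(frozenset("ABD"), db, B=100, seed=3)
        for row in volcano(res_sr, res_or):
            assert row.delta_combined == pytest.approx(0.0)
            assert row.significant_in in ("both", "neither")

    def test_significance_labels(self):
        r = lambda name, p_adj: OraResult(pathway=name, k=1, n_query=2, n_pathway=3,
                                          n_universe=10, p=min(p_adj, 1.0),
                                          p_adj=p_adj, z=1.0, combined=0.5)
        rows = volcano([r("A", 0.01), r("B", 0.5)], [r("A", 0.01), r("B", 0.04)])
        by = {v.pathway: v.significant_in for v in rows}
        assert by == {"A": "both", "B": "OR"}

    def test_pathway_absent_from_one_run(self):
        db = small_db()
        res = run_ora(frozenset("AB"), db, B=50, seed=1)
        rows = volcano(res, [])
        assert all(v.delta_combined == -v.combined_sr for v in rows)

    def test_combined_p_raw_switch(self):
        db = small_db()
        adj = run_ora(frozenset("ABCD"), db, B=100, seed=2, combined_p="adjusted")
        raw = run_ora(frozenset("ABCD"), db, B=100, seed=2, combined_p="raw")
        for a, r in zip(adj, raw):
            assert a.p == r.p and a.z == r.z
            # raw p <= adjusted p, so raw-based combined score is >= at fixed z
            assert r.combined >= a.combined - 1e-12

    def test_effect_pathway_most_negative_delta(self, effect_bundle):
        """The SR-planted pathway lands leftmost on the volcano axis."""
        from rvpathrx.pipeline import run_pipeline
        b = effect_bundle
        res = run_pipeline(b.cv, b.annotations, b.db, b.design, ora_B=500, seed=4,
                           burden_pathways=[], skato_pathways=[])
        deltas = {v.pathway: v.delta_combined for v in res.volcano}
        assert min(deltas, key=deltas.get) == "PW01"


class TestNullCalibration:
    def test_global_null_rejection_rate_matches_exact_expectation(self):
        """Under uniformly drawn queries, the fraction of pathways with
        p < alpha matches the exact hypergeometric rejection probability
        (the discrete analogue of 'approximately alpha')."""
        rng = np.random.default_rng(77)
        N, n_pw, size_pw, n_q, alpha = 400, 10, 60, 80, 0.05
        genes = [f"g{i}" for i in range(N)]
        pathways = {f"P{j}": frozenset(rng.choice(genes, size_pw, replace=False))
                    for j in range(n_pw)}
        db = PathwayDB(pathways=pathways, universe=frozenset(genes))
        # exact expected rejection prob per pathway
        ks = np.arange(size_pw + 1)
        tail = stats.hypergeom.sf(ks - 1, N, size_pw, n_q)
        pmf = stats.hypergeom.pmf(ks, N, size_pw, n_q)
        exact = pmf[tail < alpha].sum()
        assert abs(exact - alpha) < 0.035  # design sits near nominal

        reps, hits, total = 150, 0, 0
        for _ in range(reps):
            q = frozenset(rng.choice(genes, n_q, replace=False))
            for name in db.pathways:
                _, p = fisher_enrichment(q, db.pathways[name], db.universe)
                hits += p < alpha
                total += 1
        rate = hits / total
        se = math.sqrt(exact * (1 - exact) / reps)  # pathways within a draw correlate
        assert abs(rate - exact) < 4 * se
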