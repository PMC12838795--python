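"""Null model, variant weights, quadratic-form p-values, SKAT-O."""

import math

import numpy as np
import pytest
from scipy import stats

from rvpathrx.skat_o import (DEFAULT_RHO_GRID, NullModel, SeparationError,
                             fit_null_model, quadform_pvalue, run_skato,
                             skato_pathway_test, variant_weights)
from .conftest import make_design


class TestNullModel:
    def test_balanced_intercept_only(self):
        y = np.array([1.0, 0.0] * 25)
        null = fit_null_model(y)
        assert null.coef[0] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(null.mu, 0.5, atol=1e-10)

    def test_coefficient_recovery_within_3se(self):
        """n=500 logistic simulation: IRLS recovers the generating coefficients,
        and agrees with statsmodels GLM as an independent cross-check."""
        rng = np.random.default_rng(14)
        n, beta = 500, np.array([-0.4, 0.8, -0.6])
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
        y = rng.binomial(1, 1 / (1 + np.exp(-X @ beta))).astype(float)
        null = fit_null_model(y, X[:, 1:])
        cov = np.linalg.inv(X.T @ (X * (null.mu * (1 - null.mu))[:, None]))
        se = np.sqrt(np.diag(cov))
        assert (np.abs(null.coef - beta) < 3 * se).all()

        import statsmodels.api as sm
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(null.coef, ref.params, atol=1e-6)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        y = np.array([1.0] * 10 + [0.0] * 12)
        cov = rng.normal(size=(22, 2))
        perm = rng.permutation(22)
        a = fit_null_model(y, cov)
        b = fit_null_model(y[perm], cov[perm])
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-9)

    def test_separation_detected(self):
        y = np.array([1.0] * 5 + [0.0] * 5)
        sep = y.copy()  # covariate identical to outcome
        with pytest.raises(SeparationError, match="covariate"):
            fit_null_model(y, sep.reshape(-1, 1))

    def test_one_group_rejected(self):
        with pytest.raises(ValueError):
            fit_null_model(np.ones(10))

    def test_rank_deficiency_rejected(self):
        y = np.array([1.0, 0.0] * 5)
        cov = np.ones((10, 1))  # duplicates the intercept
        with pytest.raises(ValueError, match="rank"):
            fit_null_model(y, cov)


class TestVariantWeights:
    def test_closed_form_at_half(self):
        assert variant_weights([0.5])[0] == pytest.approx(25 * 0.5 ** 24, rel=1e-12)

    def test_monotone_decreasing(self):
        w = variant_weights([0.01, 0.04, 0.2, 0.5])
        assert (np.diff(w) < 0).all()

    def test_flat_weights(self):
        np.testing.assert_allclose(variant_weights([0.1, 0.3], 1.0, 1.0), 1.0)

    def test_zero_maf_rejected(self):
        with pytest.raises(ValueError):
            variant_weights([0.0, 0.1])


class TestQuadformPvalue:
    def test_single_chi_square(self):
        assert quadform_pvalue(3.841, [1.0]) == pytest.approx(
            stats.chi2.sf(3.841, 1), rel=1e-9)

    def test_equal_eigenvalues_reduce_to_chi2_df3(self):
        p, method = quadform_pvalue(7.815, [1.0, 1.0, 1.0], return_method=True)
        assert p == pytest.approx(stats.chi2.sf(7.815, 3), abs=1e-6)
        assert method == "exact"
        # a nearly-equal mixture still goes through the inversion path
        p2, method2 = quadform_pvalue(7.815, [1.0, 1.0, 0.98], return_method=True)
        assert method2 == "inversion"
        assert p2 == pytest.approx(p, abs=0.01)

    def test_scale_invariance(self):
        lam = np.array([2.0, 1.0, 0.3])
        assert quadform_pvalue(4.0, lam) == pytest.approx(
            quadform_pvalue(40.0, 10 * lam), abs=1e-7)

    def test_monte_carlo_agreement_small(self):
        rng = np.random.default_rng(21)
        lam = np.array([1.5, 0.8, 0.3, 0.1])
        draws = rng.chisquare(1, size=(200_000, 4)) @ lam
        for q in (1.0, 3.0, 8.0):
            mc = (draws >= q).mean()
            se = math.sqrt(mc * (1 - mc) / draws.shape[0])
            assert abs(quadform_pvalue(q, lam) - mc) < 4 * se

    def test_all_zero_eigenvalues_error(self):
        with pytest.raises(ValueError):
            quadform_pvalue(1.0, [0.0, 0.0])


def _toy_data(seed=5, n=60, m=6, maf=0.2):
    rng = np.random.default_rng(seed)
    y = np.array([1.0] * (n // 2) + [0.0] * (n - n // 2))
    G = rng.binomial(2, maf, size=(n, m)).astype(float)
    return y, G


class TestSkatoPathwayTest:
    def test_single_variant_degeneracy(self):
        y, G = _toy_data(m=1)
        null = fit_null_model(y)
        res = skato_pathway_test(G, null)
        assert len(set(np.round(res.p_rho, 12))) == 1
        assert res.p_opt == pytest.approx(res.p_rho[0])

    def test_rho_one_equals_weighted_burden_score_test(self):
        """Direct reduction identity: at rho=1 the statistic is the squared
        weighted burden score with a single-eigenvalue chi-square null."""
        y, G = _toy_data(seed=6)
        null = fit_null_model(y)
        w = variant_weights(np.minimum(G.mean(0) / 2, 1 - G.mean(0) / 2))
        res = skato_pathway_test(G, null, weights=w, rho_grid=(1.0,))
        # independently coded burden score test
        Z = G * w
        burden = Z.sum(axis=1)
        score = burden @ null.residuals
        V = null.variance
        X = null.X
        VX = X * V[:, None]
        proj = burden - X @ np.linalg.solve(X.T @ VX, VX.T @ burden)
        var = float(proj @ (V * proj))
        p_burden = stats.chi2.sf(score ** 2 / var, df=1)
        assert res.p_opt == pytest.approx(p_burden, abs=1e-8)

    def test_q_is_linear_in_rho(self):
        y, G = _toy_data(seed=7)
        null = fit_null_model(y)
        w = np.ones(G.shape[1])
        Z = G * w
        S = Z.T @ null.residuals
        q0, q1 = np.sum(S ** 2), np.sum(S) ** 2
        for rho in (0.0, 0.3, 0.7, 1.0):
            q_rho = (1 - rho) * q0 + rho * q1
            assert q_rho == pytest.approx(q0 + rho * (q1 - q0), rel=1e-12)

    def test_p_opt_within_min_p_and_bonferroni(self):
        for seed in range(6):
            y, G = _toy_data(seed=seed)
            null = fit_null_model(y)
            res = skato_pathway_test(G, null)
            pmin = min(res.p_rho)
            assert pmin - 1e-12 <= res.p_opt <= min(1.0, len(res.p_rho) * pmin) + 1e-12

    def test_missing_imputation_never_changes_m(self):
        y, G = _toy_data(seed=8)
        G[2, 0] = np.nan
        G[5, 3] = np.nan
        null = fit_null_model(y)
        res_mean = skato_pathway_test(G, null, missing="mean")
        res_zero = skato_pathway_test(G, null, missing="zero")
        assert res_mean.m == res_zero.m == G.shape[1]

    def test_empty_matrix(self):
        y, _ = _toy_data()
        null = fit_null_model(y)
        res = skato_pathway_test(np.empty((60, 0)), null, pathway="empty")
        assert res.m == 0 and math.isnan(res.p_opt)

    def test_permutation_oracle_agreement_small(self):
        """Smaller-scale version of the permutation comparison: analytic p_opt
        tracks the rank-based permutation oracle to ~the lattice granularity."""
        rng = np.random.default_rng(12)
        n, m, R = 60, 4, 20_000
        y = np.array([1.0] * 30 + [0.0] * 30)
        G = rng.binomial(2, 0.25, size=(n, m)).astype(float)
        null = fit_null_model(y)
        w = np.ones(m)
        res = skato_pathway_test(G, null, weights=w)
        Z = G * w
        resid = y - y.mean()
        perms = np.array([rng.permutation(resid) for _ in range(R)])
        S = perms @ Z
        rhos = np.array(DEFAULT_RHO_GRID)
        Qp = ((1 - rhos)[None, :] * (S ** 2).sum(axis=1)[:, None]
              + rhos[None, :] * (S.sum(axis=1) ** 2)[:, None])
        S0 = Z.T @ resid
        Q0 = (1 - rhos) * np.sum(S0 ** 2) + rhos * np.sum(S0) ** 2
        minp_perm = np.ones(R)
        minp_obs = 1.0
        for k in range(len(rhos)):
            col = Qp[:, k]
            order = np.argsort(col)
            ranks = np.empty(R)
            ranks[order] = np.arange(R)
            minp_perm = np.minimum(minp_perm, (R - ranks) / R)
            minp_obs = min(minp_obs, (col >= Q0[k]).mean())
        p_perm = (minp_perm <= minp_obs).mean()
        assert abs(res.p_opt - p_perm) < 0.06


class TestRunSkato:
    def _bundle_pieces(self, bundle):
        from rvpathrx.variant_classification import (build_rare_damaging_set,
                                                     classify_annotations)
        rd = build_rare_damaging_set(classify_annotations(bundle.annotations),
                                     bundle.cv)
        return rd

    def test_single_pathway_q_equals_p(self, null_bundle):
        rd = self._bundle_pieces(null_bundle)
        res = run_skato(["PW01"], null_bundle.db, rd, null_bundle.cv,
                        null_bundle.design)
        assert res[0].q == pytest.approx(res[0].p_opt)

    def test_bh_applied_across_pathways(self, null_bundle):
        from rvpathrx.pathway_ora import bh_adjust
        rd = self._bundle_pieces(null_bundle)
        names = list(null_bundle.db.pathways)
        res = run_skato(names, null_bundle.db, rd, null_bundle.cv,
                        null_bundle.design)
        tested = [r for r in res if np.isfinite(r.p_opt)]
        expected = bh_adjust([r.p_opt for r in tested])
        np.testing.assert_allclose([r.q for r in tested], expected, rtol=1e-12)

    def test_pathway_without_variants_reported_nan(self, null_bundle):
        from rvpathrx.io_formats import PathwayDB
        db = PathwayDB(pathways=dict(null_bundle.db.pathways,
                                     EMPTY=frozenset({"NO_SUCH_GENE"})))
        rd = self._bundle_pieces(null_bundle)
        res = run_skato(["EMPTY"], db, rd, null_bundle.cv, null_bundle.design)
        assert res[0].m == 0 and math.isnan(res[0].p_opt)

    def test_opposing_effects_favor_kernel_over_burden(self):
        """A pathway whose variants push in opposite directions across groups
        is detected more often by the optimal kernel test than by carrier
        counting — the rationale for running both."""
        from rvpathrx.carrier_burden import run_burden
        from rvpathrx.synthetic_cohort import (EffectSpec, SyntheticConfig,
                                               simulate_cohort)
        from rvpathrx.variant_classification import (build_rare_damaging_set,
                                                     classify_annotations)
        rng = np.random.default_rng(55)
        alpha, reps = 0.05, 60
        skato_hits = burden_hits = 0
        for _ in range(reps):
            cfg = SyntheticConfig(
                n_pathways=1, n_background_genes=0,
                qualifying_variants_per_pathway=8,
                benign_variants_per_pathway=0, extra_transcript_fraction=0.0,
                effects=(EffectSpec("PW01", 0.75, 0.15, direction_mix=0.5),),
                seed=int(rng.integers(2 ** 31)))
            b = simulate_cohort(cfg)
            rd = build_rare_damaging_set(classify_annotations(b.annotations), b.cv)
            sk = run_skato(["PW01"], b.db, rd, b.cv, b.design)
            bu = run_burden(["PW01"], b.db, rd, b.cv, b.design)
            skato_hits += np.isfinite(sk[0].p_opt) and sk[0].p_opt < alpha
            burden_hits += bu[0].p < alpha
        assert skato_hits > burden_hits
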