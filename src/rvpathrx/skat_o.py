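"""Optimal sequence kernel association test (SKAT-O) per pathway gene-set.

The test statistic family interpolates between a variance-component (SKAT)
statistic and a weighted burden statistic,

    Q_rho = (1 − rho) · Σ_j (w_j S_j)² + rho · (Σ_j w_j S_j)² ,

where S_j = Σ_i G_ij (y_i − μ_i) is the score of variant j under a
covariate-adjusted logistic null model. rho = 0 recovers SKAT (sensitive to
bidirectional effects), rho = 1 the burden test (unidirectional effects).
Each Q_rho follows a mixture of 1-df chi-squares under the null, with mixture
weights given by the eigenvalues of the projected, weighted kernel; the tail
probability is computed by characteristic-function inversion (Imhof's
integral) with a moment-matching fallback. The final p-value combines the
grid's minimum p through the one-dimensional integral of the min-p statistic's
null distribution, falling back to the Bonferroni envelope |grid|·min(p) when
the integration fails.

Variant weights default to the Beta(1, 25) density evaluated at the cohort
minor allele frequency, strongly up-weighting rarer variants. Missing dosages
are mean-imputed per variant (twice the cohort MAF) by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .io_formats import CohortDesign, CohortVariants
from .pathway_ora import bh_adjust
from .variant_classification import ClassifiedVariant

__all__ = [
    "DEFAULT_RHO_GRID", "SeparationError", "NullModel", "SkatoResult",
    "fit_null_model", "variant_weights", "quadform_pvalue",
    "skato_pathway_test", "run_skato", "skato_to_frame",
]

logger = logging.getLogger(__name__)

#: Conventional rho grid for the optimal test.
DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


class SeparationError(RuntimeError):
    """Raised when the logistic null model separates (fitted probabilities at
    0 or 1); usually a covariate perfectly predicts the response."""


@dataclass
class NullModel:
    """Covariate-adjusted logistic null model for a binary phenotype.

    ``X`` is the design matrix including the leading intercept column;
    ``variance`` holds the per-sample binomial variances μ(1−μ).
    """

    coef: np.ndarray
    mu: np.ndarray
    residuals: np.ndarray
    variance: np.ndarray
    X: np.ndarray
    n_iter: int

    @property
    def n(self) -> int:
        return len(self.mu)


def fit_null_model(y: np.ndarray, covariates: Optional[np.ndarray] = None,
                   tol: float = 1e-8, max_iter: int = 50) -> NullModel:
    """Fit the logistic null model by iteratively reweighted least squares.

    Convergence is declared when the score norm ||X'(y − μ)|| drops below
    ``tol``. Raises :class:`SeparationError` when any fitted probability comes
    within 1e-10 of 0 or 1, which advises reviewing the covariates.
    """
    sep_eps = 1e-7
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1 (OR=0, SR=1)")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both phenotype groups must be non-empty")
    n = len(y)
    if covariates is None:
        X = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        X = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient after adding intercept")

    beta = np.zeros(X.shape[1])
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        if np.any(mu < sep_eps) or np.any(mu > 1 - sep_eps):
            raise SeparationError(
                "logistic null model separated (fitted probability at 0/1); "
                "review the covariates"
            )
        score = X.T @ (y - mu)
        if np.linalg.norm(score) < tol:
            w = mu * (1 - mu)
            return NullModel(coef=beta, mu=mu, residuals=y - mu, variance=w,
                             X=X, n_iter=it)
        w = mu * (1 - mu)
        xtwx = X.T @ (X * w[:, None])
        beta = beta + np.linalg.solve(xtwx, score)
    raise RuntimeError(f"IRLS did not converge in {max_iter} iterations")


def variant_weights(mafs: Sequence[float], beta_a: float = 1.0,
                    beta_b: float = 25.0) -> np.ndarray:
    """Beta-density variant weights w_j = Beta(maf_j; a, b).

    With the default Beta(1, 25) the weight decreases monotonically in MAF on
    (0, 0.5]; ``beta_a = beta_b = 1`` gives the unweighted test. MAFs must lie
    in (0, 0.5]; uncarried variants (MAF 0) must be dropped by the caller.
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]; drop uncarried variants first")
    return stats.beta.pdf(mafs, beta_a, beta_b)


# ---------------------------------------------------------------------------
# Quadratic-form tail probabilities
# ---------------------------------------------------------------------------

def _liu_params(lam: np.ndarray):
    """Moment parameters of the skewness/kurtosis-matched chi-square surrogate."""
    c1, c2, c3, c4 = (np.sum(lam ** k) for k in (1, 2, 3, 4))
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    return c1, math.sqrt(2 * c2), df, delta


def _liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Skewness-matched (non-central) chi-square approximation of the tail."""
    mu_q, sigma_q, df, delta = _liu_params(lam)
    t = (q - mu_q) / sigma_q
    x = t * math.sqrt(2 * (df + 2 * delta)) + df + delta
    return float(stats.ncx2.sf(x, df, delta)) if delta > 0 else float(stats.chi2.sf(x, df))


def _liu_quantile(p_tail: float, lam: np.ndarray) -> float:
    """Approximate quantile q with P[Σ λ χ² > q] = p_tail (central surrogate)."""
    mu_q, sigma_q, df, _ = _liu_params(lam)
    q_org = stats.chi2.isf(p_tail, df)
    return float((q_org - df) / math.sqrt(2 * df) * sigma_q + mu_q)


def _imhof_tail_vector(qs: np.ndarray, lam: np.ndarray, tol: float = 1e-6):
    """Imhof characteristic-function inversion for thresholds sharing one
    mixture: P[Σ λ_k χ²_{1,k} ≥ q] for each q.

    The inversion integral is evaluated on one shared trapezoid grid. The
    upper limit comes from the integrand's decay envelope combined with an
    integration-by-parts bound on the oscillatory tail; the grid density
    tracks the fastest oscillation (largest threshold). Returns
    ``(p_values, inverted)`` where ``inverted`` flags thresholds the grid
    could certify — the caller applies the moment-matching fallback to the
    rest. Near-zero thresholds (tail probability ≈ 1) tolerate the floored
    phase slope; their error stays within the envelope bound.
    """
    qs = np.asarray(qs, dtype=float)
    scale = float(lam.max())
    lt = lam / scale
    qt = qs / scale

    # phase slope for large u approaches q/2; floor it so U stays finite for
    # near-zero thresholds
    slope = 0.5 * max(min(qt[qt > 0], default=1.0), 0.05 * lt.sum())

    def envelope(u):
        return 1.0 / (u * math.exp(0.25 * np.sum(np.log1p((lt * u) ** 2))))

    U, ok = 16.0, False
    while U <= 2 ** 22:
        if 2.0 * envelope(U) / slope < tol * math.pi:
            ok = True
            break
        U *= 2.0
    if not ok:
        return np.full(qs.shape, np.nan), np.zeros(qs.shape, dtype=bool)

    qmax = max(float(qt.max()), 1.0)
    # ~40 points per oscillation period of the fastest phase, floor 8192
    n_pts = int(min(2 ** 17, max(8192, 40.0 * (qmax + lt.sum()) * U / (2 * math.pi))))
    u = np.linspace(0.0, U, n_pts + 1)[1:]
    atan_sum = 0.5 * np.arctan(np.outer(u, lt)).sum(axis=1)
    log_rho = 0.25 * np.log1p(np.outer(u, lt) ** 2).sum(axis=1)
    base = np.exp(-log_rho) / u                       # shared envelope term
    theta = atan_sum[None, :] - 0.5 * np.outer(qt, u)
    vals = np.sin(theta) * base[None, :]
    # trapezoid with the analytic u -> 0 limit 0.5 (sum(lam) - q)
    f0 = 0.5 * (lt.sum() - qt)
    h = U / n_pts
    integral = h * (0.5 * f0 + vals[:, :-1].sum(axis=1) + 0.5 * vals[:, -1])
    p = 0.5 + integral / math.pi
    inverted = np.isfinite(p) & (p > -1e-4) & (p < 1 + 1e-4)
    return np.clip(p, 1e-300, 1.0), inverted


def quadform_pvalue(q: float, eigenvalues: Sequence[float], acc: float = 1e-6,
                    return_method: bool = False):
    """Tail probability P[Σ_k λ_k χ²_{1,k} ≥ q] of a weighted chi-square mixture.

    Characteristic-function inversion (Imhof's integral, absolute error target
    ``acc``) with a moment-matching chi-square fallback when the inversion
    reports trouble. With ``return_method=True`` returns ``(p, method)`` where
    method is ``'inversion'`` or ``'moment'``.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("all eigenvalues are zero (or negative)")
    q = float(q)

    if np.allclose(lam, lam[0], rtol=1e-12):  # equal weights: exact chi-square
        p = float(stats.chi2.sf(q / lam[0], df=lam.size))
        return (p, "exact") if return_method else p

    ps, inverted = _imhof_tail_vector(np.array([q]), lam, tol=acc)
    if inverted[0]:
        p, method = float(ps[0]), "inversion"
    else:
        p, method = _liu_pvalue(q, lam), "moment"
    p = min(max(p, 1e-300), 1.0)
    return (p, method) if return_method else p


# ---------------------------------------------------------------------------
# SKAT-O
# ---------------------------------------------------------------------------

@dataclass
class SkatoResult:
    """Per-pathway SKAT-O outcome; ``q`` is the BH-adjusted p across pathways."""

    pathway: str
    m: int
    rho_grid: tuple
    p_rho: tuple
    p_opt: float
    q: float = float("nan")
    significant: bool = False
    note: str = ""

    def __post_init__(self):
        finite = [p for p in self.p_rho if np.isfinite(p)]
        if finite and np.isfinite(self.p_opt):
            pmin = min(finite)
            bonf = min(1.0, len(self.p_rho) * pmin)
            if not (pmin - 1e-9 <= self.p_opt <= bonf + 1e-9):
                raise ValueError("p_opt outside [min p_rho, Bonferroni envelope]")


def _rho_sqrt_correlation(rho: float, m: int) -> np.ndarray:
    """Matrix square root of R_rho = (1−rho) I + rho 11' (compound symmetry)."""
    a = math.sqrt(1.0 - rho)
    b = (math.sqrt(1.0 - rho + m * rho) - a) / m
    return a * np.eye(m) + b * np.ones((m, m))


def _positive_eigvals(mat: np.ndarray) -> np.ndarray:
    lam = np.linalg.eigvalsh((mat + mat.T) / 2.0)
    cutoff = max(lam.max(), 0.0) * 1e-10
    return lam[lam > cutoff]


def skato_pathway_test(G: np.ndarray, null: NullModel,
                       weights: Optional[np.ndarray] = None,
                       rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
                       missing: str = "mean", pathway: str = "") -> SkatoResult:
    """SKAT-O for one pathway's dosage matrix.

    Parameters
    ----------
    G : array, shape (n_samples, m_variants)
        Alt-allele dosages 0/1/2 with missing entries as NaN; columns are the
        pathway's qualifying variants. Missing dosages are imputed per variant
        by the non-missing mean (``missing='mean'``, the default, equal to
        twice the cohort MAF) or by zero (``missing='zero'``); imputation never
        changes m.
    null : NullModel
        Fitted logistic null model (same sample order as G's rows).
    weights : array of length m, optional
        Variant weights; computed from folded cohort MAFs via Beta(1, 25)
        when omitted.
    rho_grid : sequence of rho values in [0, 1].
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != null.n:
        raise ValueError("G must be (n_samples, m) aligned with the null model")
    rho_grid = tuple(float(r) for r in rho_grid)
    if any(r < 0 or r > 1 for r in rho_grid):
        raise ValueError("rho values must lie in [0, 1]")
    n, m = G.shape
    if m == 0:
        return SkatoResult(pathway=pathway, m=0, rho_grid=rho_grid,
                           p_rho=(), p_opt=float("nan"), note="no qualifying variants")
    if missing not in ("mean", "zero"):
        raise ValueError("missing must be 'mean' or 'zero'")

    mask = np.isnan(G)
    if mask.any():
        col_mean = np.where(np.all(mask, axis=0), 0.0,
                            np.nanmean(np.where(mask, np.nan, G), axis=0))
        fill = col_mean if missing == "mean" else np.zeros(m)
        G = np.where(mask, fill[None, :], G)

    if weights is None:
        af = G.mean(axis=0) / 2.0
        maf = np.minimum(af, 1.0 - af)
        if np.any(maf <= 0):
            raise ValueError("uncarried variant (MAF 0) in G; drop it before testing")
        weights = variant_weights(maf)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (m,):
        raise ValueError("weights length must equal the number of variants")

    Z = G * weights[None, :]
    S = Z.T @ null.residuals
    Q = np.array([(1 - r) * np.sum(S ** 2) + r * np.sum(S) ** 2 for r in rho_grid])

    # B'B equals the kernel projected through the null model: Z' P0 Z with
    # P0 = V − V X (X'VX)^{-1} X' V.
    V = null.variance
    X = null.X
    VX = X * V[:, None]
    xtvx = X.T @ VX
    coefs = np.linalg.solve(xtvx, VX.T @ Z)
    B = np.sqrt(V)[:, None] * (Z - X @ coefs)
    A = B.T @ B
    if not np.any(np.diag(A) > 0):
        raise np.linalg.LinAlgError("singular null variance: projected kernel is zero")

    lam_by_rho, p_rho = [], []
    for r, q_obs in zip(rho_grid, Q):
        if r >= 1.0:
            lam = np.array([float(np.ones(m) @ A @ np.ones(m))])
        else:
            rh = _rho_sqrt_correlation(r, m)
            lam = _positive_eigvals(rh @ A @ rh)
        lam_by_rho.append(lam)
        p_rho.append(quadform_pvalue(q_obs, lam))
    p_rho = tuple(p_rho)
    pmin = min(p_rho)

    if m == 1 or len(rho_grid) == 1:
        # all Q_rho proportional: the common per-rho p IS the optimal p
        return SkatoResult(pathway=pathway, m=m, rho_grid=rho_grid,
                           p_rho=p_rho, p_opt=pmin)

    p_opt, note = _min_p_combination(pmin, lam_by_rho, rho_grid, B)
    bonf = min(1.0, len(rho_grid) * pmin)
    p_opt = min(max(p_opt, pmin), bonf)
    return SkatoResult(pathway=pathway, m=m, rho_grid=rho_grid, p_rho=p_rho,
                       p_opt=p_opt, note=note)


# 64-point Gauss–Legendre rule for the outer min-p integral, mapped to the
# half-normal representation t = sqrt(x) of the 1-df burden chi-square
# (upper limit x = 42 leaves < 1e-10 of mass untouched).
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)
_T_UPPER = math.sqrt(42.0)
_T_NODES = 0.5 * _T_UPPER * (_GL_NODES + 1.0)
_T_WEIGHTS = 0.5 * _T_UPPER * _GL_WEIGHTS


def _min_p_combination(pmin: float, lam_by_rho: list, rho_grid: tuple,
                       B: np.ndarray):
    """One-dimensional integration of the min-p statistic's null distribution.

    The weighted projected kernel ``B`` is decomposed along the common
    (burden) direction; the optimal-test p-value is one minus the expectation,
    over the burden component's 1-df chi-square, of the conditional
    probability that no Q_rho exceeds its min-p quantile. Returns
    ``(p_opt, note)``; the note records a fallback to the Bonferroni envelope
    |grid|·pmin when the integration fails.
    """
    n_grid = len(rho_grid)
    bonf = min(1.0, n_grid * pmin)
    # rho = 1 enters the conditional threshold with an 0.999 guard so the
    # (1 - rho) denominator stays positive
    rho_c = np.minimum(np.asarray(rho_grid, dtype=float), 0.999)
    m = B.shape[1]

    z_mean = B.mean(axis=1)
    denom = float(z_mean @ z_mean)
    if denom <= 0:
        return bonf, "bonferroni (degenerate common direction)"
    cof = (z_mean @ B) / denom
    B1 = np.outer(z_mean, cof)
    B2 = B - B1
    A2 = B2.T @ B2
    lam = _positive_eigvals(A2)
    if lam.size == 0:
        return bonf, "bonferroni (rank-1 kernel)"

    mu_q = float(lam.sum())
    var_remain = 4.0 * float(np.sum((B1.T @ B1) * A2))
    var_q = 2.0 * float(np.sum(lam ** 2)) + var_remain
    sd_ratio = math.sqrt(max(var_q - var_remain, 0.0) / var_q) if var_q > 0 else 1.0
    tau = (m * m * rho_c + (1.0 - rho_c) * np.sum(cof ** 2)) * denom
    q_min = np.array([_liu_quantile(pmin, l) for l in lam_by_rho])

    x_nodes = _T_NODES ** 2
    t_min = ((q_min[:, None] - np.outer(tau, x_nodes)) / (1.0 - rho_c)[:, None]).min(axis=0)
    t_adj = (t_min - mu_q) * sd_ratio + mu_q
    cdf = np.zeros(len(x_nodes))
    huge = t_min > mu_q * 1e4
    cdf[huge] = 1.0
    compute = (t_adj > 0) & ~huge
    if compute.any():
        ps, inverted = _imhof_tail_vector(t_adj[compute], lam)
        if not inverted.all():
            fallback = np.where(~inverted)[0]
            vals = t_adj[compute]
            ps[fallback] = [_liu_pvalue(float(vals[i]), lam) for i in fallback]
        cdf[compute] = 1.0 - ps
    dens = math.sqrt(2.0 / math.pi) * np.exp(-0.5 * _T_NODES ** 2)
    integral = float(np.sum(_T_WEIGHTS * cdf * dens))
    p_opt = 1.0 - integral
    if not np.isfinite(p_opt) or p_opt <= 0.0 or p_opt > 1.0 + 1e-9:
        logger.warning("min-p integration failed (p=%s); using Bonferroni envelope", p_opt)
        return bonf, "bonferroni (integration failure)"
    return min(p_opt, 1.0), ""


def skato_to_frame(results: Sequence[SkatoResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"pathway": r.pathway, "m": r.m, "p_opt": r.p_opt, "q": r.q,
               "significant": r.significant, "note": r.note}
        for rho, p in zip(r.rho_grid, r.p_rho):
            row[f"p_rho_{rho:g}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def run_skato(pathways: Sequence[str], db, rare_damaging: Iterable[ClassifiedVariant],
              cv: CohortVariants, design: CohortDesign,
              rho_grid: Sequence[float] = DEFAULT_RHO_GRID, fdr: float = 0.05,
              missing: str = "mean") -> list:
    """SKAT-O over a list of pathways with BH FDR across them.

    Qualifying variants for a pathway are the union over its genes of the
    carried rare damaging variants (a variant in two pathway genes enters once
    per pathway). Cohort MAFs drive the Beta(1, 25) weights, computed on
    non-missing calls after QC; uncarried variants are dropped (logged).
    Pathways with no qualifying variants get ``p_opt = NaN`` (reported '.').
    """
    unknown = [p for p in pathways if p not in db]
    if unknown:
        raise KeyError(f"unknown pathway name(s): {unknown}")
    design = design.aligned_to(cv.samples)
    null = fit_null_model(design.y, design.covariates())

    codes = cv.gt_codes().astype(float)
    codes[codes < 0] = np.nan
    key_to_row = {key: i for i, key in enumerate(cv.variant_keys())}
    rare_damaging = list(rare_damaging)

    results = []
    for name in pathways:
        genes = db[name]
        keys = list(dict.fromkeys(v.key for v in rare_damaging if v.gene in genes))
        rows = [key_to_row[k] for k in keys if k in key_to_row]
        if not rows:
            results.append(SkatoResult(pathway=name, m=0, rho_grid=tuple(rho_grid),
                                       p_rho=(), p_opt=float("nan"),
                                       note="no qualifying variants"))
            continue
        G = codes[rows, :].T  # n_samples × m
        af = np.nanmean(G, axis=0) / 2.0
        maf = np.minimum(af, 1.0 - af)
        carried = maf > 0
        if not carried.all():
            logger.info("skato[%s]: dropping %d uncarried variant(s)",
                        name, int((~carried).sum()))
            G, maf = G[:, carried], maf[carried]
        if G.shape[1] == 0:
            results.append(SkatoResult(pathway=name, m=0, rho_grid=tuple(rho_grid),
                                       p_rho=(), p_opt=float("nan"),
                                       note="no carried variants"))
            continue
        w = variant_weights(maf)
        results.append(skato_pathway_test(G, null, weights=w, rho_grid=rho_grid,
                                          missing=missing, pathway=name))

    tested = [r for r in results if np.isfinite(r.p_opt)]
    if tested:
        qs = bh_adjust([r.p_opt for r in tested])
        for r, q in zip(tested, qs):
            r.q = float(q)
            r.significant = bool(q < fdr)
    return results
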