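"""Genomic prediction engines.

* GBLUP: single-random-effect mixed model ``y = Xb + Zg + e`` with
  ``g ~ N(0, G sigma_g^2)``. Variance components are estimated by exact
  REML via eigen-rotation and 1-D optimisation of the variance ratio
  ``delta = sigma_e^2 / sigma_g^2`` on the profile restricted likelihood.
* BayesB: spike-and-slab marker regression ``y = Xb + Mu + e`` fitted by a
  Gibbs sampler (numba-compiled core) — each SNP effect is null with prior
  probability ``pi``, otherwise normal with a locus-specific variance under
  a scaled-inverse-chi-square prior.

Heritability is always ``h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from numba import njit
from scipy import optimize

from .structure import GRM

__all__ = [
    "VarianceComponents",
    "GBLUPModel",
    "BayesBResult",
    "RemlFit",
    "reml_single_random",
    "gblup_reml",
    "gblup_predict",
    "bayesb_gibbs",
    "heritability",
    "CHAIN_PROFILES",
]

#: chain-length presets: "fast" for tests/smoke runs, "paper" for the
#: full-length configuration (100k iterations, 3k burn-in).
CHAIN_PROFILES = {
    "fast": {"n_iter": 5000, "burn_in": 500},
    "paper": {"n_iter": 100_000, "burn_in": 3000},
}


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    method: str  # "GBLUP-REML" or "BayesB-MCMC"
    se_sigma_g2: Optional[float] = None
    se_sigma_e2: Optional[float] = None
    boundary: bool = False

    @property
    def sigma_p2(self) -> float:
        return self.sigma_g2 + self.sigma_e2

    @property
    def h2(self) -> float:
        return heritability(self.sigma_g2, self.sigma_e2)[1]


def heritability(sigma_g2: float, sigma_e2: float) -> Tuple[float, float]:
    """Total phenotypic variance and narrow-sense heritability.

    ``sigma_P^2 = sigma_g^2 + sigma_e^2``; ``h^2 = sigma_g^2 / sigma_P^2``.
    """
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    sigma_p2 = sigma_g2 + sigma_e2
    if sigma_p2 == 0:
        raise ValueError("both variance components are zero; h2 undefined")
    return sigma_p2, sigma_g2 / sigma_p2


@dataclass
class RemlFit:
    """REML solution plus the cached spectral decomposition of G."""

    sigma_g2: float
    sigma_e2: float
    loglik: float
    boundary: bool
    eigvals: np.ndarray  # eigenvalues of G (ascending, as from eigh)
    eigvecs: np.ndarray  # corresponding eigenvectors
    beta: np.ndarray
    n_iter: int
    ll_trace: list = field(default_factory=list)

    @property
    def h2(self) -> float:
        return heritability(self.sigma_g2, self.sigma_e2)[1]


@dataclass
class GBLUPModel:
    y: np.ndarray
    X: np.ndarray
    grm: GRM
    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    gebv: np.ndarray
    train_idx: np.ndarray  # rows of G whose phenotype informed the fit


class RemlConvergenceError(RuntimeError):
    def __init__(self, message: str, trace):
        super().__init__(message)
        self.ll_trace = trace


def _restricted_loglik(log_delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    """EMMA-style restricted log-likelihood profiled over sigma_g^2, as a
    function of delta = sigma_e^2 / sigma_g^2 (up to an additive constant)."""
    delta = np.exp(log_delta)
    denom = xi + delta
    q = len(xi)
    s = float(np.sum(eta2 / denom))
    return 0.5 * (q * (np.log(q / (2 * np.pi)) - 1 - np.log(s)) - float(np.sum(np.log(denom))))


def reml_single_random(
    y: np.ndarray,
    X: np.ndarray,
    grm: GRM,
    tol: float = 1e-8,
    max_iter: int = 200,
    bounds: Tuple[float, float] = (-12.0, 12.0),
    n_grid: int = 64,
) -> RemlFit:
    """Exact REML for one random effect by eigen-rotation.

    The restricted likelihood is profiled down to the scalar variance
    ratio, scanned on a log grid and polished with bounded Brent search.
    A boundary flag (not an error) marks estimates pinned at
    ``sigma_g^2 -> 0`` or ``sigma_e^2 -> 0``.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = len(y)
    p = np.linalg.matrix_rank(X)
    if n <= p:
        raise ValueError("need n > rank(X)")
    if grm.n != n:
        raise ValueError("GRM dimension mismatch")

    d, U = np.linalg.eigh(grm.matrix)

    # eigen of S G S restricted to the n - p dimensional residual space
    Q, _ = np.linalg.qr(X)
    SGS = grm.matrix - Q @ (Q.T @ grm.matrix)
    SGS = SGS - (SGS @ Q) @ Q.T
    SGS = (SGS + SGS.T) / 2.0
    xi_all, V_all = np.linalg.eigh(SGS)
    xi = np.clip(xi_all[p:], 0.0, None)  # drop the p structural zeros
    Vs = V_all[:, p:]
    eta2 = (Vs.T @ y) ** 2

    lo, hi = bounds
    grid = np.linspace(lo, hi, n_grid)
    lls = [_restricted_loglik(g, xi, eta2) for g in grid]
    best = int(np.argmax(lls))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_restricted_loglik(t, xi, eta2),
        bounds=(a, b),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    log_delta = float(res.x)
    ll = -float(res.fun)
    delta = np.exp(log_delta)
    q = n - p
    sigma_g2 = float(np.sum(eta2 / (xi + delta)) / q)
    sigma_e2 = delta * sigma_g2
    boundary = log_delta > hi - 0.5 or log_delta < lo + 0.5

    # GLS fixed effects at the REML solution
    w = 1.0 / (sigma_g2 * d + sigma_e2)
    Xs = U.T @ X
    ys = U.T @ y
    XtWX = Xs.T @ (w[:, None] * Xs)
    XtWy = Xs.T @ (w * ys)
    beta = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]

    return RemlFit(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        loglik=ll,
        boundary=boundary,
        eigvals=d,
        eigvecs=U,
        beta=beta,
        n_iter=int(res.nfev) if hasattr(res, "nfev") else max_iter,
        ll_trace=list(zip(grid.tolist(), lls)),
    )


def _reml_se(fit: RemlFit, X: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Standard errors from the numerical Hessian of the restricted
    log-likelihood in (sigma_g^2, sigma_e^2)."""
    d, U = fit.eigvals, fit.eigvecs
    ys = U.T @ y
    Xs = U.T @ X

    def nll(theta):
        sg, se = np.exp(theta)
        v = sg * d + se
        if (v <= 0).any():
            return np.inf
        w = 1.0 / v
        XtWX = Xs.T @ (w[:, None] * Xs)
        XtWy = Xs.T @ (w * ys)
        beta = np.linalg.solve(XtWX, XtWy)
        r = ys - Xs @ beta
        quad = float(np.sum(w * r**2))
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        return 0.5 * (float(np.sum(np.log(v))) + logdet_xwx + quad)

    theta0 = np.log([max(fit.sigma_g2, 1e-10), max(fit.sigma_e2, 1e-10)])
    h = 1e-4
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            tpp = theta0.copy(); tpp[i] += h; tpp[j] += h
            tpm = theta0.copy(); tpm[i] += h; tpm[j] -= h
            tmp = theta0.copy(); tmp[i] -= h; tmp[j] += h
            tmm = theta0.copy(); tmm[i] -= h; tmm[j] -= h
            H[i, j] = (nll(tpp) - nll(tpm) - nll(tmp) + nll(tmm)) / (4 * h * h)
    try:
        cov_log = np.linalg.inv(H)
        var_log = np.clip(np.diag(cov_log), 0.0, None)
        # delta method back to the variance scale
        se_g = float(np.sqrt(var_log[0]) * fit.sigma_g2)
        se_e = float(np.sqrt(var_log[1]) * fit.sigma_e2)
        return se_g, se_e
    except np.linalg.LinAlgError:
        return float("nan"), float("nan")


def gblup_reml(
    y: np.ndarray,
    X: np.ndarray,
    grm: GRM,
    tol: float = 1e-8,
    max_iter: int = 200,
    compute_se: bool = True,
) -> Tuple[VarianceComponents, GBLUPModel]:
    """Fit GBLUP by REML and back-solve for fixed effects and GEBVs."""
    y = np.asarray(y, dtype=np.float64)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    fit = reml_single_random(y, X, grm, tol=tol, max_iter=max_iter)
    d, U = fit.eigvals, fit.eigvecs
    w = 1.0 / (fit.sigma_g2 * d + fit.sigma_e2)
    resid_rot = U.T @ (y - X @ fit.beta)
    # gebv = sigma_g2 * G V^-1 (y - Xb)
    gebv = U @ (fit.sigma_g2 * d * w * resid_rot)
    se_g = se_e = None
    if compute_se:
        se_g, se_e = _reml_se(fit, X, y)
    vc = VarianceComponents(
        sigma_g2=fit.sigma_g2,
        sigma_e2=fit.sigma_e2,
        method="GBLUP-REML",
        se_sigma_g2=se_g,
        se_sigma_e2=se_e,
        boundary=fit.boundary,
    )
    model = GBLUPModel(
        y=y,
        X=X,
        grm=grm,
        sigma_g2=fit.sigma_g2,
        sigma_e2=fit.sigma_e2,
        beta=fit.beta,
        gebv=gebv,
        train_idx=np.arange(len(y)),
    )
    return vc, model


def gblup_predict(
    y: np.ndarray,
    X: np.ndarray,
    grm: GRM,
    test_idx: np.ndarray,
    sigma_g2: Optional[float] = None,
    sigma_e2: Optional[float] = None,
) -> GBLUPModel:
    """GEBVs for all individuals with the test set's phenotypes masked.

    Variance components are re-estimated on the training rows unless
    supplied. Test GEBVs come through the training-test covariance block of
    ``G``: ``g_hat_all = sigma_g^2 G[:, train] V_train^{-1} (y_t - X_t b)``.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = len(y)
    test_idx = np.asarray(test_idx, dtype=np.int64)
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    if len(train_idx) == 0:
        raise ValueError("test set covers all individuals; nothing to train on")

    G_tt = GRM(
        grm.matrix[np.ix_(train_idx, train_idx)],
        grm.denominator,
        grm.allele_freqs,
    )
    y_t, X_t = y[train_idx], X[train_idx]
    if sigma_g2 is None or sigma_e2 is None:
        fit = reml_single_random(y_t, X_t, G_tt)
        sigma_g2, sigma_e2 = fit.sigma_g2, fit.sigma_e2

    d, U = np.linalg.eigh(G_tt.matrix)
    w = 1.0 / (sigma_g2 * d + sigma_e2)
    Xs, ys = U.T @ X_t, U.T @ y_t
    XtWX = Xs.T @ (w[:, None] * Xs)
    beta = np.linalg.lstsq(XtWX, Xs.T @ (w * ys), rcond=None)[0]
    vinv_resid = U @ (w * (ys - Xs @ beta))
    gebv = sigma_g2 * grm.matrix[:, train_idx] @ vinv_resid
    return GBLUPModel(
        y=y,
        X=X,
        grm=grm,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        beta=beta,
        gebv=gebv,
        train_idx=train_idx,
    )


@njit(cache=True)
def _bayesb_core(
    y, X, M, pi, n_iter, burn_in, nu, S2, nu_e, S2_e, seed
):  # pragma: no cover - exercised through bayesb_gibbs
    np.random.seed(seed)
    n, p = X.shape
    m = M.shape[1]
    xtx = np.empty(p)
    for k in range(p):
        xtx[k] = np.dot(X[:, k], X[:, k])
    ctc = np.empty(m)
    for j in range(m):
        ctc[j] = np.dot(M[:, j], M[:, j])

    b = np.zeros(p)
    u = np.zeros(m)
    delta = np.zeros(m)
    sigma_j2 = np.full(m, S2)
    sigma_e2 = np.var(y) * 0.5 + 1e-8

    e = y.copy()  # residual with all effects at 0

    b_sum = np.zeros(p)
    u_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    se2_sum = 0.0
    sj2_sum = np.zeros(m)
    n_keep = 0
    trace_se2 = np.empty(n_iter - burn_in)
    trace_nin = np.empty(n_iter - burn_in)

    for it in range(n_iter):
        # fixed effects: flat prior, normal full conditional
        for k in range(p):
            if xtx[k] <= 0.0:
                continue
            r = np.dot(X[:, k], e) + xtx[k] * b[k]
            mean = r / xtx[k]
            sd = np.sqrt(sigma_e2 / xtx[k])
            new_b = np.random.normal(mean, sd)
            e += X[:, k] * (b[k] - new_b)
            b[k] = new_b

        # marker effects: spike-and-slab
        for j in range(m):
            c = ctc[j]
            if c <= 0.0:
                u[j] = 0.0
                delta[j] = 0.0
                continue
            r = np.dot(M[:, j], e) + c * u[j]
            if pi >= 1.0:
                prob_in = 0.0
            elif pi <= 0.0:
                prob_in = 1.0
            else:
                v0 = c * sigma_e2
                v1 = c * sigma_e2 + c * c * sigma_j2[j]
                log_l0 = -0.5 * np.log(v0) - 0.5 * r * r / v0
                log_l1 = -0.5 * np.log(v1) - 0.5 * r * r / v1
                log_odds = np.log(1.0 - pi) - np.log(pi) + log_l1 - log_l0
                if log_odds > 35.0:
                    prob_in = 1.0
                elif log_odds < -35.0:
                    prob_in = 0.0
                else:
                    prob_in = 1.0 / (1.0 + np.exp(-log_odds))
            if np.random.random() < prob_in:
                prec = c + sigma_e2 / sigma_j2[j]
                mean = r / prec
                sd = np.sqrt(sigma_e2 / prec)
                new_u = np.random.normal(mean, sd)
                e += M[:, j] * (u[j] - new_u)
                u[j] = new_u
                delta[j] = 1.0
                # locus variance | effect: scaled-inverse-chi-square
                sigma_j2[j] = (nu * S2 + new_u * new_u) / np.random.chisquare(nu + 1.0)
            else:
                if u[j] != 0.0:
                    e += M[:, j] * u[j]
                    u[j] = 0.0
                delta[j] = 0.0
                # refresh from the prior (locus carries no data when null)
                sigma_j2[j] = nu * S2 / np.random.chisquare(nu)

        # residual variance
        sse = np.dot(e, e)
        sigma_e2 = (sse + nu_e * S2_e) / np.random.chisquare(n + nu_e)
        if not np.isfinite(sigma_e2) or sigma_e2 <= 0.0:
            return (b_sum, u_sum, incl_sum, se2_sum, sj2_sum, -1, trace_se2, trace_nin)

        if it >= burn_in:
            trace_se2[n_keep] = sigma_e2
            trace_nin[n_keep] = delta.sum()
            n_keep += 1
            b_sum += b
            u_sum += u
            incl_sum += delta
            se2_sum += sigma_e2
            sj2_sum += sigma_j2

    return (b_sum, u_sum, incl_sum, se2_sum, sj2_sum, n_keep, trace_se2, trace_nin)


@dataclass
class BayesBResult:
    beta: np.ndarray  # posterior-mean fixed effects
    u: np.ndarray  # posterior-mean SNP effects
    inclusion_prob: np.ndarray
    sigma_e2: float
    sigma_j2: np.ndarray  # posterior-mean locus variances
    gebv: np.ndarray  # M_centered @ E[u]
    vc: VarianceComponents
    n_kept: int
    trace: Optional["pd.DataFrame"] = None  # per-kept-iteration diagnostics

    @property
    def sigma_g2(self) -> float:
        return self.vc.sigma_g2


def bayesb_gibbs(
    y: np.ndarray,
    X: np.ndarray,
    M: np.ndarray,
    pi: float = 0.95,
    n_iter: int = 5000,
    burn_in: int = 500,
    nu: float = 5.0,
    S2: Optional[float] = None,
    h2_prior: float = 0.5,
    nu_e: float = 4.0,
    seed: int = 0,
    trace_path=None,
) -> BayesBResult:
    """Spike-and-slab marker regression by Gibbs sampling.

    ``M`` is the 0/1/2 reference-allele dosage matrix; columns are centered
    internally. Each sweep samples fixed effects, per-SNP indicator +
    effect + locus variance, and the residual variance. The default slab
    scale ``S2`` is set so the prior-mean total marker variance matches
    ``h2_prior`` of the phenotypic variance.

    The additive variance reported in ``vc`` is ``Var(M E[u])`` across
    individuals (our documented estimator for the MCMC fit).
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must be in [0, 1]")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    y = np.asarray(y, dtype=np.float64)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    M = np.asarray(M, dtype=np.float64)
    if np.isnan(M).any():
        raise ValueError("genotypes must be complete")
    p_freq = M.mean(axis=0) / 2.0
    Mc = M - 2.0 * p_freq
    var_y = float(np.var(y))

    if S2 is None:
        sum2pq = float(np.sum(2.0 * p_freq * (1.0 - p_freq)))
        slab_frac = max(1.0 - pi, 1e-3)
        if nu <= 2 or sum2pq <= 0:
            raise ValueError("cannot derive S2; supply it explicitly (nu>2 needed)")
        # E[sigma_j^2] = nu S2/(nu-2); match slab_frac * sum2pq * E[sigma_j^2]
        # to h2_prior * var(y)
        S2 = h2_prior * var_y * (nu - 2.0) / (nu * slab_frac * sum2pq)
    if not np.isfinite(S2) or S2 <= 0:
        raise ValueError(f"degenerate slab scale S2={S2}")
    S2_e = max(var_y * 0.5, 1e-10)

    out = _bayesb_core(
        y, np.asfortranarray(X), np.asfortranarray(Mc), float(pi), int(n_iter), int(burn_in),
        float(nu), float(S2), float(nu_e), float(S2_e), int(seed) % (2**32),
    )
    b_sum, u_sum, incl_sum, se2_sum, sj2_sum, n_keep, trace_se2, trace_nin = out
    if n_keep < 0:
        raise RuntimeError(
            "non-finite residual variance in the chain; check hyperparameters nu/S2"
        )
    beta = b_sum / n_keep
    u = u_sum / n_keep
    gebv = Mc @ u
    sigma_g2 = float(np.var(gebv))
    sigma_e2 = float(se2_sum / n_keep)
    vc = VarianceComponents(sigma_g2=sigma_g2, sigma_e2=sigma_e2, method="BayesB-MCMC")
    import pandas as pd

    trace = pd.DataFrame(
        {
            "iteration": np.arange(int(burn_in), int(n_iter)),
            "sigma_e2": trace_se2[:n_keep],
            "n_included": trace_nin[:n_keep].astype(int),
        }
    )
    if trace_path is not None:
        trace.to_csv(trace_path, index=False)
    return BayesBResult(
        trace=trace,
        beta=beta,
        u=u,
        inclusion_prob=incl_sum / n_keep,
        sigma_e2=sigma_e2,
        sigma_j2=sj2_sum / n_keep,
        gebv=gebv,
        vc=vc,
        n_kept=int(n_keep),
    )
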