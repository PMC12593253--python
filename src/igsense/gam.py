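"""Gaussian additive model with one penalized-spline smooth.

Fits  y = a0 + a'covariates + f(x) + e,  where f is a cubic B-spline with
a second-order difference penalty on its coefficients and a sum-to-zero
constraint for identifiability. The smoothing parameter is selected by
restricted maximum likelihood: after a Demmler-Reinsch reparametrization
the spline's penalized directions become i.i.d. Gaussian random effects,
and the variance ratio is profiled out of the exact REML criterion, which
is then optimized in one dimension.

Reported quantities follow the conventions of penalized-regression
software: effective degrees of freedom (edf) are traces of the influence
matrix, the smooth is tested with an approximate F statistic comparing
against the covariates-only model on edf-scaled degrees of freedom, and
parametric terms use the Bayesian posterior covariance of the penalized
fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class ParametricTerm:
    estimate: float
    se: float
    tstat: float
    pvalue: float


@dataclass(frozen=True)
class GamResult:
    smooth_f: float
    smooth_edf: float
    smooth_p: float
    parametric: dict[str, ParametricTerm]
    adjusted_r2: float
    aic: float
    edf_total: float
    lam: float
    n: int
    fitted: np.ndarray
    coef: np.ndarray


def bspline_basis(
    x: np.ndarray, k: int = 10, degree: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """P-spline design matrix with ``k`` basis functions (uniform knots
    extended beyond the data range, after Eilers & Marx), paired with a
    second-order difference penalty. With equally spaced knots, straight
    lines have coefficients linear in the basis index and are therefore
    exactly unpenalized. If ``x`` has fewer unique values than ``k``, the
    basis shrinks with a warning.
    """
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValueError("need at least 2 unique x values for a spline basis")
    if uniq.size < k:
        k_new = max(degree + 1, uniq.size)
        warnings.warn(
            f"only {uniq.size} unique covariate values; shrinking spline "
            f"basis from {k} to {k_new}",
            stacklevel=2,
        )
        k = k_new
    lo, hi = float(uniq[0]), float(uniq[-1])
    h = (hi - lo) / (k - degree)
    knots = lo + h * (np.arange(k + degree + 1) - degree)
    B = BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()
    D = np.diff(np.eye(k), n=2, axis=0)
    return B, D.T @ D


def _reml_lambda(
    y: np.ndarray, X_fixed: np.ndarray, Z: np.ndarray
) -> tuple[float, float]:
    """Profile-REML estimate of the penalty for y = X_f a + Z b + e.

    ``Z`` columns carry i.i.d. N(0, sigma_b^2) coefficients. Returns
    (lambda, sigma2) with lambda = sigma^2 / sigma_b^2.
    """
    n, pf = X_fixed.shape
    Q = np.linalg.qr(X_fixed, mode="complete")[0]
    C = Q[:, pf:]  # orthonormal complement of the fixed-effect span
    yt = C.T @ y
    Zt = C.T @ Z
    U, d, _ = np.linalg.svd(Zt, full_matrices=False)
    v = d**2
    w = U.T @ yt
    resid2 = float(yt @ yt - w @ w)
    nf = n - pf
    if float(yt @ yt) <= 1e-10 * (float(y @ y) + 1.0):
        # response lies in the fixed-effect span (e.g., noise-free linear
        # data): fully penalize the smooth down to its null space
        return 1e12, float(yt @ yt) / nf

    def neg2reml(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        denom = 1.0 + gamma * v
        rss = float((w**2 / denom).sum()) + resid2
        sigma2 = rss / nf
        return nf * np.log(sigma2) + float(np.log(denom).sum())

    res = optimize.minimize_scalar(
        neg2reml, bounds=(-25.0, 25.0), method="bounded",
        options={"xatol": 1e-8},
    )
    gamma = float(np.exp(res.x))
    denom = 1.0 + gamma * v
    sigma2 = (float((w**2 / denom).sum()) + resid2) / nf
    lam = 1.0 / max(gamma, 1e-300)
    return lam, sigma2


def fit_gam(
    y: np.ndarray,
    x: np.ndarray,
    covariates: dict[str, np.ndarray] | None = None,
    k: int = 10,
) -> GamResult:
    """Fit y ~ covariates + s(x) with REML-selected smoothness."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    covariates = covariates or {}
    n = len(y)
    if len(x) != n or any(len(v) != n for v in covariates.values()):
        raise ValueError("response, smooth covariate and covariates must align")

    B, S = bspline_basis(x, k=k)
    kb = B.shape[1]
    # sum-to-zero constraint: reparametrize into the null space of 1'B
    c = B.sum(axis=0)
    Qc = np.linalg.qr(c.reshape(-1, 1), mode="complete")[0]
    Zc = Qc[:, 1:]
    Bc = B @ Zc
    Sc = Zc.T @ S @ Zc

    # Demmler-Reinsch: split the constrained smooth into an unpenalized
    # null-space direction (linear trend) and penalized random directions
    dvals, Uv = np.linalg.eigh(Sc)
    tol = dvals.max() * 1e-10
    pen = dvals > tol
    X_par = np.column_stack([np.ones(n)] + [np.asarray(v, float) for v in covariates.values()])
    par_names = ["intercept"] + list(covariates.keys())
    rank = np.linalg.matrix_rank(X_par)
    if rank < X_par.shape[1]:
        raise ValueError("parametric design is rank deficient (collinear covariates)")
    X_null = Bc @ Uv[:, ~pen]
    Zr = Bc @ Uv[:, pen] / np.sqrt(dvals[pen])
    lam, _ = _reml_lambda(y, np.column_stack([X_par, X_null]), Zr)

    # final penalized fit on the original constrained basis
    X = np.column_stack([X_par, Bc])
    p_par = X_par.shape[1]
    S_full = np.zeros((X.shape[1], X.shape[1]))
    S_full[p_par:, p_par:] = Sc
    XtX = X.T @ X
    A = XtX + lam * S_full
    Ainv = np.linalg.inv(A)
    beta = Ainv @ (X.T @ y)
    fitted = X @ beta
    rss = float(((y - fitted) ** 2).sum())
    F = Ainv @ XtX
    edf_col = np.diag(F)
    edf_total = float(edf_col.sum())
    edf_smooth = float(edf_col[p_par:].sum())
    df_resid = n - edf_total
    sigma2 = rss / df_resid

    # approximate smooth test against the covariates-only null model
    beta0, *_ = np.linalg.lstsq(X_par, y, rcond=None)
    rss0 = float(((y - X_par @ beta0) ** 2).sum())
    edf_num = max(edf_smooth, 1e-8)
    f_stat = ((rss0 - rss) / edf_num) / sigma2
    smooth_p = float(stats.f.sf(max(f_stat, 0.0), edf_num, df_resid))

    Vb = sigma2 * Ainv  # Bayesian covariance of the penalized estimator
    se = np.sqrt(np.diag(Vb)[:p_par])
    tstats = beta[:p_par] / se
    parametric = {
        name: ParametricTerm(
            estimate=float(beta[j]),
            se=float(se[j]),
            tstat=float(tstats[j]),
            pvalue=float(2 * stats.t.sf(abs(tstats[j]), df_resid)),
        )
        for j, name in enumerate(par_names)
    }

    tss = float(((y - y.mean()) ** 2).sum())
    adj_r2 = 1.0 - (rss / df_resid) / (tss / (n - 1))
    aic = n * np.log(2 * np.pi * rss / n) + n + 2.0 * (edf_total + 1.0)
    return GamResult(
        smooth_f=float(f_stat),
        smooth_edf=edf_smooth,
        smooth_p=smooth_p,
        parametric=parametric,
        adjusted_r2=float(adj_r2),
        aic=float(aic),
        edf_total=edf_total,
        lam=float(lam),
        n=n,
        fitted=fitted,
        coef=beta,
    )
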