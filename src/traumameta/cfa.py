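"""Ordinal confirmatory factor analysis for unidimensionality checks.

Item-level ordinal data are summarized by polychoric correlations (two-step
maximum likelihood under a discretized bivariate-normal model); a factor
pattern is then fit to the polychoric matrix by unweighted least squares and
judged with the usual incremental and absolute fit indices (CFI, TLI, RMSEA)
against the independence baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import norm


class UndefinedCorrelationError(ValueError):
    pass


def _thresholds_from_margins(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Category codes (contiguous) and N(0,1) thresholds from marginal
    cumulative proportions."""
    cats, codes = np.unique(x, return_inverse=True)
    if cats.size < 2:
        raise UndefinedCorrelationError("variable is constant after listwise deletion")
    props = np.bincount(codes) / codes.size
    cum = np.cumsum(props)[:-1]
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    return codes, norm.ppf(cum)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def _bivariate_rect_prob(a_lo, a_hi, b_lo, b_hi, rho):
    """P(a_lo < X < a_hi, b_lo < Y < b_hi) for standard bivariate normal,
    by Gauss-Legendre quadrature over the X interval.

    Bounds are arrays of matching shape; infinities allowed.
    """
    a_lo = np.clip(a_lo, -8.5, 8.5)
    a_hi = np.clip(a_hi, -8.5, 8.5)
    mid = 0.5 * (a_lo + a_hi)
    half = 0.5 * (a_hi - a_lo)
    x = mid[..., None] + half[..., None] * _GL_NODES  # (..., Q)
    s = np.sqrt(max(1.0 - rho * rho, 1e-12))
    inner = norm.cdf((b_hi[..., None] - rho * x) / s) - norm.cdf(
        (b_lo[..., None] - rho * x) / s
    )
    integrand = norm.pdf(x) * inner
    return half * np.sum(integrand * _GL_WEIGHTS, axis=-1)


def polychoric_correlation(x: np.ndarray, y: np.ndarray, min_n: int = 20) -> float:
    """Two-step ML polychoric correlation between two ordinal vectors.

    Thresholds come from each margin's cumulative proportions; the latent
    correlation maximizes the contingency-table likelihood under a
    discretized bivariate normal.  Missing values (NaN) are dropped pairwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < min_n:
        raise UndefinedCorrelationError(f"need >= {min_n} complete pairs, got {x.size}")
    cx, tx = _thresholds_from_margins(x)
    cy, ty = _thresholds_from_margins(y)
    kx, ky = tx.size + 1, ty.size + 1
    counts = np.zeros((kx, ky))
    np.add.at(counts, (cx, cy), 1)

    ax = np.concatenate([[-np.inf], tx, [np.inf]])
    ay = np.concatenate([[-np.inf], ty, [np.inf]])
    a_lo = np.repeat(ax[:-1], ky).reshape(kx, ky)
    a_hi = np.repeat(ax[1:], ky).reshape(kx, ky)
    b_lo = np.tile(ay[:-1], kx).reshape(kx, ky)
    b_hi = np.tile(ay[1:], kx).reshape(kx, ky)

    def nll(rho):
        p = _bivariate_rect_prob(a_lo, a_hi, b_lo, b_hi, rho)
        return -np.sum(counts * np.log(np.clip(p, 1e-12, None)))

    res = minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def polychoric_matrix(data: np.ndarray) -> np.ndarray:
    """Pairwise polychoric correlation matrix of the columns of ``data``."""
    data = np.asarray(data, dtype=float)
    p = data.shape[1]
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            R[i, j] = R[j, i] = polychoric_correlation(data[:, i], data[:, j])
    return R


@dataclass
class FactorFitResult:
    """Fit summary for a factor pattern against a correlation matrix."""

    chi2: float
    df: int
    baseline_chi2: float
    baseline_df: int
    n: int
    cfi: float
    tli: float
    rmsea: float
    loadings: np.ndarray
    factor_corr: np.ndarray
    converged: bool


class FactorFitError(RuntimeError):
    pass


def _nearest_psd(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= eps:
        return R
    vals = np.clip(vals, eps, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def fit_factor_model(
    corr: np.ndarray,
    n: int,
    pattern: np.ndarray,
    max_iter: int = 2000,
) -> FactorFitResult:
    """Unweighted-least-squares factor fit with standard fit indices.

    Parameters
    ----------
    corr : (p, p) correlation matrix (ridge-repaired to PSD if needed).
    n : sample size behind the correlations.
    pattern : (p, m) binary matrix; a 1 frees the loading of item i on
        factor j.  Every item must load on at least one factor.  Factor
        correlations are free for m > 1.

    The discrepancy is the sum of squared off-diagonal residuals
    ``F = sum_{i<j} (r_ij - sigma_ij)^2`` (uniquenesses absorb the
    diagonal); ``chi2 = (n - 1) * F``; incremental indices use the
    independence baseline ``sigma = I``.
    """
    R = _nearest_psd(np.asarray(corr, dtype=float))
    pattern = np.asarray(pattern, dtype=bool)
    p, m = pattern.shape
    if R.shape != (p, p):
        raise ValueError("pattern rows must match correlation dimension")
    if not pattern.any(axis=1).all():
        raise ValueError("every item must load on at least one factor")

    free_idx = np.argwhere(pattern)
    n_load = free_idx.shape[0]
    n_phi = m * (m - 1) // 2
    iu = np.triu_indices(p, 1)
    tril_m = np.tril_indices(m, -1)

    def implied(theta):
        L = np.zeros((p, m))
        L[free_idx[:, 0], free_idx[:, 1]] = theta[:n_load]
        Phi = np.eye(m)
        if n_phi:
            Phi[tril_m] = np.tanh(theta[n_load:])
            Phi = Phi + Phi.T - np.eye(m)
        return L @ Phi @ L.T, L, Phi

    def objective(theta):
        S, _, _ = implied(theta)
        resid = R[iu] - S[iu]
        return np.sum(resid**2)

    x0 = np.concatenate([np.full(n_load, 0.5), np.zeros(n_phi)])
    res = minimize(objective, x0, method="L-BFGS-B", options={"maxiter": max_iter})
    if not res.success and res.fun > 1e-4:
        raise FactorFitError(f"factor fit did not converge (discrepancy {res.fun:.4g})")
    S, L, Phi = implied(res.x)

    F_model = float(res.fun)
    F_base = float(np.sum(R[iu] ** 2))
    n_pairs = p * (p - 1) // 2
    df_m = n_pairs - (n_load + n_phi)
    df_0 = n_pairs
    chi2_m = (n - 1) * F_model
    chi2_0 = (n - 1) * F_base

    if df_m <= 0:
        cfi, tli, rmsea = 1.0, 1.0, 0.0
        df_m = max(df_m, 0)
    else:
        num = max(chi2_m - df_m, 0.0)
        den = max(chi2_0 - df_0, chi2_m - df_m, 0.0)
        cfi = 1.0 if den == 0 else 1.0 - num / den
        ratio_0 = chi2_0 / df_0
        ratio_m = chi2_m / df_m
        tli = (ratio_0 - ratio_m) / (ratio_0 - 1.0) if ratio_0 > 1 else 1.0
        tli = float(np.clip(tli, 0.0, 1.0))
        rmsea = float(np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * (n - 1))))

    return FactorFitResult(
        chi2=float(chi2_m),
        df=int(df_m),
        baseline_chi2=float(chi2_0),
        baseline_df=int(df_0),
        n=int(n),
        cfi=float(np.clip(cfi, 0.0, 1.0)),
        tli=float(tli),
        rmsea=float(rmsea),
        loadings=L,
        factor_corr=Phi,
        converged=bool(res.success or res.fun <= 1e-4),
    )
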