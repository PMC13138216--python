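"""Internal likelihood machinery shared across the modelling modules.

Implements Newton-Raphson maximum likelihood for binary and multinomial
logistic regression -- including fits with equality constraints that tie a
predictor's coefficient across outcome equations, which the off-the-shelf
fitters do not expose -- and a random-intercept binary GLM (logit or probit
link) integrated by Gauss-Hermite quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm


class SeparationWarning(UserWarning):
    pass


class FitError(RuntimeError):
    pass


@dataclass
class MLFit:
    """Maximum-likelihood fit: packed coefficients, covariance, and bookkeeping."""

    params: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    converged: bool
    n_iter: int
    grad_norm: float
    ridge_used: float = 0.0


def _multinomial_loglik(beta_mat, X, Yind):
    eta = X @ beta_mat  # (n, K-1)
    full = np.hstack([np.zeros((X.shape[0], 1)), eta])
    lse = logsumexp(full, axis=1)
    ll = float(np.sum(full[Yind.astype(bool)]) - lse.sum())
    P = np.exp(full - lse[:, None])  # (n, K)
    return ll, P


def fit_multinomial_ml(
    X: np.ndarray,
    y: np.ndarray,
    n_categories: int | None = None,
    mapping: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 0.0,
) -> MLFit:
    """Multinomial logit MLE with category 0 as reference.

    Parameters
    ----------
    X : (n, p) design matrix (include the intercept column explicitly).
    y : integer outcome codes 0..K-1; 0 is the reference category.
    mapping : optional (p*(K-1), q) matrix expressing the packed coefficient
        vector as ``M @ theta``; used to impose equality constraints across
        outcome equations (e.g., a shared coefficient).  Identity when None.
    ridge : small L2 penalty added on separation-suspect refits.

    The packed coefficient layout is column-major by outcome equation:
    ``beta_mat = params.reshape(p, K - 1, order="F")``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    K = int(n_categories if n_categories is not None else y.max() + 1)
    if K < 2:
        raise ValueError("need at least 2 outcome categories")
    Yind = np.zeros((n, K))
    Yind[np.arange(n), y] = 1.0

    n_full = p * (K - 1)
    M = np.eye(n_full) if mapping is None else np.asarray(mapping, dtype=float)
    q = M.shape[1]
    theta = np.zeros(q)

    ll_prev = -np.inf
    converged = False
    grad_norm = np.inf
    for it in range(max_iter):
        beta_mat = (M @ theta).reshape(p, K - 1, order="F")
        ll, P = _multinomial_loglik(beta_mat, X, Yind)
        resid = Yind[:, 1:] - P[:, 1:]  # (n, K-1)
        g_full = (X.T @ resid).reshape(n_full, order="F")
        H_full = np.zeros((n_full, n_full))
        for a in range(K - 1):
            for b in range(a, K - 1):
                w = P[:, a + 1] * ((1.0 if a == b else 0.0) - P[:, b + 1])
                block = -(X * w[:, None]).T @ X
                H_full[a * p:(a + 1) * p, b * p:(b + 1) * p] = block
                if a != b:
                    H_full[b * p:(b + 1) * p, a * p:(a + 1) * p] = block
        g = M.T @ g_full - ridge * theta
        H = M.T @ H_full @ M - ridge * np.eye(q)
        grad_norm = float(np.linalg.norm(g))
        if grad_norm < tol * max(1.0, abs(ll)) or (ll - ll_prev) < tol * max(1.0, abs(ll)) and it > 0 and grad_norm < 1e-6:
            converged = True
            break
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -g, rcond=None)[0]
        # step-halving line search on the penalized log-likelihood
        scale = 1.0
        pen = lambda t: -0.5 * ridge * float(t @ t)
        for _ in range(30):
            theta_new = theta + scale * step
            beta_new = (M @ theta_new).reshape(p, K - 1, order="F")
            ll_new, _ = _multinomial_loglik(beta_new, X, Yind)
            if ll_new + pen(theta_new) >= ll + pen(theta) - 1e-12:
                break
            scale *= 0.5
        theta = theta + scale * step
        ll_prev = ll

    beta_mat = (M @ theta).reshape(p, K - 1, order="F")
    ll, P = _multinomial_loglik(beta_mat, X, Yind)
    H_full = np.zeros((n_full, n_full))
    for a in range(K - 1):
        for b in range(a, K - 1):
            w = P[:, a + 1] * ((1.0 if a == b else 0.0) - P[:, b + 1])
            block = -(X * w[:, None]).T @ X
            H_full[a * p:(a + 1) * p, b * p:(b + 1) * p] = block
            if a != b:
                H_full[b * p:(b + 1) * p, a * p:(a + 1) * p] = block
    H = M.T @ H_full @ M - ridge * np.eye(q)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-H)
    return MLFit(
        params=theta,
        cov=cov,
        loglik=ll,
        n=n,
        converged=converged,
        n_iter=it + 1,
        grad_norm=grad_norm,
        ridge_used=ridge,
    )


def equality_mapping(p: int, n_eq: int, shared_cols: list[int]) -> np.ndarray:
    """Mapping matrix tying the listed design columns to one coefficient
    shared across all ``n_eq`` outcome equations.

    Layout matches :func:`fit_multinomial_ml`: free coefficients first
    (column-major by equation), then one shared parameter per tied column.
    """
    shared = set(shared_cols)
    free = [(j, k) for k in range(n_eq) for j in range(p) if j not in shared]
    q = len(free) + len(shared)
    M = np.zeros((p * n_eq, q))
    for idx, (j, k) in enumerate(free):
        M[k * p + j, idx] = 1.0
    for s_idx, j in enumerate(sorted(shared)):
        for k in range(n_eq):
            M[k * p + j, len(free) + s_idx] = 1.0
    return M


def fit_logistic_ml(X, y, **kwargs) -> MLFit:
    """Binary logistic MLE (multinomial with K=2)."""
    return fit_multinomial_ml(X, np.asarray(y, dtype=int), n_categories=2, **kwargs)


def check_separation(fit: MLFit, threshold: float = 15.0) -> bool:
    """Heuristic separation flag: any unreasonably large coefficient."""
    return bool(np.any(np.abs(fit.params) > threshold))


# ---------------------------------------------------------------------------
# Random-intercept binary GLM by Gauss-Hermite quadrature
# ---------------------------------------------------------------------------


@dataclass
class RandomInterceptFit:
    beta: np.ndarray
    sigma_u: float
    cov_beta: np.ndarray
    loglik: float
    converged: bool
    group_effects: dict
    link: str


def _link_funcs(link):
    if link == "logit":
        def logp(eta, y):
            return np.where(y > 0.5, log_expit(eta), log_expit(-eta))

        def dlogp(eta, y):
            return y - expit(eta)

        return logp, dlogp
    if link == "probit":
        def logp(eta, y):
            return np.where(y > 0.5, norm.logcdf(eta), norm.logcdf(-eta))

        def dlogp(eta, y):
            r = np.exp(norm.logpdf(eta) - norm.logcdf(eta))
            r_neg = np.exp(norm.logpdf(eta) - norm.logcdf(-eta))
            return np.where(y > 0.5, r, -r_neg)

        return logp, dlogp
    raise ValueError(f"unknown link {link!r}")


def fit_binary_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    link: str = "probit",
    n_nodes: int = 15,
    max_iter: int = 200,
) -> RandomInterceptFit:
    """Binary GLM with a normal random intercept per group, fit by maximum
    likelihood with Gauss-Hermite quadrature over the random effect.

    Returns empirical-Bayes group intercepts alongside the fixed effects.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    codes, inv = np.unique(groups, return_inverse=True)
    G = codes.size
    nodes, wts = np.polynomial.hermite_e.hermegauss(n_nodes)
    wts = wts / wts.sum()
    logp, dlogp = _link_funcs(link)

    classes = np.unique(y)
    if classes.size < 2:
        raise FitError("outcome has a single class; cannot fit binary model")

    def pack_ll(par, with_grad=True):
        beta = par[:-1]
        # bounded variance parameterization keeps the optimizer's
        # exploratory steps finite
        sigma = np.exp(np.clip(par[-1], -10.0, 2.0))
        eta0 = X @ beta
        # (n, Q) log density contributions
        etas = np.clip(eta0[:, None] + sigma * nodes[None, :], -35.0, 35.0)
        lp = logp(etas, y[:, None])
        # segment-sum over groups
        grp_lp = np.zeros((G, n_nodes))
        np.add.at(grp_lp, inv, lp)
        tot = grp_lp + np.log(wts)[None, :]
        m = tot.max(axis=1, keepdims=True)
        log_int = m.ravel() + np.log(np.exp(tot - m).sum(axis=1))
        ll = float(log_int.sum())
        if not with_grad:
            return -ll
        post = np.exp(tot - log_int[:, None])  # (G, Q) posterior node weights
        s = dlogp(etas, y[:, None])  # (n, Q)
        w_obs = post[inv]  # (n, Q)
        g_beta = X.T @ np.sum(w_obs * s, axis=1)
        g_sigma = float(np.sum(w_obs * s * nodes[None, :])) * sigma
        return -ll, -np.concatenate([g_beta, [g_sigma]])

    x0 = np.zeros(X.shape[1] + 1)
    x0[-1] = np.log(0.5)
    res = minimize(pack_ll, x0, jac=True, method="BFGS",
                   options={"maxiter": max_iter, "gtol": 1e-6})
    beta = res.x[:-1]
    sigma = float(np.exp(np.clip(res.x[-1], -10.0, 2.0)))
    if np.any(np.abs(beta) > 15):
        raise FitError(
            "suspected perfect separation (|coef| > 15); reduce the predictor set"
        )

    # empirical-Bayes group intercepts (posterior means on the final fit)
    eta0 = X @ beta
    etas = np.clip(eta0[:, None] + sigma * nodes[None, :], -35.0, 35.0)
    lp = logp(etas, y[:, None])
    grp_lp = np.zeros((G, n_nodes))
    np.add.at(grp_lp, inv, lp)
    tot = grp_lp + np.log(wts)[None, :]
    post = np.exp(tot - logsumexp(tot, axis=1, keepdims=True))
    eb = post @ (sigma * nodes)
    group_effects = dict(zip(codes.tolist(), eb.tolist()))

    # covariance of beta from the inverse Hessian block (numeric via BFGS inv)
    cov_full = res.hess_inv if isinstance(res.hess_inv, np.ndarray) else res.hess_inv.todense()
    cov_beta = np.asarray(cov_full)[: X.shape[1], : X.shape[1]]
    return RandomInterceptFit(
        beta=beta,
        sigma_u=sigma,
        cov_beta=cov_beta,
        loglik=-res.fun,
        converged=bool(res.success),
        group_effects=group_effects,
        link=link,
    )
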