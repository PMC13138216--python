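"""Graded response model (GRM) for ordinal items on a latent-trait metric.

The GRM models the probability that an item response reaches category ``k``
or higher as a logistic function of the latent trait:

    P(X >= k | theta) = 1 / (1 + exp(-a * (theta - b_k)))

with item discrimination ``a > 0`` and strictly increasing thresholds
``b_1 < ... < b_K``.  Fitting is marginal maximum likelihood via EM with a
fixed rectangular quadrature grid, identifying the latent metric as N(0, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit


@dataclass
class GRMParameters:
    """Per-item discrimination and ordered thresholds for a set of items.

    Parameters
    ----------
    labels : list of str
        Item names.
    discriminations : ndarray
        Positive slope per item.
    thresholds : list of ndarray
        Strictly increasing threshold vector per item; its length equals the
        item's maximum score.
    anchor : ndarray of bool
        Marks items administered under more than one calibration and used for
        scale linking.
    """

    labels: list[str]
    discriminations: np.ndarray
    thresholds: list[np.ndarray]
    anchor: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.discriminations = np.asarray(self.discriminations, dtype=float)
        self.thresholds = [np.asarray(b, dtype=float) for b in self.thresholds]
        if self.anchor is None:
            self.anchor = np.zeros(len(self.labels), dtype=bool)
        self.anchor = np.asarray(self.anchor, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = len(self.labels)
        if not (len(self.thresholds) == n and self.discriminations.shape == (n,)):
            raise ValueError("labels, discriminations and thresholds must align")
        for lab, a, b in zip(self.labels, self.discriminations, self.thresholds):
            if not np.isfinite(a) or a <= 0:
                raise ValueError(f"item {lab!r}: discrimination must be positive, got {a}")
            if b.size < 1 or not np.all(np.diff(b) > 0) or not np.all(np.isfinite(b)):
                raise ValueError(f"item {lab!r}: thresholds must be finite and strictly increasing")

    @property
    def n_items(self) -> int:
        return len(self.labels)

    @property
    def max_scores(self) -> np.ndarray:
        return np.array([b.size for b in self.thresholds])

    def subset(self, labels: list[str]) -> "GRMParameters":
        idx = [self.labels.index(l) for l in labels]
        return GRMParameters(
            labels=[self.labels[i] for i in idx],
            discriminations=self.discriminations[idx],
            thresholds=[self.thresholds[i] for i in idx],
            anchor=self.anchor[idx],
        )

    def transform(self, A: float, B: float) -> "GRMParameters":
        """Re-express parameters on the metric ``theta* = A * theta + B``."""
        if A <= 0:
            raise ValueError("scale constant A must be positive")
        return GRMParameters(
            labels=list(self.labels),
            discriminations=self.discriminations / A,
            thresholds=[A * b + B for b in self.thresholds],
            anchor=self.anchor.copy(),
        )

    def to_json(self, path) -> None:
        payload = [
            {
                "label": lab,
                "discrimination": float(a),
                "thresholds": [float(x) for x in b],
                "anchor": bool(anc),
            }
            for lab, a, b, anc in zip(
                self.labels, self.discriminations, self.thresholds, self.anchor
            )
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GRMParameters":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            labels=[d["label"] for d in payload],
            discriminations=np.array([d["discrimination"] for d in payload]),
            thresholds=[np.array(d["thresholds"]) for d in payload],
            anchor=np.array([d.get("anchor", False) for d in payload]),
        )


def category_probabilities(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Category probabilities P(X = k | theta), shape (len(theta), K + 1)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    # cumulative P(X >= k) for k = 1..K, padded with 1 at k=0 and 0 at K+1
    cum = expit(a * (theta[:, None] - b[None, :]))
    ones = np.ones((theta.size, 1))
    zeros = np.zeros((theta.size, 1))
    star = np.hstack([ones, cum, zeros])
    return star[:, :-1] - star[:, 1:]


def expected_item_score(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """E[X | theta] for one item (the item response function)."""
    probs = category_probabilities(a, b, theta)
    k = np.arange(probs.shape[1])
    return probs @ k


def test_characteristic_curve(params: GRMParameters, theta: np.ndarray) -> np.ndarray:
    """Expected total score over all items as a function of theta.

    Monotone increasing from 0 (theta -> -inf) to the maximum total score.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    total = np.zeros(theta.size)
    for a, b in zip(params.discriminations, params.thresholds):
        total += expected_item_score(a, b, theta)
    return total


class GRMFitError(RuntimeError):
    pass


def _item_loglik_and_grad(pars, counts, grid):
    """Negative expected complete-data log-likelihood and gradient for one item.

    ``pars`` = (log a, b_1, log delta_2, ..., log delta_K) parametrizes strictly
    increasing thresholds; ``counts`` has shape (Q, K + 1) of expected counts
    per quadrature node and category.
    """
    K = counts.shape[1] - 1
    a = np.exp(pars[0])
    b = np.empty(K)
    b[0] = pars[1]
    if K > 1:
        b[1:] = pars[1] + np.cumsum(np.exp(pars[2:]))
    z = a * (grid[:, None] - b[None, :])  # (Q, K)
    cum = expit(z)
    star = np.hstack([np.ones((grid.size, 1)), cum, np.zeros((grid.size, 1))])
    probs = np.clip(star[:, :-1] - star[:, 1:], 1e-12, None)
    nll = -np.sum(counts * np.log(probs))

    # dP_k/da and dP_k/db_j from the cumulative logistic derivatives
    dcum = cum * (1 - cum)  # sigma'(z_k), (Q, K)
    pad = np.zeros((grid.size, 1))
    dcum_pad = np.hstack([pad, dcum, pad])  # index k = 0..K+1
    tdiff = grid[:, None] - b[None, :]
    dz_da = np.hstack([pad, dcum * tdiff, pad])
    w = counts / probs  # (Q, K+1)
    # P_k = star_k - star_{k+1}; d star_k/da = sigma'(z_k) * (theta - b_k)
    grad_a = -np.sum(w * (dz_da[:, :-1] - dz_da[:, 1:])) * a  # chain rule for log a
    grad_b = np.zeros(K)
    for j in range(1, K + 1):
        # star_j depends on b_j with d star_j / d b_j = -a * sigma'(z_j);
        # star_j enters P_{j-1} with +, P_j with -
        contrib = -a * dcum_pad[:, j]
        grad_b[j - 1] = np.sum((w[:, j - 1] - w[:, j]) * contrib)
    # chain rule to the increment parametrization
    grad = np.empty_like(pars)
    grad[0] = grad_a
    grad[1] = grad_b.sum()
    if K > 1:
        for j in range(1, K):
            grad[j + 1] = grad_b[j:].sum() * np.exp(pars[j + 1])
    return nll, grad


def _item_score_contributions(a, b, responses, post, grid):
    """Per-person score vector of the marginal log-likelihood w.r.t. one
    item's (a, b_1..b_K), via the Fisher identity (posterior-expected
    complete-data score)."""
    K = b.size
    z = a * (grid[:, None] - b[None, :])
    cum = expit(z)
    star = np.hstack([np.ones((grid.size, 1)), cum, np.zeros((grid.size, 1))])
    probs = np.clip(star[:, :-1] - star[:, 1:], 1e-12, None)
    dcum = cum * (1 - cum)
    pad = np.zeros((grid.size, 1))
    dcum_pad = np.hstack([pad, dcum, pad])
    dz_da = np.hstack([pad, dcum * (grid[:, None] - b[None, :]), pad])
    # dlogP_k/da and /db_j evaluated on the grid, shape (Q, K+1)
    dlog_da = (dz_da[:, :-1] - dz_da[:, 1:]) / probs
    dlog_db = np.zeros((grid.size, K, K + 1))
    for j in range(1, K + 1):
        contrib = -a * dcum_pad[:, j]
        # P_{j-1} = star_{j-1} - star_j loses d star_j; P_j gains it
        dlog_db[:, j - 1, j - 1] -= contrib / probs[:, j - 1]
        dlog_db[:, j - 1, j] += contrib / probs[:, j]
    n = responses.size
    out = np.zeros((n, K + 1))
    obs = responses >= 0
    r = responses[obs]
    # gather d log P at the observed category, then posterior-average
    out[obs, 0] = np.sum(post[obs] * dlog_da[:, r].T, axis=1)
    for j in range(K):
        out[obs, j + 1] = np.sum(post[obs] * dlog_db[:, j, r].T, axis=1)
    return out


def fit_grm(
    responses: np.ndarray,
    labels: list[str] | None = None,
    anchor: np.ndarray | None = None,
    n_quadrature: int = 61,
    grid_bound: float = 6.0,
    max_iter: int = 500,
    tol: float = 1e-4,
    compute_se: bool = False,
):
    """Fit a graded response model by marginal maximum likelihood EM.

    Parameters
    ----------
    responses : ndarray of shape (n_persons, n_items)
        Integer category codes starting at 0; negative values or NaN mark
        missing responses.
    labels : item names (defaults to ``item_1`` ...).
    anchor : optional boolean anchor flags carried into the result.
    n_quadrature : number of equally spaced quadrature nodes on
        ``[-grid_bound, grid_bound]`` with N(0,1) weights.
    tol : EM stops when the largest absolute parameter change falls below it.
    compute_se : also return asymptotic standard errors from the empirical
        Fisher information of the marginal likelihood.

    Returns
    -------
    (GRMParameters, dict) with fit info: ``loglik`` trace, ``n_iter``,
    ``converged``, optionally ``se`` (list of per-item arrays [se_a, se_b...]).
    """
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2:
        raise ValueError("responses must be 2-D (persons x items)")
    X = np.where(np.isnan(X), -1, X).astype(int)
    n, p = X.shape
    if labels is None:
        labels = [f"item_{j + 1}" for j in range(p)]

    max_cats = X.max(axis=0)
    for j in range(p):
        obs = X[:, j][X[:, j] >= 0]
        if obs.size and obs.min() == obs.max():
            raise GRMFitError(f"item {labels[j]!r}: all observed responses identical")
        seen = np.unique(obs)
        if not np.array_equal(seen, np.arange(max_cats[j] + 1)):
            # collapse unobserved categories to a contiguous code
            remap = {c: i for i, c in enumerate(seen)}
            X[:, j] = np.array([remap.get(v, -1) for v in X[:, j]])
            max_cats[j] = len(seen) - 1

    grid = np.linspace(-grid_bound, grid_bound, n_quadrature)
    weights = np.exp(-0.5 * grid**2)
    weights /= weights.sum()

    # starting values: a = 1, thresholds at equally spaced quantile positions
    a_hat = np.ones(p)
    b_hat = []
    for j in range(p):
        K = max_cats[j]
        obs = X[:, j][X[:, j] >= 0]
        cuts = np.array([(obs >= k).mean() for k in range(1, K + 1)])
        cuts = np.clip(cuts, 1e-3, 1 - 1e-3)
        from scipy.stats import norm

        b0 = -norm.ppf(cuts)
        b0 = np.maximum.accumulate(b0 + 1e-6 * np.arange(K))
        b_hat.append(b0)

    from scipy.optimize import minimize

    ll_trace = []
    converged = False
    for it in range(max_iter):
        # E-step: posterior over the grid per person
        log_like = np.zeros((n, grid.size))
        prob_tables = []
        for j in range(p):
            probs = np.clip(
                category_probabilities(a_hat[j], b_hat[j], grid), 1e-12, None
            )  # (Q, K+1)
            prob_tables.append(probs)
            obs = X[:, j] >= 0
            log_like[obs] += np.log(probs[:, X[obs, j]].T)
        log_post = log_like + np.log(weights)[None, :]
        m = log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post - m)
        norm_c = post.sum(axis=1, keepdims=True)
        ll = float(np.sum(m.ravel() + np.log(norm_c.ravel())))
        ll_trace.append(ll)
        post /= norm_c

        # M-step per item on expected category counts
        max_change = 0.0
        for j in range(p):
            K = max_cats[j]
            counts = np.zeros((grid.size, K + 1))
            for k in range(K + 1):
                sel = X[:, j] == k
                if sel.any():
                    counts[:, k] = post[sel].sum(axis=0)
            x0 = np.empty(K + 1)
            x0[0] = np.log(a_hat[j])
            x0[1] = b_hat[j][0]
            if K > 1:
                x0[2:] = np.log(np.diff(b_hat[j]))
            res = minimize(
                _item_loglik_and_grad,
                x0,
                args=(counts, grid),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 50},
            )
            a_new = float(np.exp(res.x[0]))
            b_new = np.empty(K)
            b_new[0] = res.x[1]
            if K > 1:
                b_new[1:] = res.x[1] + np.cumsum(np.exp(res.x[2:]))
            max_change = max(
                max_change,
                abs(a_new - a_hat[j]),
                float(np.max(np.abs(b_new - b_hat[j]))),
            )
            a_hat[j] = a_new
            b_hat[j] = b_new
        if max_change < tol:
            converged = True
            break

    if not converged and max_iter > 1:
        # EM made max_iter passes without meeting tol; report the last change
        info_msg = f"EM stopped after {max_iter} iterations (last max change {max_change:.2e})"
    else:
        info_msg = None

    params = GRMParameters(
        labels=list(labels),
        discriminations=a_hat,
        thresholds=b_hat,
        anchor=anchor,
    )
    info = {"loglik": ll_trace, "n_iter": len(ll_trace), "converged": converged, "message": info_msg}

    if compute_se:
        # final posterior with converged parameters
        log_like = np.zeros((n, grid.size))
        for j in range(p):
            probs = np.clip(category_probabilities(a_hat[j], b_hat[j], grid), 1e-12, None)
            obs = X[:, j] >= 0
            log_like[obs] += np.log(probs[:, X[obs, j]].T)
        log_post = log_like + np.log(weights)[None, :]
        post = np.exp(log_post - log_post.max(axis=1, keepdims=True))
        post /= post.sum(axis=1, keepdims=True)
        ses = []
        for j in range(p):
            scores = _item_score_contributions(a_hat[j], b_hat[j], X[:, j], post, grid)
            fisher = scores.T @ scores
            try:
                cov = np.linalg.inv(fisher)
                ses.append(np.sqrt(np.clip(np.diag(cov), 0, None)))
            except np.linalg.LinAlgError:
                ses.append(np.full(scores.shape[1], np.nan))
        info["se"] = ses
    return params, info
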