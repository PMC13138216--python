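"""Multiple imputation by chained equations for the pooled two-wave cohort.

Variables are imputed in the combined sample with fixed study effects (dummy
variables per study) and a participant-level random intercept to respect the
two-level structure (waves nested within participants).  Continuous variables
use a linear mixed model with study-specific residual variances; binary
variables use a random-intercept probit.  Predictor sets are screened by
pairwise correlation with the index variable (default |r| >= 0.10), with the
study dummies always retained.  Per-imputation estimates are combined by
Rubin's rules with Barnard-Rubin degrees of freedom.

Parameter uncertainty is propagated by drawing coefficients from their
asymptotic normal distribution and residual variances from scaled chi-square
draws before each posterior-predictive imputation (normal-approximation FCS,
not full Bayes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from ._glm import FitError, fit_binary_random_intercept


@dataclass
class ImputationSpec:
    m: int = 20
    cycles: int = 10
    predictor_threshold: float = 0.10
    variables: dict = field(default_factory=dict)  # name -> continuous|binary|categorical
    seed: int = 0
    id_col: str = "participant_id"
    study_col: str = "study_id"

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need m >= 2 imputations")
        if not 0.0 <= self.predictor_threshold < 1.0:
            raise ValueError("predictor screen threshold must lie in [0, 1)")


@dataclass
class ImputedDatasets:
    datasets: list
    metadata: dict

    @property
    def m(self) -> int:
        return len(self.datasets)

    def write_csvs(self, directory) -> None:
        import json
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.datasets, 1):
            df.to_csv(d / f"imputation_{i:03d}.csv", index=False)
        with open(d / "imputation_metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=1, default=str)


@dataclass
class PooledEstimate:
    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci_low: float
    ci_high: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def rubin_pool(
    estimates,
    variances,
    alpha: float = 0.05,
    n_complete: int | None = None,
) -> PooledEstimate:
    """Combine per-imputation estimates and variances by Rubin's rules.

    ``T = U-bar + (1 + 1/m) B`` with Barnard-Rubin small-sample degrees of
    freedom when ``n_complete`` (complete-data residual df) is supplied,
    otherwise the classical large-sample df.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 imputations")
    if np.any(u <= 0):
        raise ValueError("within-imputation variances must be positive")
    qbar = float(q.mean())
    ubar = float(u.mean())
    b = float(q.var(ddof=1))
    total = ubar + (1 + 1 / m) * b
    if b > 0:
        r = (1 + 1 / m) * b / ubar
        df_old = (m - 1) * (1 + 1 / r) ** 2
        lam = (1 + 1 / m) * b / total
        if n_complete is not None:
            nu_com = n_complete
            nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / nu_obs)
        else:
            df = df_old
    else:
        df = np.inf if n_complete is None else float(n_complete)
    crit = t_dist.ppf(1 - alpha / 2, df) if np.isfinite(df) else norm.ppf(1 - alpha / 2)
    half = crit * np.sqrt(total)
    return PooledEstimate(
        estimate=qbar,
        within_var=ubar,
        between_var=b,
        total_var=total,
        df=float(df),
        ci_low=qbar - half,
        ci_high=qbar + half,
        m=m,
    )


def _numeric_frame(table: pd.DataFrame, exclude=()) -> pd.DataFrame:
    """Numeric view of a mixed table: bools to 0/1, object/categorical columns
    dummy-coded (first level dropped)."""
    cols = {}
    for c in table.columns:
        if c in exclude:
            continue
        s = table[c]
        if s.dtype == bool:
            cols[c] = s.astype(float)
        elif s.dtype.kind in "ifu":
            cols[c] = s.astype(float)
        else:
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            for dc in dummies.columns:
                cols[dc] = dummies[dc]
    return pd.DataFrame(cols, index=table.index)


def select_predictors(
    table: pd.DataFrame,
    target: str,
    threshold: float = 0.10,
    always: tuple = (),
) -> list[str]:
    """Variables correlated at least ``threshold`` (absolute Pearson, which is
    the point-biserial for flags) with the target, pairwise-complete.

    The target itself is excluded; ``always`` columns are appended
    unconditionally (the study dummies in the pipeline).
    """
    num = _numeric_frame(table)
    if target not in num.columns:
        raise ValueError(f"target {target!r} is not numeric-codable")
    y = num[target]
    if y.dropna().nunique() < 2:
        raise ValueError(f"target {target!r} has zero variance")
    chosen = []
    for c in num.columns:
        if c == target or c in always:
            continue
        r = num[c].corr(y)
        if pd.notna(r) and abs(r) >= threshold:
            chosen.append((abs(r), c))
    # strongest predictors first (the order also guides separation fallback)
    ordered = [c for _, c in sorted(chosen, reverse=True)]
    return ordered + [c for c in always if c in num.columns or c in table.columns]


# ---------------------------------------------------------------------------
# Conditional imputation models
# ---------------------------------------------------------------------------


class SingularDesignError(np.linalg.LinAlgError):
    pass


def _safe_lstsq(X, y):
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        norms = np.linalg.norm(X - X.mean(0), axis=0)
        bad = [int(i) for i in np.where(norms < 1e-10)[0]]
        raise SingularDesignError(f"design is rank-deficient (suspect columns {bad})")
    return coef


@dataclass
class MixedModelFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    tau2: float
    sigma2_by_study: dict
    n_by_study: dict


def fit_continuous_mixed(
    X: np.ndarray,
    y: np.ndarray,
    participant: np.ndarray,
    study: np.ndarray,
) -> MixedModelFit:
    """Linear model with participant random intercept, fixed study effects
    in ``X``, and heteroskedastic (study-specific) residual variances.

    Moment-based two-stage fit: OLS residuals give the random-intercept
    variance (within-participant residual covariance) and per-study residual
    variances; a weighted refit then updates the coefficients.
    """
    n, p = X.shape
    if n < max(30, p + 2):
        raise ValueError(f"need at least {max(30, p + 2)} complete cases, got {n}")
    beta = _safe_lstsq(X, y)
    resid = y - X @ beta

    rdf = pd.DataFrame({"pid": participant, "r": resid, "s": study})
    pair_products = []
    for _, grp in rdf.groupby("pid"):
        if len(grp) >= 2:
            r = grp["r"].to_numpy()
            pair_products.extend(r[i] * r[j] for i in range(len(r)) for j in range(i + 1, len(r)))
    tau2 = float(np.clip(np.mean(pair_products), 0.0, None)) if pair_products else 0.0

    sigma2 = {}
    n_by = {}
    for s, grp in rdf.groupby("s"):
        sigma2[s] = float(max(np.mean(grp["r"] ** 2) - tau2, 1e-8))
        n_by[s] = int(len(grp))

    w = 1.0 / np.array([tau2 + sigma2[s] for s in study])
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    try:
        cov = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(str(exc)) from exc
    beta = cov @ (Xw.T @ y)
    return MixedModelFit(beta=beta, cov_beta=cov, tau2=tau2, sigma2_by_study=sigma2, n_by_study=n_by)


def impute_continuous_mixed(
    table: pd.DataFrame,
    target: str,
    predictors: list[str],
    seed: int,
    id_col: str = "participant_id",
    study_col: str = "study_id",
) -> np.ndarray:
    """One posterior-predictive completion of a continuous variable.

    Returns the full column with missing entries replaced by draws; observed
    entries are returned untouched.
    """
    rng = np.random.default_rng(seed)
    num_all = _numeric_frame(table)
    cols = [c for c in predictors if c in num_all.columns and c != target]
    X_all = np.column_stack([np.ones(len(table))] + [num_all[c].to_numpy() for c in cols])
    y = table[target].to_numpy(dtype=float)
    obs = ~np.isnan(y)
    if np.isnan(X_all).any():
        # predictors already completed earlier in the cycle; any residual NaN
        # (first cycle) is mean-filled for the fit
        col_means = np.nanmean(X_all, axis=0)
        X_all = np.where(np.isnan(X_all), col_means, X_all)
    if obs.all():
        return y
    pid = table[id_col].to_numpy()
    study = table[study_col].to_numpy()

    fit = fit_continuous_mixed(X_all[obs], y[obs], pid[obs], study[obs])
    L = np.linalg.cholesky(fit.cov_beta + 1e-12 * np.eye(len(fit.beta)))
    beta_star = fit.beta + L @ rng.standard_normal(len(fit.beta))
    sigma2_star = {
        s: v * fit.n_by_study[s] / max(rng.chisquare(fit.n_by_study[s]), 1e-8)
        for s, v in fit.sigma2_by_study.items()
    }

    resid_obs = y[obs] - X_all[obs] @ fit.beta
    resid_by_pid = pd.Series(resid_obs).groupby(pid[obs]).mean()
    n_obs_by_pid = pd.Series(resid_obs).groupby(pid[obs]).size()

    out = y.copy()
    for i in np.where(~obs)[0]:
        s = study[i]
        sig2 = sigma2_star.get(s, np.mean(list(sigma2_star.values())))
        p = pid[i]
        if fit.tau2 > 0 and p in resid_by_pid.index:
            k = n_obs_by_pid[p]
            shrink = fit.tau2 / (fit.tau2 + sig2 / k)
            b_mean = shrink * resid_by_pid[p]
            b_var = fit.tau2 * (1 - shrink)
        else:
            b_mean, b_var = 0.0, fit.tau2
        b = b_mean + np.sqrt(max(b_var, 0.0)) * rng.standard_normal()
        out[i] = X_all[i] @ beta_star + b + np.sqrt(sig2) * rng.standard_normal()
    return out


def impute_binary_probit(
    table: pd.DataFrame,
    target: str,
    predictors: list[str],
    seed: int,
    id_col: str = "participant_id",
    study_col: str = "study_id",
) -> np.ndarray:
    """One posterior-predictive completion of a binary variable via a
    random-intercept (participant) probit model."""
    rng = np.random.default_rng(seed)
    num_all = _numeric_frame(table)
    cols = [c for c in predictors if c in num_all.columns and c != target]
    X_all = np.column_stack([np.ones(len(table))] + [num_all[c].to_numpy() for c in cols])
    if np.isnan(X_all).any():
        col_means = np.nanmean(X_all, axis=0)
        X_all = np.where(np.isnan(X_all), col_means, X_all)
    y = table[target].to_numpy(dtype=float)
    obs = ~np.isnan(y)
    if obs.all():
        return y
    vals = np.unique(y[obs])
    if vals.size < 2:
        raise FitError(f"{target}: both classes must be present among complete cases")
    pid = table[id_col].to_numpy()

    # standardize non-constant columns: affine, so predictions are unchanged,
    # but the separation heuristic then applies on a comparable scale
    for j in range(1, X_all.shape[1]):
        sd = X_all[:, j].std()
        if sd > 1e-12:
            X_all[:, j] = (X_all[:, j] - X_all[:, j].mean()) / sd

    fit = fit_binary_random_intercept(X_all[obs], y[obs], pid[obs], link="probit")
    cov = 0.5 * (fit.cov_beta + fit.cov_beta.T)
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(fit.beta)))
    beta_star = fit.beta + L @ rng.standard_normal(len(fit.beta))

    out = y.copy()
    miss = np.where(~obs)[0]
    eta = X_all[miss] @ beta_star
    b = np.array([
        fit.group_effects.get(pid[i], 0.0)
        + (0.0 if pid[i] in fit.group_effects else fit.sigma_u * rng.standard_normal())
        for i in miss
    ])
    p = norm.cdf(eta + b)
    out[miss] = (rng.random(miss.size) < p).astype(float)
    return out


def run_mice(table: pd.DataFrame, spec: ImputationSpec) -> ImputedDatasets:
    """Chained-equations imputation producing ``spec.m`` completed tables.

    Variables are visited in order of increasing missingness.  Categorical
    variables (``spec.variables[name] == "categorical"``) are split into
    dummy indicators, imputed as binary, and reassembled by the most probable
    (first on ties) category.  Observed cells are identical across the m
    completed tables.
    """
    work = table.copy()
    study_dummies = pd.get_dummies(work[spec.study_col], prefix="study", drop_first=True, dtype=float)
    for c in study_dummies.columns:
        work[c] = study_dummies[c]
    always = tuple(study_dummies.columns)

    targets = {v: k for v, k in spec.variables.items() if work[v].isna().any()}
    # increasing missingness; continuous variables first at equal missingness
    order = sorted(
        targets, key=lambda v: (work[v].isna().mean(), targets[v] != "continuous")
    )

    predictor_sets = {}
    candidates = [c for c in work.columns if c not in (spec.id_col, spec.study_col)]
    for v in order:
        pool = work[[c for c in candidates if c != v]]
        if targets[v] == "categorical":
            # screen against each level indicator and pool the hits
            chosen: list[str] = []
            for lev in sorted(work[v].dropna().unique()):
                ind = (work[v] == lev).astype(float).where(work[v].notna())
                tmp = pd.concat([pool, ind.rename("_level")], axis=1)
                for c in select_predictors(tmp, "_level", spec.predictor_threshold):
                    if c not in chosen:
                        chosen.append(c)
            predictor_sets[v] = chosen + list(always)
        else:
            predictor_sets[v] = select_predictors(
                pd.concat([pool, work[[v]]], axis=1), v, spec.predictor_threshold,
                always=always,
            )

    chain_means: dict = {v: [] for v in order}
    datasets = []
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(spec.m)]
    for k in range(spec.m):
        rng = np.random.default_rng(child_seeds[k])
        cur = work.copy()
        # initial fill: sample observed values with replacement
        for v in order:
            miss = cur[v].isna()
            obs_vals = cur.loc[~miss, v].to_numpy()
            cur.loc[miss, v] = rng.choice(obs_vals, size=int(miss.sum()))
        if not order:
            datasets.append(cur.drop(columns=list(always)))
            continue
        means_k = {v: [] for v in order}
        for cycle in range(spec.cycles):
            for v in order:
                model = targets[v]
                miss_mask = work[v].isna()
                cur.loc[miss_mask, v] = np.nan
                preds = list(predictor_sets[v])
                seed_v = int(rng.integers(2**31 - 1))
                impute_fn = {
                    "continuous": impute_continuous_mixed,
                    "binary": impute_binary_probit,
                    "categorical": _impute_categorical,
                }.get(model)
                if impute_fn is None:
                    raise ValueError(f"{v}: unknown model type {model!r}")
                # on separation, retry without the strongest remaining predictor
                while True:
                    try:
                        cur[v] = impute_fn(cur, v, preds, seed_v, spec.id_col, spec.study_col)
                        break
                    except FitError:
                        droppable = [c for c in preds if c not in always]
                        if not droppable:
                            raise
                        preds.remove(droppable[0])
                vals = pd.to_numeric(cur.loc[miss_mask, v], errors="coerce")
                means_k[v].append(float(vals.mean()) if vals.notna().any() else np.nan)
        for v in order:
            chain_means[v].append(means_k[v])
        datasets.append(cur.drop(columns=list(always)))

    meta = {
        "m": spec.m,
        "cycles": spec.cycles,
        "seed": spec.seed,
        "visit_order": order,
        "predictor_sets": predictor_sets,
        "chain_means": chain_means,
    }
    return ImputedDatasets(datasets=datasets, metadata=meta)


def _impute_categorical(table, target, predictors, seed, id_col, study_col):
    """Split a multi-level variable into dummies, impute each as binary, and
    reassemble with a most-probable-category (first on ties) rule."""
    rng = np.random.default_rng(seed)
    y = table[target]
    obs = y.notna()
    levels = sorted(y[obs].unique())
    scores = pd.DataFrame(index=table.index, columns=levels, dtype=float)
    for lev in levels:
        t2 = table.copy()
        t2["_dummy"] = np.where(obs, (y == lev).astype(float), np.nan)
        scores[lev] = impute_binary_probit(
            t2, "_dummy", predictors, int(rng.integers(2**31 - 1)), id_col, study_col
        )
    out = y.copy()
    miss_idx = table.index[~obs]
    picked = scores.loc[miss_idx].idxmax(axis=1)  # first level wins ties
    out.loc[miss_idx] = picked
    return out


def chain_autocorrelation(chain_means: list[list[float]], burn_in: int = 2) -> float:
    """Lag-1 autocorrelation of per-cycle chain means, averaged over chains;
    a mixing diagnostic (values near 0 indicate fast mixing)."""
    acs = []
    for means in chain_means:
        x = np.asarray(means, dtype=float)[burn_in:]
        x = x[~np.isnan(x)]
        if x.size >= 3 and x.std() > 0:
            acs.append(float(np.corrcoef(x[:-1], x[1:])[0, 1]))
    return float(np.mean(acs)) if acs else 0.0
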