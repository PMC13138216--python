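"""Inferential models for acute and persistent PTSD/MDD after trauma.

Three analyses operate on the wide classified table (one row per
participant):

* Multinomial logistic regression of trajectory class (Never as reference,
  Acute and Persistent as outcomes) on the seven harmonized risk factors,
  with fixed study dummies; fit per imputed dataset and pooled by Rubin's
  rules on the log-odds scale.
* Likelihood-ratio tests of whether a risk factor's effect differs between
  the Acute and Persistent equations, comparing the unconstrained fit to one
  with the coefficient tied across equations; per-imputation chi-square
  statistics are combined by the D2 rule.
* Logistic models of persistence (Persistent = 1 vs Acute = 0) adding acute
  symptom severities in three nested specifications; odds ratios are scaled
  per 5 points for depression and PTSD cluster severities and per 15 points
  for total PTSD severity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist, f as f_dist, norm, ttest_ind
from scipy.stats import chi2_contingency

from ._glm import MLFit, equality_mapping, fit_multinomial_ml, check_separation
from .classify import Trajectory
from .mice import rubin_pool

RISK_FACTORS = [
    "age_c",
    "female",
    "single",
    "below_secondary",
    "prior_noninterp",
    "prior_interp",
    "index_other",
    "index_assault",
]

# odds-ratio scaling increments (points of severity per reported OR unit)
SEVERITY_INCREMENTS = {
    "w1_dep_severity": 5.0,
    "w1_ptsd_severity": 15.0,
    "w1_ptsd_B": 5.0,
    "w1_ptsd_C": 5.0,
    "w1_ptsd_D": 5.0,
}

OUTCOME_ORDER = [Trajectory.NEVER.value, Trajectory.ACUTE.value, Trajectory.PERSISTENT.value]


def risk_factor_design(
    df: pd.DataFrame, extra: tuple = (), study_dummies: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, the seven risk factors (age centred at 38,
    categorical factors dummy-coded against their reference levels),
    optional extra severity columns, and fixed study dummies."""
    cols = [np.ones(len(df))]
    labels = ["intercept"]
    base = {
        "age_c": df["age"].to_numpy(dtype=float) - 38.0,
        "female": df["female"].to_numpy(dtype=float),
        "single": df["single"].to_numpy(dtype=float),
        "below_secondary": df["below_secondary"].to_numpy(dtype=float),
        "prior_noninterp": (df["prior_trauma"] == "non-interpersonal").to_numpy(dtype=float),
        "prior_interp": (df["prior_trauma"] == "interpersonal").to_numpy(dtype=float),
        "index_other": (df["index_trauma"] == "other_accident").to_numpy(dtype=float),
        "index_assault": (df["index_trauma"] == "assault").to_numpy(dtype=float),
    }
    for name in RISK_FACTORS:
        cols.append(base[name])
        labels.append(name)
    for name in extra:
        cols.append(df[name].to_numpy(dtype=float))
        labels.append(name)
    if study_dummies:
        studies = sorted(df["study_id"].unique())
        for s in studies[1:]:
            cols.append((df["study_id"] == s).to_numpy(dtype=float))
            labels.append(f"study_{s}")
    return np.column_stack(cols), labels


@dataclass
class ModelFit:
    """Labelled model fit: packed coefficients with covariance."""

    fit: MLFit
    labels: list[str]
    outcome_levels: list[str]
    separation_flagged: bool = False

    def coef_frame(self) -> pd.DataFrame:
        p = len(self.labels)
        n_eq = len(self.outcome_levels) - 1
        beta = self.fit.params.reshape(p, n_eq, order="F")
        se = np.sqrt(np.clip(np.diag(self.fit.cov), 0, None)).reshape(p, n_eq, order="F")
        rows = []
        for k, lev in enumerate(self.outcome_levels[1:]):
            for j, lab in enumerate(self.labels):
                rows.append(
                    {"outcome": lev, "predictor": lab, "coef": beta[j, k], "se": se[j, k]}
                )
        return pd.DataFrame(rows)


def _subset_for_multinomial(df: pd.DataFrame, disorder: str) -> tuple[pd.DataFrame, np.ndarray]:
    col = f"{disorder}_trajectory"
    keep = df[col].isin(OUTCOME_ORDER)
    sub = df[keep].reset_index(drop=True)
    y = sub[col].map({lev: i for i, lev in enumerate(OUTCOME_ORDER)}).to_numpy()
    return sub, y


def fit_multinomial(
    df: pd.DataFrame,
    disorder: str,
    extra: tuple = (),
    study_dummies: bool = True,
) -> ModelFit:
    """Multinomial trajectory model (Never reference; Acute, Persistent).

    Participants with Delayed or Unclassifiable labels are excluded.  A fit
    with implausibly large coefficients is refit with a small ridge penalty
    and flagged.
    """
    sub, y = _subset_for_multinomial(df, disorder)
    if np.unique(y).size < 3:
        raise ValueError(f"{disorder}: need all three trajectory classes observed")
    X, labels = risk_factor_design(sub, extra=extra, study_dummies=study_dummies)
    fit = fit_multinomial_ml(X, y, n_categories=3)
    flagged = False
    if check_separation(fit):
        fit = fit_multinomial_ml(X, y, n_categories=3, ridge=1e-3)
        flagged = True
    return ModelFit(fit=fit, labels=labels, outcome_levels=OUTCOME_ORDER,
                    separation_flagged=flagged)


def pool_multinomial(
    tables: list[pd.DataFrame], disorder: str, study_dummies: bool = True
) -> pd.DataFrame:
    """Fit the multinomial model on each completed dataset and Rubin-pool.

    Returns the long odds-ratio table (risk factor x outcome) with 95% CIs.
    """
    frames = []
    for df in tables:
        mf = fit_multinomial(df, disorder, study_dummies=study_dummies)
        frames.append(mf.coef_frame())
    rows = []
    n = len(tables[0])
    for (outcome, pred), grp in frames[0].groupby(["outcome", "predictor"], sort=False):
        ests = [f.set_index(["outcome", "predictor"]).loc[(outcome, pred), "coef"] for f in frames]
        ses = [f.set_index(["outcome", "predictor"]).loc[(outcome, pred), "se"] for f in frames]
        if len(tables) >= 2:
            pooled = rubin_pool(ests, [s**2 for s in ses], n_complete=n)
            est, lo, hi, se = pooled.estimate, pooled.ci_low, pooled.ci_high, pooled.se
        else:
            est, se = ests[0], ses[0]
            lo, hi = est - 1.96 * se, est + 1.96 * se
        rows.append(
            {
                "disorder": disorder,
                "outcome": outcome,
                "predictor": pred,
                "log_or": est,
                "se": se,
                "or": np.exp(est),
                "or_low": np.exp(lo),
                "or_high": np.exp(hi),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    loglik_unconstrained: float
    loglik_constrained: float
    pooled: bool = False


def constrained_lrt(df: pd.DataFrame, disorder: str, predictor: str,
                    study_dummies: bool = True) -> LRTResult:
    """LRT of equal Acute and Persistent coefficients for one risk factor.

    The constrained model maximizes the same multinomial likelihood with the
    predictor's coefficient shared across the two non-reference equations
    (one equality constraint, so 1 df).
    """
    sub, y = _subset_for_multinomial(df, disorder)
    X, labels = risk_factor_design(sub, study_dummies=study_dummies)
    if predictor not in labels:
        raise ValueError(f"unknown predictor {predictor!r}")
    j = labels.index(predictor)
    fit_u = fit_multinomial_ml(X, y, n_categories=3)
    M = equality_mapping(X.shape[1], 2, [j])
    fit_c = fit_multinomial_ml(X, y, n_categories=3, mapping=M)
    stat = max(2.0 * (fit_u.loglik - fit_c.loglik), 0.0)
    return LRTResult(
        statistic=stat,
        df=1,
        p_value=float(chi2_dist.sf(stat, 1)),
        loglik_unconstrained=fit_u.loglik,
        loglik_constrained=fit_c.loglik,
    )


def pool_lrt_d2(statistics, df: int) -> tuple[float, float]:
    """D2 combination of per-imputation chi-square statistics.

    Returns (F statistic, p-value) on F(df, nu) reference; the standard
    moment-based rule for pooling likelihood-ratio chi-squares across
    imputations.
    """
    d = np.asarray(statistics, dtype=float)
    m = d.size
    if m < 2:
        return float(d[0] / df), float(chi2_dist.sf(d[0], df))
    sqrt_d = np.sqrt(np.clip(d, 0, None))
    r = (1 + 1 / m) * float(np.var(sqrt_d, ddof=1))
    D2 = (d.mean() / df - (m + 1) / (m - 1) * r) / (1 + r)
    D2 = max(D2, 0.0)
    nu = df ** (-3 / m) * (m - 1) * (1 + 1 / r) ** 2 if r > 0 else np.inf
    p = float(f_dist.sf(D2, df, nu)) if np.isfinite(nu) else float(chi2_dist.sf(D2 * df, df))
    return float(D2), p


def pooled_constrained_lrt(tables: list[pd.DataFrame], disorder: str, predictor: str,
                           study_dummies: bool = True) -> LRTResult:
    """Constrained-equality LRT repeated per imputed dataset, D2-combined."""
    results = [constrained_lrt(df, disorder, predictor, study_dummies) for df in tables]
    stats = [r.statistic for r in results]
    D2, p = pool_lrt_d2(stats, df=1)
    return LRTResult(
        statistic=float(np.mean(stats)),
        df=1,
        p_value=p,
        loglik_unconstrained=float(np.mean([r.loglik_unconstrained for r in results])),
        loglik_constrained=float(np.mean([r.loglik_constrained for r in results])),
        pooled=True,
    )


PERSISTENCE_MODEL_EXTRAS = {
    "ptsd": {
        1: ("w1_dep_severity",),
        2: ("w1_dep_severity", "w1_ptsd_severity"),
        3: ("w1_dep_severity", "w1_ptsd_B", "w1_ptsd_C", "w1_ptsd_D"),
    },
    "mdd": {
        1: ("w1_ptsd_severity",),
        2: ("w1_ptsd_severity", "w1_dep_severity"),
        3: ("w1_dep_severity", "w1_ptsd_B", "w1_ptsd_C", "w1_ptsd_D"),
    },
}


def fit_persistence_logistic(
    tables: list[pd.DataFrame],
    disorder: str,
    model: int,
    study_dummies: bool = True,
) -> pd.DataFrame:
    """Persistence (vs acute) logistic model per completed dataset, pooled.

    ``model`` selects the acute-severity adjustment set: 1 = the other
    disorder's acute severity; 2 = both disorders' severities; 3 = depression
    severity plus the three PTSD cluster severities.  Datasets missing one of
    the two outcome classes are excluded from pooling (counted in the output
    attrs).  Output rows carry ORs at their scaling increment.
    """
    if model not in (1, 2, 3):
        raise ValueError("model must be 1, 2 or 3")
    extras = PERSISTENCE_MODEL_EXTRAS[disorder][model]
    col = f"{disorder}_trajectory"
    per_fit = []
    skipped = 0
    labels = None
    for df in tables:
        sub = df[df[col].isin([Trajectory.ACUTE.value, Trajectory.PERSISTENT.value])]
        sub = sub.reset_index(drop=True)
        y = (sub[col] == Trajectory.PERSISTENT.value).to_numpy(dtype=int)
        if y.min() == y.max():
            skipped += 1
            continue
        X, labels = risk_factor_design(sub, extra=extras, study_dummies=study_dummies)
        fit = fit_multinomial_ml(X, y, n_categories=2)
        if check_separation(fit):
            fit = fit_multinomial_ml(X, y, n_categories=2, ridge=1e-2)
        se = np.sqrt(np.clip(np.diag(fit.cov), 0, None))
        per_fit.append((fit.params, se, len(sub)))
    if not per_fit:
        raise ValueError(f"{disorder}: no completed dataset had both outcome classes")
    rows = []
    n = per_fit[0][2]
    for j, lab in enumerate(labels):
        inc = SEVERITY_INCREMENTS.get(lab, 1.0)
        ests = [p[0][j] for p in per_fit]
        vars_ = [p[1][j] ** 2 for p in per_fit]
        if len(per_fit) >= 2:
            pooled = rubin_pool(ests, vars_, n_complete=n)
            est, lo, hi = pooled.estimate, pooled.ci_low, pooled.ci_high
        else:
            est = ests[0]
            lo, hi = est - 1.96 * np.sqrt(vars_[0]), est + 1.96 * np.sqrt(vars_[0])
        rows.append(
            {
                "disorder": disorder,
                "model": model,
                "predictor": lab,
                "increment": inc,
                "or": np.exp(est * inc),
                "or_low": np.exp(lo * inc),
                "or_high": np.exp(hi * inc),
                "log_or_per_unit": est,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["skipped_datasets"] = skipped
    return out


CATEGORICAL_DESCRIPTORS = {
    "female": None,
    "single": None,
    "below_secondary": None,
    "prior_trauma": ["none", "non-interpersonal", "interpersonal"],
    "index_trauma": ["MVA", "other_accident", "assault"],
}
CONTINUOUS_DESCRIPTORS = ["age", "w1_ptsd_severity", "w1_dep_severity"]


def describe_groups(table: pd.DataFrame, disorder: str) -> pd.DataFrame:
    """Descriptive statistics by trajectory group (Never/Acute/Persistent
    plus a Missing column for unclassifiable participants).

    Percentages use each variable's non-missing denominator within the
    group; continuous variables report mean (SD).  Group differences across
    Never/Acute/Persistent use Welch t-tests (largest-vs-reference contrast
    supplemented by a chi-square for categorical variables).
    """
    col = f"{disorder}_trajectory"
    groups = {
        "Never": table[table[col] == Trajectory.NEVER.value],
        "Acute": table[table[col] == Trajectory.ACUTE.value],
        "Persistent": table[table[col] == Trajectory.PERSISTENT.value],
        "Missing": table[table[col] == Trajectory.UNCLASSIFIABLE.value],
    }
    if any(len(g) == 0 for n, g in groups.items() if n != "Missing"):
        empty = [n for n, g in groups.items() if len(g) == 0 and n != "Missing"]
        raise ValueError(f"empty trajectory group(s): {empty}; percentages undefined")
    rows = []
    for var, levels in CATEGORICAL_DESCRIPTORS.items():
        if var not in table.columns:
            continue
        if levels is None:  # binary flag
            obs_groups = []
            for gname, g in groups.items():
                s = g[var].dropna()
                n_true = int(s.astype(bool).sum())
                denom = len(s)
                rows.append(
                    {
                        "variable": var,
                        "level": "yes",
                        "group": gname,
                        "n": n_true,
                        "denominator": denom,
                        "pct": 100.0 * n_true / denom if denom else np.nan,
                    }
                )
                if gname != "Missing" and denom:
                    obs_groups.append((np.array([n_true, denom - n_true])))
            if len(obs_groups) == 3:
                try:
                    p = chi2_contingency(np.array(obs_groups))[1]
                except ValueError:
                    p = np.nan
                for r in rows[-4:]:
                    r["p_value"] = p
        else:
            contingency = []
            for gname, g in groups.items():
                s = g[var].dropna()
                denom = int(s.isin(levels).sum())
                counts = []
                for lev in levels:
                    n_lev = int((s == lev).sum())
                    counts.append(n_lev)
                    rows.append(
                        {
                            "variable": var,
                            "level": lev,
                            "group": gname,
                            "n": n_lev,
                            "denominator": denom,
                            "pct": 100.0 * n_lev / denom if denom else np.nan,
                        }
                    )
                if gname != "Missing":
                    contingency.append(counts)
            ct = np.array(contingency)
            ct = ct[:, ct.sum(axis=0) > 0]
            try:
                p = chi2_contingency(ct)[1] if ct.size else np.nan
            except ValueError:
                p = np.nan
            for r in rows[-4 * len(levels):]:
                r["p_value"] = p
    for var in CONTINUOUS_DESCRIPTORS:
        if var not in table.columns:
            continue
        never = groups["Never"][var].dropna()
        for gname, g in groups.items():
            s = g[var].dropna()
            p = np.nan
            if gname in ("Acute", "Persistent") and len(s) > 1 and len(never) > 1:
                p = float(ttest_ind(never, s, equal_var=False).pvalue)
            rows.append(
                {
                    "variable": var,
                    "level": "mean",
                    "group": gname,
                    "n": len(s),
                    "denominator": len(s),
                    "mean": float(s.mean()) if len(s) else np.nan,
                    "sd": float(s.std(ddof=1)) if len(s) > 1 else np.nan,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
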