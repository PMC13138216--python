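"""Study-heterogeneity diagnostics via bootstrap out-of-bag calibration.

A pooled multi-study model can hide between-study heterogeneity.  The check
implemented here resamples participants with replacement, fits a persistence
model on the in-bag sample (fixed study dummies, or a random study intercept
fit by Gauss-Hermite quadrature), predicts the out-of-bag participants (those
never drawn, about 36.8% of the pool), and accumulates two per-study
statistics: the expected/observed ratio (sum of predicted probabilities over
observed events; above 1 means over-prediction) and the Brier score (mean
squared difference between predicted probability and outcome).  Statistics
are averaged over replicates and then over imputed datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._glm import FitError, fit_binary_random_intercept, fit_multinomial_ml
from .classify import PERSISTENT_WINDOW, Trajectory, assign_trajectory
from .models import risk_factor_design


def brier_score(probs: np.ndarray, outcomes: np.ndarray) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != y.shape:
        raise ValueError("probs and outcomes must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def expected_observed_ratio(
    probs: np.ndarray, outcomes: np.ndarray, study_labels: np.ndarray
) -> dict:
    """Per-study ratio of expected events (sum of predicted probabilities) to
    observed events.  Studies with zero observed events get ``nan``."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    s = np.asarray(study_labels)
    out = {}
    for study in np.unique(s):
        sel = s == study
        observed = y[sel].sum()
        out[study] = float(p[sel].sum() / observed) if observed > 0 else np.nan
    return out


@dataclass
class CalibrationReport:
    """Per-study calibration summary from bootstrap out-of-bag evaluation."""

    table: pd.DataFrame  # study, eo_ratio, brier, n_replicates_used
    model_type: str
    disorder: str
    n_bootstrap: int
    n_imputations: int
    skipped_replicates: int


def _persistence_outcome(df: pd.DataFrame, disorder: str) -> np.ndarray:
    return (df[f"{disorder}_trajectory"] == Trajectory.PERSISTENT.value).to_numpy(dtype=float)


def _fit_predict(train: pd.DataFrame, test: pd.DataFrame, disorder: str, model_type: str):
    y_tr = _persistence_outcome(train, disorder)
    if y_tr.min() == y_tr.max():
        raise FitError("in-bag sample has a single outcome class")
    if model_type == "fixed":
        X_tr, labels = risk_factor_design(train, study_dummies=False)
        studies = sorted(train["study_id"].unique())
        for s in studies[1:]:
            X_tr = np.column_stack([X_tr, (train["study_id"] == s).to_numpy(dtype=float)])
        fit = fit_multinomial_ml(X_tr, y_tr.astype(int), n_categories=2)
        if np.any(np.abs(fit.params) > 15):
            fit = fit_multinomial_ml(X_tr, y_tr.astype(int), n_categories=2, ridge=1e-2)
        X_te, _ = risk_factor_design(test, study_dummies=False)
        for s in studies[1:]:
            X_te = np.column_stack([X_te, (test["study_id"] == s).to_numpy(dtype=float)])
        eta = X_te @ fit.params
        return 1.0 / (1.0 + np.exp(-eta))
    if model_type == "pooled":
        # no study adjustment at all: the miscalibration baseline
        X_tr, _ = risk_factor_design(train, study_dummies=False)
        fit = fit_multinomial_ml(X_tr, y_tr.astype(int), n_categories=2)
        if np.any(np.abs(fit.params) > 15):
            fit = fit_multinomial_ml(X_tr, y_tr.astype(int), n_categories=2, ridge=1e-2)
        X_te, _ = risk_factor_design(test, study_dummies=False)
        return 1.0 / (1.0 + np.exp(-(X_te @ fit.params)))
    if model_type == "random":
        X_tr, _ = risk_factor_design(train, study_dummies=False)
        fit = fit_binary_random_intercept(
            X_tr, y_tr, train["study_id"].to_numpy(), link="logit"
        )
        X_te, _ = risk_factor_design(test, study_dummies=False)
        # empirical-Bayes study intercept where the study was in-bag,
        # otherwise the population (zero) intercept
        b = np.array([fit.group_effects.get(s, 0.0) for s in test["study_id"]])
        eta = X_te @ fit.beta + b
        return 1.0 / (1.0 + np.exp(-eta))
    raise ValueError(f"unknown model type {model_type!r}")


def bootstrap_calibration(
    tables: list[pd.DataFrame],
    disorder: str,
    model_type: str = "fixed",
    n_bootstrap: int = 100,
    seed: int = 0,
) -> CalibrationReport:
    """Bootstrap out-of-bag calibration of the persistent-vs-rest model.

    ``tables`` are completed (imputed) wide datasets; pass a singleton list
    for a complete-case run.  Deterministic under a fixed seed.
    """
    if n_bootstrap < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    studies = sorted(tables[0]["study_id"].unique())
    acc_eo = {s: [] for s in studies}
    acc_brier = {s: [] for s in studies}
    skipped = 0
    for df in tables:
        df = df[df[f"{disorder}_trajectory"].isin(
            [t.value for t in (Trajectory.NEVER, Trajectory.ACUTE,
                               Trajectory.PERSISTENT, Trajectory.DELAYED)]
        )].reset_index(drop=True)
        n = len(df)
        for _ in range(n_bootstrap):
            draw = rng.integers(0, n, size=n)
            oob_mask = np.ones(n, dtype=bool)
            oob_mask[np.unique(draw)] = False
            if not oob_mask.any():
                skipped += 1
                continue
            train = df.iloc[draw].reset_index(drop=True)
            test = df.iloc[oob_mask].reset_index(drop=True)
            try:
                probs = _fit_predict(train, test, disorder, model_type)
            except FitError:
                skipped += 1
                continue
            y = _persistence_outcome(test, disorder)
            s_lab = test["study_id"].to_numpy()
            eos = expected_observed_ratio(probs, y, s_lab)
            for s in studies:
                if s in eos and np.isfinite(eos[s]):
                    acc_eo[s].append(eos[s])
                sel = s_lab == s
                if sel.any():
                    acc_brier[s].append(brier_score(probs[sel], y[sel]))
    rows = [
        {
            "study": s,
            "eo_ratio": float(np.mean(acc_eo[s])) if acc_eo[s] else np.nan,
            "brier": float(np.mean(acc_brier[s])) if acc_brier[s] else np.nan,
            "n_replicates_used": len(acc_brier[s]),
        }
        for s in studies
    ]
    return CalibrationReport(
        table=pd.DataFrame(rows),
        model_type=model_type,
        disorder=disorder,
        n_bootstrap=n_bootstrap,
        n_imputations=len(tables),
        skipped_replicates=skipped,
    )


def leave_one_study_out(tables: list[pd.DataFrame], excluded_study: str):
    """Completed datasets with one study dropped, for sensitivity refits.

    Returns the reduced tables; rerun the risk models on them to obtain the
    leave-one-study-out odds-ratio tables (same schema as the primary run).
    """
    remaining = [t[t["study_id"] != excluded_study].reset_index(drop=True) for t in tables]
    n_left = remaining[0]["study_id"].nunique()
    if n_left < 2:
        raise ValueError("leave-one-study-out needs at least 2 remaining studies")
    return remaining


def restrict_followup_window(table: pd.DataFrame, window: tuple) -> pd.DataFrame:
    """Re-derive trajectories after restricting the follow-up window.

    Wave-2 assessments outside ``window`` (within the admissible persistent
    range) are set to unobserved and every trajectory label is recomputed.
    """
    lo, hi = window
    if lo < PERSISTENT_WINDOW[0] or hi > PERSISTENT_WINDOW[1] or lo >= hi:
        raise ValueError(f"window must lie within {PERSISTENT_WINDOW}, got {window}")
    out = table.copy()
    outside = (out["w2_day"] < lo) | (out["w2_day"] > hi)
    for col in ("w2_ptsd_dx", "w2_mdd_dx", "w2_ptsd_severity", "w2_dep_severity",
                "w2_ptsd_B", "w2_ptsd_C", "w2_ptsd_D"):
        if col in out.columns:
            out.loc[outside, col] = np.nan
    for dis in ("ptsd", "mdd"):
        labels = []
        for _, row in out.iterrows():
            w1 = row.get(f"w1_{dis}_dx")
            w2 = row.get(f"w2_{dis}_dx")
            if w1 != w1:
                labels.append(Trajectory.UNCLASSIFIABLE.value)
            else:
                labels.append(
                    assign_trajectory(bool(w1), None if w2 != w2 else bool(w2)).value
                )
        out[f"{dis}_trajectory"] = labels
    n_classifiable = (out["ptsd_trajectory"] != Trajectory.UNCLASSIFIABLE.value).sum()
    if n_classifiable == 0:
        raise ValueError("no participant has a follow-up inside the window")
    return out
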