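"""Diagnosis scoring, trajectory labels, and covariate harmonization.

PTSD is scored from the 17-symptom CAPS (DSM-IV): each symptom is rated for
frequency (0-4) and intensity (0-4); severity is the sum of frequency and
intensity over all symptoms (0-136).  A symptom is present when frequency >= 1
and intensity >= 2; the diagnosis requires at least one reexperiencing
(criterion B, symptoms 1-5), three avoidance (criterion C, symptoms 6-12) and
two hyperarousal (criterion D, symptoms 13-17) symptoms.  Duration and
impairment criteria are not evaluated (not collected consistently across the
contributing cohorts).

Probable MDD uses BDI >= 20 directly, or the equated-BDI threshold for HADS
studies (HADS >= 13 under the packaged crosswalk).

A participant assessed in the acute window (0-60 days post-trauma) and the
persistent window (122-456 days) is labelled Never / Acute / Persistent from
the pair of wave diagnoses; the uncommon diagnosis-only-at-follow-up pattern
is labelled Delayed and a missing follow-up is Unclassifiable until resolved
by imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .equating import Crosswalk, equate_score

# CAPS symptom indices (1-based) per DSM-IV cluster
CRITERION_B = list(range(1, 6))       # reexperiencing
CRITERION_C = list(range(6, 13))      # avoidance
CRITERION_D = list(range(13, 18))     # hyperarousal

ACUTE_WINDOW = (0, 60)
PERSISTENT_WINDOW = (122, 456)

BDI_PROBABLE_MDD = 20
BDI_RANGE = (0, 63)
HADS_RANGE = (0, 21)


class Trajectory(str, Enum):
    NEVER = "Never"
    ACUTE = "Acute"
    PERSISTENT = "Persistent"
    DELAYED = "Delayed"
    UNCLASSIFIABLE = "Unclassifiable-missing"


@dataclass
class PTSDAssessment:
    total_severity: int
    cluster_severities: dict[str, int]
    diagnosis: bool
    symptom_present: np.ndarray


def score_caps(frequency: np.ndarray, intensity: np.ndarray) -> PTSDAssessment:
    """Score one CAPS record (17 frequency and 17 intensity ratings, 0-4)."""
    freq = np.asarray(frequency, dtype=float)
    inten = np.asarray(intensity, dtype=float)
    if freq.shape != (17,) or inten.shape != (17,):
        raise ValueError("expected 17 frequency and 17 intensity ratings")
    for name, arr in (("frequency", freq), ("intensity", inten)):
        bad = np.where((arr < 0) | (arr > 4) | ~np.isfinite(arr))[0]
        if bad.size:
            raise ValueError(f"{name} rating out of range 0-4 at symptom {bad[0] + 1}")

    item_sev = freq + inten
    b_idx = np.array(CRITERION_B) - 1
    c_idx = np.array(CRITERION_C) - 1
    d_idx = np.array(CRITERION_D) - 1
    clusters = {
        "B": int(item_sev[b_idx].sum()),
        "C": int(item_sev[c_idx].sum()),
        "D": int(item_sev[d_idx].sum()),
    }
    present = (freq >= 1) & (inten >= 2)
    diagnosis = (
        present[b_idx].sum() >= 1
        and present[c_idx].sum() >= 3
        and present[d_idx].sum() >= 2
    )
    return PTSDAssessment(
        total_severity=int(item_sev.sum()),
        cluster_severities=clusters,
        diagnosis=bool(diagnosis),
        symptom_present=present,
    )


def score_caps_table(freq: np.ndarray, inten: np.ndarray) -> pd.DataFrame:
    """Vectorized CAPS scoring for (n, 17) frequency and intensity arrays."""
    freq = np.asarray(freq, dtype=float)
    inten = np.asarray(inten, dtype=float)
    if freq.ndim != 2 or freq.shape[1] != 17 or freq.shape != inten.shape:
        raise ValueError("expected (n, 17) frequency and intensity arrays")
    if ((freq < 0) | (freq > 4)).any() or ((inten < 0) | (inten > 4)).any():
        raise ValueError("CAPS ratings must lie in 0-4")
    sev = freq + inten
    b = slice(0, 5)
    c = slice(5, 12)
    d = slice(12, 17)
    present = (freq >= 1) & (inten >= 2)
    return pd.DataFrame(
        {
            "ptsd_severity": sev.sum(axis=1).astype(int),
            "severity_B": sev[:, b].sum(axis=1).astype(int),
            "severity_C": sev[:, c].sum(axis=1).astype(int),
            "severity_D": sev[:, d].sum(axis=1).astype(int),
            "ptsd_dx": (
                (present[:, b].sum(axis=1) >= 1)
                & (present[:, c].sum(axis=1) >= 3)
                & (present[:, d].sum(axis=1) >= 2)
            ),
        }
    )


def classify_mdd(score: int, instrument: str, xwalk: Crosswalk) -> tuple[bool, int]:
    """Probable-MDD flag and equated (BDI-metric) severity for one total score."""
    score = int(score)
    if instrument == "BDI":
        lo, hi = BDI_RANGE
        if not lo <= score <= hi:
            raise ValueError(f"BDI score {score} outside [{lo}, {hi}]")
        return score >= BDI_PROBABLE_MDD, score
    if instrument == "HADS":
        lo, hi = HADS_RANGE
        if not lo <= score <= hi:
            raise ValueError(f"HADS score {score} outside [{lo}, {hi}]")
        equated = equate_score(xwalk, score)
        return equated >= BDI_PROBABLE_MDD, equated
    raise ValueError(f"unknown instrument {instrument!r}")


class WindowViolationError(ValueError):
    pass


def assign_trajectory(
    wave1_dx: bool,
    wave2_dx: bool | None,
    wave1_day: float | None = None,
    wave2_day: float | None = None,
) -> Trajectory:
    """Trajectory label from the pair of wave diagnoses.

    ``wave2_dx=None`` marks a missing follow-up assessment.  Assessment days,
    when given, are validated against the acute [0, 60] and persistent
    [122, 456] windows (closed intervals).
    """
    if wave1_day is not None and not ACUTE_WINDOW[0] <= wave1_day <= ACUTE_WINDOW[1]:
        raise WindowViolationError(
            f"acute assessment at day {wave1_day} outside {ACUTE_WINDOW}"
        )
    if wave2_dx is not None and wave2_day is not None:
        if not PERSISTENT_WINDOW[0] <= wave2_day <= PERSISTENT_WINDOW[1]:
            raise WindowViolationError(
                f"follow-up assessment at day {wave2_day} outside {PERSISTENT_WINDOW}"
            )
    if wave2_dx is None:
        return Trajectory.UNCLASSIFIABLE
    if wave1_dx and wave2_dx:
        return Trajectory.PERSISTENT
    if wave1_dx:
        return Trajectory.ACUTE
    if wave2_dx:
        return Trajectory.DELAYED
    return Trajectory.NEVER


@dataclass(frozen=True)
class RiskFactorVector:
    age: float
    female: bool
    single_not_cohabiting: bool
    below_secondary_education: bool
    prior_trauma: str   # none | non-interpersonal | interpersonal
    index_trauma: str   # MVA | other_accident | assault

    def __post_init__(self):
        if self.prior_trauma not in {"none", "non-interpersonal", "interpersonal"}:
            raise ValueError(f"invalid prior_trauma {self.prior_trauma!r}")
        if self.index_trauma not in {"MVA", "other_accident", "assault"}:
            raise ValueError(f"invalid index_trauma {self.index_trauma!r}")


class HarmonizationError(KeyError):
    pass


def load_harmonization_yaml(path) -> dict:
    """Per-study harmonization dictionaries from a YAML file: top-level keys
    are study ids, values are the field mappings `harmonize_covariates`
    expects."""
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def harmonize_covariates(raw: dict, mapping: dict, study_id: str = "?") -> RiskFactorVector:
    """Map study-specific raw covariate codes onto the pooled risk-factor set.

    ``mapping`` supplies per-field dictionaries from raw codes to harmonized
    values (fields ``sex``, ``marital``, ``education``, ``index_trauma``).
    Prior traumas are supplied as a list of type strings classified by
    ``mapping['prior_trauma_types']`` into interpersonal or non-interpersonal;
    any interpersonal exposure dominates, any exposure at all beats none.
    """

    def look(field, code):
        table = mapping.get(field, {})
        if code not in table:
            raise HarmonizationError(
                f"study {study_id}: unmapped {field} code {code!r}"
            )
        return table[code]

    female = bool(look("sex", raw["sex"]))
    single = bool(look("marital", raw["marital"]))
    below_sec = bool(look("education", raw["education"]))
    index = look("index_trauma", raw["index_trauma"])

    priors = raw.get("prior_traumas", []) or []
    if not priors:
        prior = "none"
    else:
        kinds = {look("prior_trauma_types", t) for t in priors}
        prior = "interpersonal" if "interpersonal" in kinds else "non-interpersonal"

    return RiskFactorVector(
        age=float(raw["age"]),
        female=female,
        single_not_cohabiting=single,
        below_secondary_education=below_sec,
        prior_trauma=prior,
        index_trauma=index,
    )


def classify_cohort(cohort: pd.DataFrame, xwalk: Crosswalk) -> pd.DataFrame:
    """Build the wide analysis table (one row per participant) from a tidy
    participant-wave cohort.

    Expects the column layout produced by :mod:`traumameta.synth`:
    ``participant_id, study_id, wave, days_since_trauma``, CAPS columns
    ``caps{i}_freq`` / ``caps{i}_int``, a depression total in ``dep_total``
    with its ``instrument``, observedness flags ``ptsd_observed`` /
    ``dep_observed``, and the harmonized covariates.
    """
    caps_f = [f"caps{i}_freq" for i in range(1, 18)]
    caps_i = [f"caps{i}_int" for i in range(1, 18)]
    covars = [
        "age",
        "female",
        "single",
        "below_secondary",
        "prior_trauma",
        "index_trauma",
    ]
    rows = []
    for pid, grp in cohort.groupby("participant_id", sort=True):
        grp = grp.sort_values("wave")
        if len(grp) != 2:
            raise ValueError(f"participant {pid} must have exactly 2 waves")
        w1, w2 = grp.iloc[0], grp.iloc[1]
        rec = {"participant_id": pid, "study_id": w1["study_id"],
               "instrument": w1["instrument"]}
        for c in covars:
            rec[c] = w1[c]
        for wave, row in (("w1", w1), ("w2", w2)):
            rec[f"{wave}_day"] = row["days_since_trauma"]
            if row["ptsd_observed"]:
                scored = score_caps(
                    row[caps_f].to_numpy(dtype=float),
                    row[caps_i].to_numpy(dtype=float),
                )
                rec[f"{wave}_ptsd_severity"] = scored.total_severity
                rec[f"{wave}_ptsd_B"] = scored.cluster_severities["B"]
                rec[f"{wave}_ptsd_C"] = scored.cluster_severities["C"]
                rec[f"{wave}_ptsd_D"] = scored.cluster_severities["D"]
                rec[f"{wave}_ptsd_dx"] = scored.diagnosis
            else:
                for k in ("ptsd_severity", "ptsd_B", "ptsd_C", "ptsd_D", "ptsd_dx"):
                    rec[f"{wave}_{k}"] = np.nan
            if row["dep_observed"]:
                flag, equated = classify_mdd(
                    int(row["dep_total"]), row["instrument"], xwalk
                )
                rec[f"{wave}_dep_severity"] = equated
                rec[f"{wave}_mdd_dx"] = flag
            else:
                rec[f"{wave}_dep_severity"] = np.nan
                rec[f"{wave}_mdd_dx"] = np.nan
        for dis, col in (("ptsd", "ptsd_dx"), ("mdd", "mdd_dx")):
            w1_dx = rec[f"w1_{col}"]
            w2_dx = rec[f"w2_{col}"]
            if w1_dx != w1_dx:  # NaN: acute assessment itself missing
                rec[f"{dis}_trajectory"] = Trajectory.UNCLASSIFIABLE.value
            else:
                rec[f"{dis}_trajectory"] = assign_trajectory(
                    bool(w1_dx),
                    None if w2_dx != w2_dx else bool(w2_dx),
                    rec["w1_day"],
                    rec["w2_day"] if w2_dx == w2_dx else None,
                ).value
        rows.append(rec)
    return pd.DataFrame(rows)
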