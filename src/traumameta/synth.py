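"""Synthetic multi-study trauma cohorts with known generative truth.

The generator emulates the structure of a pooled emergency-room consortium:
five studies of different sizes and countries, CAPS PTSD interviews at an
acute (0-60 days) and a follow-up (122-456 days) wave, depression measured by
the BDI-II in some studies and the HADS depression subscale in others, seven
harmonized baseline risk factors, and study-specific follow-up loss.

Trajectory classes (Never / Acute / Persistent / Delayed) per disorder are
sampled from a multinomial logistic model in the risk factors, so the
generative log-odds are exactly the estimands the downstream models target.
Comorbidity between the two disorders enters through a Gaussian copula on the
class draws, which leaves each disorder's marginal class model intact.  Item
responses are then drawn from a graded response model given wave-specific
latent severities consistent with the class, and minimally projected so that
re-scoring the items reproduces the intended diagnoses exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .grm import GRMParameters, category_probabilities

ACUTE_BOUNDS = (0.0, 60.0)
PERSISTENT_BOUNDS = (122.0, 456.0)

CLASS_LEVELS = ["Never", "Acute", "Persistent", "Delayed"]
# diagnosis pattern (wave1, wave2) implied by each class
CLASS_TO_DX = {
    "Never": (False, False),
    "Acute": (True, False),
    "Persistent": (True, True),
    "Delayed": (False, True),
}

PREDICTORS = [
    "age_c",
    "female",
    "single",
    "below_secondary",
    "prior_noninterp",
    "prior_interp",
    "index_other",
    "index_assault",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class StudyConfig:
    study_id: str
    n_participants: int
    instrument: str  # "BDI" or "HADS"
    setting: str = "ER"
    acute_day_mean: float = 20.0
    acute_day_sd: float = 8.0
    persistent_day_mean: float = 250.0
    persistent_day_sd: float = 60.0
    followup_rate: float = 0.75

    def __post_init__(self):
        if self.n_participants < 1:
            raise ConfigurationError(f"{self.study_id}: n_participants must be >= 1")
        if self.instrument not in {"BDI", "HADS"}:
            raise ConfigurationError(f"{self.study_id}: instrument must be BDI or HADS")
        if not 0.0 < self.followup_rate <= 1.0:
            raise ConfigurationError(f"{self.study_id}: followup_rate must be in (0, 1]")


def default_study_configs(scale: float = 1.0) -> list[StudyConfig]:
    """Five studies shaped like the contributing consortium cohorts: sample
    sizes, depression instrument, care setting, assessment timing and
    follow-up rates.  ``scale`` shrinks every study proportionally for
    desk-scale runs (minimum 20 participants per study)."""
    raw = [
        ("multisite_asd", 1082, "HADS", "ER", 6.8, 7.1, 366.8, 46.7, 0.764),
        ("hadassah_startle", 118, "BDI", "ER", 37.6, 9.2, 153.3, 38.2, 0.873),
        ("jtops", 735, "BDI", "ER", 19.4, 5.2, 201.5, 77.0, 0.720),
        ("tcom", 155, "HADS", "CCU", 38.9, 6.1, 201.0, 28.5, 0.594),
        ("amsterdam_cortisol", 481, "HADS", "ER", 42.1, 8.6, 327.0, 95.4, 0.726),
    ]
    return [
        StudyConfig(
            study_id=s,
            n_participants=max(20, int(round(n * scale))),
            instrument=inst,
            setting=setting,
            acute_day_mean=am,
            acute_day_sd=asd,
            persistent_day_mean=pm,
            persistent_day_sd=psd,
            followup_rate=fr,
        )
        for s, n, inst, setting, am, asd, pm, psd, fr in raw
    ]


def _default_effects() -> dict:
    """Default covariate log-odds on trajectory class, scaled to the
    odds ratios the pooled risk-factor models typically report (female
    excess risk, assaultive index trauma excess, accident deficit)."""
    ln = np.log
    return {
        "ptsd": {
            "Acute": {
                "intercept": -1.75,
                "age_c": -0.005,
                "female": ln(1.86),
                "index_assault": ln(1.76),
                "index_other": ln(0.50),
                "prior_noninterp": ln(0.68),
                "prior_interp": ln(0.63),
            },
            "Persistent": {
                "intercept": -2.60,
                "age_c": -0.005,
                "female": ln(2.14),
                "index_assault": ln(1.78),
                "index_other": ln(0.45),
                "prior_noninterp": ln(0.80),
                "prior_interp": ln(0.80),
            },
            "Delayed": {"intercept": -4.5},
        },
        "mdd": {
            "Acute": {
                "intercept": -2.30,
                "age_c": -0.008,
                "female": ln(1.54),
                "index_assault": ln(1.50),
                "index_other": ln(0.50),
            },
            "Persistent": {
                "intercept": -3.00,
                "age_c": -0.005,
                "female": ln(1.48),
                "index_assault": ln(1.50),
                "index_other": ln(0.40),
            },
            "Delayed": {"intercept": -4.5},
        },
    }


def default_item_bank(bank_seed: int = 20240101) -> dict[str, GRMParameters]:
    """Item bank for the generator: 21 BDI items and 7 HADS items (0-3),
    34 CAPS rating scales (frequency and intensity per 17 symptoms, 0-4),
    and 3 CAPS-derived anchor items (0-4).

    Discriminations are log-normal(0, 0.3); thresholds are sorted normal
    draws.  Anchor items get discrimination 1.5 to stabilize linking.
    """
    rng = np.random.default_rng(bank_seed)

    def make(labels, n_thresh, mean, spread, anchors=(), log_a_mean=0.0, log_a_sd=0.3):
        a = np.exp(rng.normal(log_a_mean, log_a_sd, size=len(labels)))
        bs = []
        for lab in labels:
            b = np.sort(rng.normal(mean, spread, size=n_thresh))
            b += 1e-3 * np.arange(n_thresh)  # guard against ties
            bs.append(b)
        anchor = np.array([lab in anchors for lab in labels])
        a[anchor] = 1.5
        return GRMParameters(labels=list(labels), discriminations=a, thresholds=bs, anchor=anchor)

    # depression items are hard and discriminating enough that the
    # moderate-severity cut (BDI 20) falls in the upper tail of the latent
    # distribution, as it does for clinical instruments in acute-trauma
    # populations
    bdi = make([f"bdi_{j}" for j in range(1, 22)], 3, 2.2, 1.3, log_a_mean=0.5, log_a_sd=0.25)
    hads = make([f"hads_{j}" for j in range(1, 8)], 3, 2.2, 1.3, log_a_mean=0.5, log_a_sd=0.25)
    caps = make(
        [f"caps{i}_freq" for i in range(1, 18)] + [f"caps{i}_int" for i in range(1, 18)],
        4,
        1.3,
        0.9,
    )
    anchor_labels = ["anchor_C4", "anchor_D1", "anchor_D3"]
    anchors = make(anchor_labels, 4, 1.3, 0.9, anchors=anchor_labels)
    return {"BDI": bdi, "HADS": hads, "CAPS": caps, "ANCHOR": anchors}


@dataclass
class GenerativeParams:
    theta_study_shift: dict = field(default_factory=dict)
    theta_wave_corr: float = 0.7
    dep_ptsd_corr: float = 0.6
    item_bank: dict = None
    covariate_effects: dict = None
    missing_mechanism: str = "MCAR"  # or "MAR"
    extra_dep_missing: float = 0.18  # extra wave-2 depression loss beyond PTSD
    mar_severity_slope: float = 0.8  # MAR: log-odds of loss per SD of wave-1 severity

    def __post_init__(self):
        for name, r in (("theta_wave_corr", self.theta_wave_corr),
                        ("dep_ptsd_corr", self.dep_ptsd_corr)):
            if not -1.0 < r < 1.0:
                raise ConfigurationError(f"{name} must lie strictly inside (-1, 1), got {r}")
        if self.missing_mechanism not in {"MCAR", "MAR"}:
            raise ConfigurationError(f"unknown missing_mechanism {self.missing_mechanism!r}")
        if self.item_bank is None:
            self.item_bank = default_item_bank()
        for key, bank in self.item_bank.items():
            try:
                bank.validate()
            except ValueError as exc:
                raise ConfigurationError(f"item bank {key!r}: {exc}") from exc
        if self.covariate_effects is None:
            self.covariate_effects = _default_effects()


@dataclass
class MultiStudyCohort:
    """Tidy participant-wave table plus the generative truth behind it."""

    data: pd.DataFrame
    truth: pd.DataFrame
    params_sidecar: dict

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def write_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.params_sidecar, fh, indent=1, default=str)


def generate_item_responses(theta: np.ndarray, items: GRMParameters, seed: int) -> np.ndarray:
    """Draw ordinal responses from the graded response model given ``theta``.

    Returns an integer matrix of shape (len(theta), n_items).
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    items.validate()
    rng = np.random.default_rng(seed)
    n = theta.size
    out = np.zeros((n, items.n_items), dtype=int)
    for j, (a, b) in enumerate(zip(items.discriminations, items.thresholds)):
        u = rng.random(n)
        # P(X >= k | theta) for k = 1..K; response = count of exceeded cumulatives
        cum = 1.0 / (1.0 + np.exp(-a * (theta[:, None] - b[None, :])))
        out[:, j] = (u[:, None] < cum).sum(axis=1)
    return out


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a = norm.cdf((lo - mean) / sd)
    b = norm.cdf((hi - mean) / sd)
    u = rng.uniform(a, b, size=size)
    return mean + sd * norm.ppf(u)


def _one_sided_truncated(u, tau, above: np.ndarray):
    """Map uniforms to N(0,1) draws truncated above/below ``tau`` per row."""
    p_tau = norm.cdf(tau)
    q = np.where(above, p_tau + u * (1 - p_tau), u * p_tau)
    return norm.ppf(np.clip(q, 1e-12, 1 - 1e-12))


def _design_matrix(cov: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [
            np.ones(len(cov)),
            cov["age"] - 38.0,
            cov["female"].astype(float),
            cov["single"].astype(float),
            cov["below_secondary"].astype(float),
            (cov["prior_trauma"] == "non-interpersonal").astype(float),
            (cov["prior_trauma"] == "interpersonal").astype(float),
            (cov["index_trauma"] == "other_accident").astype(float),
            (cov["index_trauma"] == "assault").astype(float),
        ]
    )


def _class_probabilities(X: np.ndarray, effects: dict) -> np.ndarray:
    """Multinomial class probabilities (n, 4) with Never as reference."""
    names = ["intercept"] + PREDICTORS
    etas = [np.zeros(X.shape[0])]
    for cls in CLASS_LEVELS[1:]:
        beta = np.array([effects.get(cls, {}).get(nm, 0.0) for nm in names])
        etas.append(X @ beta)
    eta = np.column_stack(etas)
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    return p / p.sum(axis=1, keepdims=True)


def _sample_class_copula(rng, p_ptsd, p_mdd, rho):
    """Sample both disorders' classes with a Gaussian copula of correlation
    ``rho`` on the underlying uniforms; marginals stay exactly multinomial."""
    n = p_ptsd.shape[0]
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    u = norm.cdf(z)
    cls = np.empty((n, 2), dtype=int)
    for d, (u_d, probs) in enumerate(((u[:, 0], p_ptsd), (u[:, 1], p_mdd))):
        cum = np.cumsum(probs, axis=1)
        cls[:, d] = (u_d[:, None] > cum).sum(axis=1)
    return cls[:, 0], cls[:, 1]


def _score_caps_arrays(freq, inten):
    present = (freq >= 1) & (inten >= 2)
    nb = present[:, 0:5].sum(axis=1)
    nc = present[:, 5:12].sum(axis=1)
    nd = present[:, 12:17].sum(axis=1)
    return (nb >= 1) & (nc >= 3) & (nd >= 2)


def _project_caps_to_dx(freq, inten, target_dx, theta, rng):
    """Minimally edit CAPS ratings so the scoring rule reproduces target_dx."""
    dx = _score_caps_arrays(freq, inten)
    clusters = {"B": np.arange(0, 5), "C": np.arange(5, 12), "D": np.arange(12, 17)}
    need = {"B": 1, "C": 3, "D": 2}
    fix_up = np.where(target_dx & ~dx)[0]
    for i in fix_up:
        for cl, k in need.items():
            idx = clusters[cl]
            present = (freq[i, idx] >= 1) & (inten[i, idx] >= 2)
            deficit = k - present.sum()
            if deficit > 0:
                # promote the symptoms already closest to presence
                order = np.argsort(-(freq[i, idx] + inten[i, idx]))
                for j in order:
                    if deficit == 0:
                        break
                    if not present[j]:
                        freq[i, idx[j]] = max(freq[i, idx[j]], 1)
                        inten[i, idx[j]] = max(inten[i, idx[j]], 2)
                        deficit -= 1
    fix_down = np.where(~target_dx & dx)[0]
    for i in fix_down:
        # break criterion C: demote its weakest present symptoms below 3
        idx = clusters["C"]
        present = np.where((freq[i, idx] >= 1) & (inten[i, idx] >= 2))[0]
        order = present[np.argsort(freq[i, idx[present]] + inten[i, idx[present]])]
        for j in order:
            if ((freq[i, idx] >= 1) & (inten[i, idx] >= 2)).sum() <= 2:
                break
            inten[i, idx[j]] = 1
    return freq, inten


def _project_dep_total(resp, max_score, threshold, target_ge):
    """Minimally edit item responses so the total is >= / < the threshold."""
    total = resp.sum(axis=1)
    for i in np.where(target_ge & (total < threshold))[0]:
        j = 0
        while resp[i].sum() < threshold:
            if resp[i, j % resp.shape[1]] < max_score:
                resp[i, j % resp.shape[1]] += 1
            j += 1
    for i in np.where(~target_ge & (total >= threshold))[0]:
        j = 0
        while resp[i].sum() >= threshold:
            if resp[i, j % resp.shape[1]] > 0:
                resp[i, j % resp.shape[1]] -= 1
            j += 1
    return resp


def generate_cohort(
    configs: list[StudyConfig],
    params: GenerativeParams | None = None,
    seed: int = 0,
    items: bool = True,
    apply_missing: bool = True,
    hads_threshold: int = 13,
) -> MultiStudyCohort:
    """Generate a synthetic multi-study cohort.

    Returns a :class:`MultiStudyCohort` whose ``data`` is a tidy table with
    one row per participant-wave and whose ``truth`` records the generative
    trajectory class per disorder and the latent severities.

    With ``items=False`` only diagnoses, severities-as-latents and covariates
    are produced (fast path for model-recovery studies).
    """
    if not configs:
        raise ConfigurationError("need at least one StudyConfig")
    params = params or GenerativeParams()
    rng = np.random.default_rng(seed)

    frames = []
    truths = []
    pid_offset = 0
    for cfg in configs:
        n = cfg.n_participants
        sub = np.random.default_rng(rng.integers(0, 2**31 - 1))

        cov = pd.DataFrame(
            {
                "age": np.clip(sub.normal(38.4, 13.9, n), 18, 90).round(0),
                "female": sub.random(n) < 0.36,
                "single": sub.random(n) < 0.50,
                "below_secondary": sub.random(n) < 0.20,
            }
        )
        u_prior = sub.random(n)
        cov["prior_trauma"] = np.where(
            u_prior < 0.18, "none", np.where(u_prior < 0.52, "non-interpersonal", "interpersonal")
        )
        if cfg.setting == "CCU":
            cov["index_trauma"] = "MVA"
        else:
            u_idx = sub.random(n)
            cov["index_trauma"] = np.where(
                u_idx < 0.70, "MVA", np.where(u_idx < 0.92, "other_accident", "assault")
            )

        X = _design_matrix(cov)
        p_ptsd = _class_probabilities(X, params.covariate_effects["ptsd"])
        p_mdd = _class_probabilities(X, params.covariate_effects["mdd"])
        cls_ptsd, cls_mdd = _sample_class_copula(sub, p_ptsd, p_mdd, params.dep_ptsd_corr)

        dx = {}
        for dis, cls in (("ptsd", cls_ptsd), ("mdd", cls_mdd)):
            pat = np.array([CLASS_TO_DX[CLASS_LEVELS[c]] for c in cls])
            dx[(dis, 1)] = pat[:, 0]
            dx[(dis, 2)] = pat[:, 1]

        shift = params.theta_study_shift.get(cfg.study_id, 0.0)
        rho_w = params.theta_wave_corr
        tau = {"ptsd": 1.3, "mdd": 1.2}
        theta = {}
        for dis in ("ptsd", "mdd"):
            z1 = sub.standard_normal(n)
            z2 = rho_w * z1 + np.sqrt(1 - rho_w**2) * sub.standard_normal(n)
            for w, z in ((1, z1), (2, z2)):
                u = norm.cdf(z)
                theta[(dis, w)] = _one_sided_truncated(u, tau[dis], dx[(dis, w)]) + shift

        day1 = _truncated_normal(sub, cfg.acute_day_mean, cfg.acute_day_sd, *ACUTE_BOUNDS, size=n)
        day2 = _truncated_normal(
            sub, cfg.persistent_day_mean, cfg.persistent_day_sd, *PERSISTENT_BOUNDS, size=n
        )

        pids = np.arange(pid_offset, pid_offset + n)
        pid_offset += n

        bank = params.item_bank
        dep_bank = bank[cfg.instrument]
        dep_max = 3 * dep_bank.n_items
        dep_threshold = 20 if cfg.instrument == "BDI" else hads_threshold

        for wave in (1, 2):
            row = pd.DataFrame(
                {
                    "participant_id": pids,
                    "study_id": cfg.study_id,
                    "wave": wave,
                    "days_since_trauma": np.round(day1 if wave == 1 else day2, 1),
                    "instrument": cfg.instrument,
                    "ptsd_observed": True,
                    "dep_observed": True,
                }
            )
            for c in cov.columns:
                row[c] = cov[c].to_numpy()
            if items:
                caps = generate_item_responses(
                    theta[("ptsd", wave)], bank["CAPS"], int(sub.integers(2**31 - 1))
                )
                freq = caps[:, :17].astype(int)
                inten = caps[:, 17:].astype(int)
                freq, inten = _project_caps_to_dx(
                    freq, inten, dx[("ptsd", wave)], theta[("ptsd", wave)], sub
                )
                for i in range(17):
                    row[f"caps{i + 1}_freq"] = freq[:, i]
                    row[f"caps{i + 1}_int"] = inten[:, i]
                dep = generate_item_responses(
                    theta[("mdd", wave)], dep_bank, int(sub.integers(2**31 - 1))
                )
                dep = _project_dep_total(dep, 3, dep_threshold, dx[("mdd", wave)])
                for j in range(dep_bank.n_items):
                    row[f"dep_item_{j + 1}"] = dep[:, j]
                row["dep_total"] = dep.sum(axis=1)
            else:
                row["ptsd_dx_true"] = dx[("ptsd", wave)]
                row["mdd_dx_true"] = dx[("mdd", wave)]
            frames.append(row)

        truths.append(
            pd.DataFrame(
                {
                    "participant_id": pids,
                    "study_id": cfg.study_id,
                    "ptsd_class": [CLASS_LEVELS[c] for c in cls_ptsd],
                    "mdd_class": [CLASS_LEVELS[c] for c in cls_mdd],
                    "theta_ptsd_w1": theta[("ptsd", 1)],
                    "theta_ptsd_w2": theta[("ptsd", 2)],
                    "theta_mdd_w1": theta[("mdd", 1)],
                    "theta_mdd_w2": theta[("mdd", 2)],
                }
            )
        )

    data = pd.concat(frames, ignore_index=True)
    data = data.sort_values(["participant_id", "wave"], kind="mergesort").reset_index(drop=True)
    truth = pd.concat(truths, ignore_index=True)

    sidecar = {
        "seed": int(seed),
        "configs": [asdict(c) for c in configs],
        "theta_wave_corr": params.theta_wave_corr,
        "dep_ptsd_corr": params.dep_ptsd_corr,
        "missing_mechanism": params.missing_mechanism,
        "covariate_effects": params.covariate_effects,
    }
    cohort = MultiStudyCohort(data=data, truth=truth, params_sidecar=sidecar)
    if apply_missing:
        rates = {c.study_id: 1.0 - c.followup_rate for c in configs}
        cohort = apply_missingness(cohort, params, int(rng.integers(2**31 - 1)), rates=rates)
    return cohort


def apply_missingness(
    cohort: MultiStudyCohort,
    params: GenerativeParams,
    seed: int,
    rates: dict | float,
) -> MultiStudyCohort:
    """Clear wave-2 observed flags according to the configured mechanism.

    ``rates`` gives the target wave-2 PTSD missingness per study (or one
    scalar for all); depression loses an extra ``params.extra_dep_missing``
    share on top.  Under MCAR, loss is independent of everything; under MAR,
    the loss probability increases with wave-1 PTSD severity (latent scale)
    on a logit scale with slope ``params.mar_severity_slope``, recentred so
    the marginal rate stays near the target.
    """
    data = cohort.data.copy()
    rng = np.random.default_rng(seed)
    w2 = data["wave"] == 2

    for study, grp in data[w2].groupby("study_id"):
        rate = rates if np.isscalar(rates) else rates.get(study, 0.0)
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"missing rate for {study} outside [0, 1]: {rate}")
        n = len(grp)
        if params.missing_mechanism == "MCAR" or rate == 0.0:
            lost = rng.random(n) < rate
        else:
            sev = cohort.truth.set_index("participant_id").loc[
                grp["participant_id"], "theta_ptsd_w1"
            ].to_numpy()
            sev = (sev - sev.mean()) / max(sev.std(), 1e-9)
            eta = norm.ppf(np.clip(rate, 1e-9, 1 - 1e-9)) + params.mar_severity_slope * sev
            p = norm.cdf(eta)
            p *= rate / max(p.mean(), 1e-12)  # recentre to the target marginal
            lost = rng.random(n) < np.clip(p, 0, 1)
        extra = rng.random(n) < params.extra_dep_missing
        idx = grp.index
        data.loc[idx[lost], "ptsd_observed"] = False
        data.loc[idx[lost | extra], "dep_observed"] = False

    return MultiStudyCohort(data=data, truth=cohort.truth, params_sidecar=cohort.params_sidecar)


def anchor_items_from_caps(freq: np.ndarray, inten: np.ndarray) -> np.ndarray:
    """Recode the three depression-overlapping CAPS symptoms (C4 = symptom 9,
    D1 = symptom 13, D3 = symptom 15) to ordinal 0-4 anchor responses by
    binning frequency + intensity as 0, 1-2, 3-4, 5-6, 7-8."""
    freq = np.asarray(freq, dtype=float)
    inten = np.asarray(inten, dtype=float)
    idx = np.array([9, 13, 15]) - 1
    total = freq[:, idx] + inten[:, idx]
    return np.clip(np.ceil(total / 2.0), 0, 4).astype(int)
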