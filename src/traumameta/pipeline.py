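"""End-to-end orchestration: simulate -> equate -> classify -> impute ->
model -> calibrate, with declarative YAML configuration and deterministic
per-stage seeding.

Every artifact CSV starts with a comment line carrying the configuration
checksum so a run directory is self-identifying; a JSON manifest records
seeds, stage outputs and content checksums.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import synth
from .calibration import (
    bootstrap_calibration,
    leave_one_study_out,
    restrict_followup_window,
)
from .classify import Trajectory, assign_trajectory, classify_cohort
from .equating import (
    build_crosswalk,
    load_reference_crosswalk,
    mean_sigma_link,
    apply_link,
)
from .grm import fit_grm
from .mice import ImputationSpec, run_mice
from .models import (
    RISK_FACTORS,
    describe_groups,
    fit_persistence_logistic,
    pool_multinomial,
    pooled_constrained_lrt,
)
from .synth import anchor_items_from_caps


class ConfigError(ValueError):
    pass


_DEFAULTS = {
    "seed": 0,
    "scale": 0.2,
    "stages": {
        "equate": True,
        "classify": True,
        "impute": True,
        "model": True,
        "calibrate": True,
    },
    "imputation": {"m": 5, "cycles": 5, "predictor_threshold": 0.10},
    "bootstrap": {"replicates": 100, "model_types": ["fixed", "random"]},
    "window": None,
    "loso": False,
    "use_packaged_crosswalk": True,
}


@dataclass
class RunConfig:
    raw: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def checksum(self) -> str:
        # stage toggles select which artifacts exist but never change the
        # content of an artifact that is produced, so they stay out of the
        # identifying checksum
        rest = {k: v for k, v in self.raw.items() if k != "stages"}
        blob = json.dumps(rest, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.raw['seed']}:{stage}".encode()).hexdigest()
        return int(h[:8], 16) % (2**31 - 1)


def _merge_with_defaults(user: dict, defaults: dict, path: str = "") -> dict:
    out = {}
    for key, default in defaults.items():
        if isinstance(default, dict) and key in user and isinstance(user[key], dict):
            out[key] = _merge_with_defaults(user[key], default, f"{path}{key}.")
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = json.loads(json.dumps(default))  # deep copy
    for key in user:
        if key not in defaults:
            hint = difflib.get_close_matches(key, defaults.keys(), n=1)
            msg = f"unknown configuration key {path}{key!r}"
            if hint:
                msg += f" (did you mean {hint[0]!r}?)"
            raise ConfigError(msg)
    return out


def validate_config(text: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Parse YAML config text, fill defaults, reject unknown keys."""
    user = yaml.safe_load(text) if text else {}
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ConfigError("configuration must be a YAML mapping")
    if overrides:
        user = {**user, **{k: v for k, v in overrides.items() if v is not None}}
    merged = _merge_with_defaults(user, _DEFAULTS)
    imp = merged["imputation"]
    if not isinstance(imp["m"], int) or imp["m"] < 2:
        raise ConfigError("imputation.m must be an integer >= 2")
    if imp["cycles"] < 1:
        raise ConfigError("imputation.cycles must be >= 1")
    if merged["bootstrap"]["replicates"] < 1:
        raise ConfigError("bootstrap.replicates must be >= 1")
    if merged["window"] is not None:
        lo, hi = merged["window"]
        if not (122 <= lo < hi <= 456):
            raise ConfigError("window must satisfy 122 <= lo < hi <= 456")
    if not (0 < merged["scale"] <= 2):
        raise ConfigError("scale must lie in (0, 2]")
    return RunConfig(raw=merged)


# ---------------------------------------------------------------------------
# wide <-> long conversion around the imputation stage
# ---------------------------------------------------------------------------

_LONG_VARS = ["ptsd_severity", "dep_severity", "ptsd_dx", "mdd_dx"]
_COVARS = ["age", "female", "single", "below_secondary", "prior_trauma", "index_trauma"]


def wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for wave in (1, 2):
        sub = pd.DataFrame(
            {
                "participant_id": wide["participant_id"],
                "study_id": wide["study_id"],
                "wave": wave,
                "ptsd_severity": wide[f"w{wave}_ptsd_severity"],
                "dep_severity": wide[f"w{wave}_dep_severity"],
                "ptsd_dx": wide[f"w{wave}_ptsd_dx"].astype(float),
                "mdd_dx": wide[f"w{wave}_mdd_dx"].astype(float),
            }
        )
        for c in _COVARS:
            sub[c] = wide[c].to_numpy()
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def long_to_wide(completed: pd.DataFrame, original_wide: pd.DataFrame) -> pd.DataFrame:
    """Fold one completed long table back onto the wide layout and re-derive
    trajectory labels from the completed diagnosis flags."""
    out = original_wide.copy()
    for wave in (1, 2):
        sub = completed[completed["wave"] == wave].set_index("participant_id")
        sub = sub.loc[out["participant_id"]]
        out[f"w{wave}_ptsd_severity"] = np.clip(sub["ptsd_severity"].to_numpy(), 0, 136)
        out[f"w{wave}_dep_severity"] = np.clip(sub["dep_severity"].to_numpy(), 0, 63)
        out[f"w{wave}_ptsd_dx"] = sub["ptsd_dx"].to_numpy() >= 0.5
        out[f"w{wave}_mdd_dx"] = sub["mdd_dx"].to_numpy() >= 0.5
    for dis in ("ptsd", "mdd"):
        out[f"{dis}_trajectory"] = [
            assign_trajectory(bool(w1), bool(w2)).value
            for w1, w2 in zip(out[f"w1_{dis}_dx"], out[f"w2_{dis}_dx"])
        ]
    return out


def impute_analysis_table(
    wide: pd.DataFrame, m: int, cycles: int, threshold: float, seed: int
) -> tuple[list[pd.DataFrame], dict]:
    """MICE over the long two-wave table; returns m completed wide tables."""
    long = wide_to_long(wide)
    spec = ImputationSpec(
        m=m,
        cycles=cycles,
        predictor_threshold=threshold,
        variables={
            "ptsd_severity": "continuous",
            "dep_severity": "continuous",
            "ptsd_dx": "binary",
        },
        seed=seed,
    )
    imputed = run_mice(long, spec)
    completed = []
    for d in imputed.datasets:
        d = d.copy()
        # probable MDD is, by definition, a severity threshold on the
        # BDI-equated metric, so the flag follows the completed severity
        miss = d["mdd_dx"].isna()
        d.loc[miss, "mdd_dx"] = (d.loc[miss, "dep_severity"] >= 20).astype(float)
        completed.append(long_to_wide(d, wide))
    return completed, imputed.metadata


# ---------------------------------------------------------------------------
# equating on generated item data
# ---------------------------------------------------------------------------


def equate_from_cohort(cohort_data: pd.DataFrame, seed: int = 0):
    """Fit pooled GRMs per instrument (with CAPS-derived anchors) on wave-1
    data, link by mean/sigma, and build the HADS -> BDI crosswalk."""
    w1 = cohort_data[cohort_data["wave"] == 1]
    caps_f = w1[[f"caps{i}_freq" for i in range(1, 18)]].to_numpy(dtype=float)
    caps_i = w1[[f"caps{i}_int" for i in range(1, 18)]].to_numpy(dtype=float)
    anchors = anchor_items_from_caps(caps_f, caps_i).astype(float)
    anchor_labels = ["anchor_C4", "anchor_D1", "anchor_D3"]

    fits = {}
    for inst, n_items in (("BDI", 21), ("HADS", 7)):
        sel = (w1["instrument"] == inst).to_numpy()
        items = w1.loc[sel, [f"dep_item_{j}" for j in range(1, n_items + 1)]].to_numpy(dtype=float)
        mat = np.column_stack([items, anchors[sel]])
        labels = [f"{inst.lower()}_{j}" for j in range(1, n_items + 1)] + anchor_labels
        anchor_flags = np.array([False] * n_items + [True] * 3)
        params, info = fit_grm(mat, labels=labels, anchor=anchor_flags, max_iter=200)
        fits[inst] = params
    constants = mean_sigma_link(
        fits["BDI"].subset(anchor_labels), fits["HADS"].subset(anchor_labels)
    )
    hads_linked = apply_link(fits["HADS"], constants)
    bdi_only = fits["BDI"].subset([f"bdi_{j}" for j in range(1, 22)])
    hads_only = hads_linked.subset([f"hads_{j}" for j in range(1, 8)])
    xwalk = build_crosswalk(bdi_only, hads_only)
    return xwalk, constants, fits


# ---------------------------------------------------------------------------
# the run itself
# ---------------------------------------------------------------------------


class StageError(RuntimeError):
    def __init__(self, stage, original):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _write_csv(df: pd.DataFrame, path: pathlib.Path, checksum: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_checksum: {checksum}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksum = config.checksum
    manifest = {"config": config.raw, "config_checksum": checksum, "artifacts": {}}

    def record(name, path):
        manifest["artifacts"][name] = {
            "path": str(path.name),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }

    stage = "simulate"
    try:
        configs = synth.default_study_configs(scale=config["scale"])
        cohort = synth.generate_cohort(configs, seed=config.stage_seed("simulate"))
        cohort_path = out / "cohort.csv"
        _write_csv(cohort.data, cohort_path, checksum)
        cohort.write_sidecar(out / "cohort_truth_params.json")
        record("cohort", cohort_path)

        stage = "equate"
        if config["stages"]["equate"]:
            xwalk_fit, constants, _ = equate_from_cohort(
                cohort.data, seed=config.stage_seed("equate")
            )
            _write_csv(xwalk_fit.to_frame(), out / "crosswalk_fitted.csv", checksum)
            record("crosswalk_fitted", out / "crosswalk_fitted.csv")
            manifest["linking_constants"] = {"A": constants.A, "B": constants.B}
        xwalk = load_reference_crosswalk() if config["use_packaged_crosswalk"] else xwalk_fit
        _write_csv(xwalk.to_frame(), out / "crosswalk.csv", checksum)
        record("crosswalk", out / "crosswalk.csv")

        stage = "classify"
        wide = classify_cohort(cohort.data, xwalk)
        _write_csv(wide, out / "analysis_table.csv", checksum)
        record("analysis_table", out / "analysis_table.csv")
        for dis in ("ptsd", "mdd"):
            desc = describe_groups(wide, dis)
            _write_csv(desc, out / f"descriptives_{dis}.csv", checksum)
            record(f"descriptives_{dis}", out / f"descriptives_{dis}.csv")
        if not config["stages"]["classify"]:
            return _finish(manifest, out)

        stage = "impute"
        if config["stages"]["impute"]:
            imp = config["imputation"]
            completed, meta = impute_analysis_table(
                wide, imp["m"], imp["cycles"], imp["predictor_threshold"],
                config.stage_seed("impute"),
            )
            with open(out / "imputation_metadata.json", "w") as fh:
                json.dump(meta, fh, indent=1, default=str)
        else:
            completed = [wide[wide["ptsd_trajectory"] != Trajectory.UNCLASSIFIABLE.value]
                         .reset_index(drop=True)]

        stage = "model"
        if config["stages"]["model"]:
            _run_models(completed, out, checksum, record)

        stage = "calibrate"
        if config["stages"]["calibrate"]:
            for dis in ("ptsd", "mdd"):
                frames = []
                for mt in config["bootstrap"]["model_types"]:
                    rep = bootstrap_calibration(
                        completed[: min(2, len(completed))],
                        dis,
                        model_type=mt,
                        n_bootstrap=config["bootstrap"]["replicates"],
                        seed=config.stage_seed(f"calibrate:{dis}:{mt}"),
                    )
                    t = rep.table.copy()
                    t["model_type"] = mt
                    frames.append(t)
                _write_csv(pd.concat(frames), out / f"calibration_{dis}.csv", checksum)
                record(f"calibration_{dis}", out / f"calibration_{dis}.csv")
            if config["loso"]:
                for study in sorted(wide["study_id"].unique()):
                    reduced = leave_one_study_out(completed, study)
                    ors = pd.concat(
                        [pool_multinomial(reduced, dis) for dis in ("ptsd", "mdd")]
                    )
                    _write_csv(ors, out / f"loso_{study}.csv", checksum)
                    record(f"loso_{study}", out / f"loso_{study}.csv")
            if config["window"] is not None:
                restricted = restrict_followup_window(wide, tuple(config["window"]))
                imp = config["imputation"]
                completed_w, _ = impute_analysis_table(
                    restricted, imp["m"], imp["cycles"], imp["predictor_threshold"],
                    config.stage_seed("impute:window"),
                )
                ors = pd.concat(
                    [pool_multinomial(completed_w, dis) for dis in ("ptsd", "mdd")]
                )
                _write_csv(ors, out / "window_sensitivity_or.csv", checksum)
                record("window_sensitivity_or", out / "window_sensitivity_or.csv")
    except Exception as exc:  # noqa: BLE001 - structured stage failure
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        if isinstance(exc, (ConfigError, StageError)):
            raise
        raise StageError(stage, exc) from exc

    return _finish(manifest, out)


def _run_models(completed, out, checksum, record):
    for dis in ("ptsd", "mdd"):
        ors = pool_multinomial(completed, dis)
        _write_csv(ors, out / f"multinomial_or_{dis}.csv", checksum)
        record(f"multinomial_or_{dis}", out / f"multinomial_or_{dis}.csv")
        lrt_rows = []
        for rf in RISK_FACTORS:
            res = pooled_constrained_lrt(completed, dis, rf)
            lrt_rows.append(
                {"disorder": dis, "predictor": rf, "statistic": res.statistic,
                 "df": res.df, "p_value": res.p_value}
            )
        _write_csv(pd.DataFrame(lrt_rows), out / f"lrt_{dis}.csv", checksum)
        record(f"lrt_{dis}", out / f"lrt_{dis}.csv")
        model_frames = []
        for model in (1, 2, 3):
            try:
                model_frames.append(fit_persistence_logistic(completed, dis, model))
            except ValueError:
                continue
        if model_frames:
            _write_csv(pd.concat(model_frames), out / f"persistence_or_{dis}.csv", checksum)
            record(f"persistence_or_{dis}", out / f"persistence_or_{dis}.csv")


def _finish(manifest, out):
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
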