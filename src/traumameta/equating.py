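"""Placing two depression instruments on one latent metric and equating scores.

The workflow mirrors standard anchor-item IRT equating: fit a graded response
model separately to the pooled data of each instrument (each augmented with
the same anchor items), compute mean/sigma linking constants from the anchor
threshold parameters, transform the target calibration onto the base metric,
and build a total-score crosswalk by true-score equating through the test
characteristic curves (TCC).

The packaged reference crosswalk maps the 7-item HADS depression subscale
(0-21) onto the 21-item BDI-II (0-63); under it the probable-depression
threshold HADS >= 13 corresponds to BDI >= 20.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import GRMParameters, test_characteristic_curve


@dataclass(frozen=True)
class LinkingConstants:
    """Scale (A) and shift (B) constants for ``theta* = A * theta + B``."""

    A: float
    B: float

    def __post_init__(self):
        if not (np.isfinite(self.A) and np.isfinite(self.B)):
            raise ValueError("linking constants must be finite")
        if self.A <= 0:
            raise ValueError("scale constant A must be positive")


class CrosswalkRangeError(KeyError):
    pass


@dataclass
class Crosswalk:
    """Total-score lookup mapping one instrument's range onto another's.

    ``table`` maps every integer source score (no gaps) to a non-decreasing
    equated target score.
    """

    source_instrument: str
    target_instrument: str
    table: dict[int, int]
    method: str = "tcc_true_score"

    def __post_init__(self):
        scores = sorted(self.table)
        if scores != list(range(scores[0], scores[-1] + 1)):
            raise ValueError("crosswalk must cover its source range with no gaps")
        equated = [self.table[s] for s in scores]
        if any(b < a for a, b in zip(equated, equated[1:])):
            raise ValueError("equated scores must be non-decreasing in the source score")

    @property
    def source_range(self) -> tuple[int, int]:
        return (min(self.table), max(self.table))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"source_score": sorted(self.table), "equated_score": [self.table[s] for s in sorted(self.table)]}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, source="HADS", target="BDI", method="packaged") -> "Crosswalk":
        df = pd.read_csv(path)
        table = dict(zip(df["source_score"].astype(int), df["equated_score"].astype(int)))
        return cls(source_instrument=source, target_instrument=target, table=table, method=method)


def equate_score(xwalk: Crosswalk, s: int) -> int:
    """Look up the equated target-instrument score for source score ``s``."""
    s = int(s)
    if s not in xwalk.table:
        lo, hi = xwalk.source_range
        raise CrosswalkRangeError(
            f"score {s} outside {xwalk.source_instrument} range [{lo}, {hi}]"
        )
    return int(xwalk.table[s])


def load_reference_crosswalk() -> Crosswalk:
    """The packaged HADS-depression -> BDI-II crosswalk used for probable-MDD
    harmonization (13 -> 20, 21 -> 63)."""
    ref = importlib.resources.files("traumameta.data").joinpath("hads_bdi_crosswalk.csv")
    with importlib.resources.as_file(ref) as path:
        return Crosswalk.from_csv(path, source="HADS", target="BDI", method="packaged")


def _pooled_anchor_thresholds(params: GRMParameters, anchors: list[str]) -> np.ndarray:
    sub = params.subset(anchors)
    return np.concatenate(sub.thresholds)


def mean_sigma_link(
    anchors_base: GRMParameters, anchors_target: GRMParameters
) -> LinkingConstants:
    """Mean/sigma linking constants from anchor-item threshold parameters.

    All thresholds of the shared anchor items are pooled in each calibration;
    ``A`` is the ratio of their standard deviations (base over target) and
    ``B = mean_base - A * mean_target``.  Applying ``theta* = A theta + B``
    (so ``b* = A b + B``, ``a* = a / A``) expresses the target calibration on
    the base metric.
    """
    labels = [l for l in anchors_base.labels if l in anchors_target.labels]
    if not labels:
        raise ValueError("no shared anchor items between calibrations")
    base_sub = anchors_base.subset(labels)
    targ_sub = anchors_target.subset(labels)
    if [b.size for b in base_sub.thresholds] != [b.size for b in targ_sub.thresholds]:
        raise ValueError("anchor items must have identical category counts in both calibrations")
    b_base = np.concatenate(base_sub.thresholds)
    b_targ = np.concatenate(targ_sub.thresholds)
    if np.unique(b_targ).size < 2 or np.unique(b_base).size < 2:
        raise ValueError("need at least 2 distinct anchor thresholds to identify the scale")
    A = float(np.std(b_base, ddof=0) / np.std(b_targ, ddof=0))
    B = float(np.mean(b_base) - A * np.mean(b_targ))
    return LinkingConstants(A=A, B=B)


def apply_link(target: GRMParameters, constants: LinkingConstants) -> GRMParameters:
    """Transform a target calibration onto the base metric."""
    return target.transform(constants.A, constants.B)


def _invert_tcc(params: GRMParameters, score: float, lo=-12.0, hi=12.0, tol=1e-10) -> float:
    """Bisection solve of TCC(theta) = score; the TCC is strictly monotone."""
    f_lo = test_characteristic_curve(params, np.array([lo]))[0] - score
    f_hi = test_characteristic_curve(params, np.array([hi]))[0] - score
    if f_lo > 0:
        return lo
    if f_hi < 0:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = test_characteristic_curve(params, np.array([mid]))[0] - score
        if abs(f_mid) < tol or (hi - lo) < 1e-12:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_crosswalk(
    grm_base: GRMParameters,
    grm_target_linked: GRMParameters,
    source_instrument: str = "HADS",
    target_instrument: str = "BDI",
) -> Crosswalk:
    """True-score equating: map each integer source total to a target total.

    For each source score ``s`` the source TCC is inverted by bisection to a
    latent value ``theta_s``; the equated score is the base-instrument TCC at
    ``theta_s``, rounded half-up to an integer.  Endpoints are pinned to the
    score-range extremes (both TCCs vanish together as theta -> -inf and
    saturate together as theta -> +inf).  Scores below the TCC floor or above
    its ceiling are clamped to the nearest attainable value.
    """
    src_max = int(grm_target_linked.max_scores.sum())
    tgt_max = int(grm_base.max_scores.sum())
    table: dict[int, int] = {}
    for s in range(src_max + 1):
        if s == 0:
            table[s] = 0
            continue
        if s == src_max:
            table[s] = tgt_max
            continue
        theta_s = _invert_tcc(grm_target_linked, float(s))
        t = test_characteristic_curve(grm_base, np.array([theta_s]))[0]
        table[s] = int(np.floor(t + 0.5))
    # enforce monotonicity against rounding ties
    prev = 0
    for s in range(src_max + 1):
        table[s] = max(table[s], prev)
        prev = table[s]
    return Crosswalk(
        source_instrument=source_instrument,
        target_instrument=target_instrument,
        table=table,
    )


def invert_crosswalk_threshold(xwalk: Crosswalk, target_threshold: int) -> int | None:
    """Smallest source score whose equated value reaches ``target_threshold``.

    Used to carry a case-definition cut-off from the base instrument onto the
    source instrument (e.g., BDI >= 20 onto the HADS scale).  Returns None if
    no source score reaches the threshold.
    """
    for s in sorted(xwalk.table):
        if xwalk.table[s] >= target_threshold:
            return s
    return None
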