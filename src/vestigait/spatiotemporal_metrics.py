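"""Spatial and temporal gait parameters: zone-based CoM and foot scores,
step width, medio-lateral step distance, tandem step count, walking speed,
double-support time, task time, and per-cycle aggregation.

The zone scores overlay four nested medio-lateral bands about the walkway
midline (innermost band scores zero).  The CoM score counts lateral
excursions by the outermost zone they reach; the foot score integrates the
fraction of trial time during which BOTH heels lie in the outer zones.
Default half-widths are the 6/10/15-inch deviation bands used by
level-surface gait scoring in the Functional Gait Assessment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .body_model import ComTrajectory
from .stability_metrics import ml_axis
from .trial_io import GaitEventTable, TrialRecord

__all__ = [
    "ZoneSpec",
    "StepSeries",
    "fit_midline",
    "lateral_offsets",
    "com_zone_score",
    "foot_zone_score",
    "build_step_series",
    "step_width",
    "ml_step_distance",
    "tandem_step_count",
    "walking_speed",
    "double_support_time",
    "task_time",
    "aggregate_per_trial",
]


@dataclass(frozen=True)
class ZoneSpec:
    """Nested medio-lateral zones about the walkway midline.

    ``boundaries`` are the increasing half-widths (m) separating zone 0
    (innermost) from zones 1..len(boundaries); ``weights`` give one weight
    per zone, with weight 0 for zone 0.
    """

    boundaries: tuple[float, ...] = (0.1524, 0.254, 0.381)
    weights: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)

    def __post_init__(self):
        b = np.asarray(self.boundaries)
        if np.any(np.diff(b) <= 0) or np.any(b <= 0):
            raise ValueError("boundaries must be positive and strictly increasing")
        if len(self.weights) != len(self.boundaries) + 1:
            raise ValueError("need one weight per zone (len(boundaries) + 1)")
        if self.weights[0] != 0:
            raise ValueError("zone 0 weight must be 0")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")

    def zone_of(self, offsets: np.ndarray) -> np.ndarray:
        """Zone index (0..n_zones-1) of each lateral offset."""
        return np.searchsorted(np.asarray(self.boundaries), np.abs(offsets),
                               side="left")


@dataclass
class StepSeries:
    """Per-strike heel placements with derived lateral offsets.

    ``steps`` has columns time, side, x, y (floor plane, m) and ``lateral``
    (signed offset from the walkway midline, m).
    """

    steps: pd.DataFrame

    def side(self, side: str) -> pd.DataFrame:
        return self.steps[self.steps["side"] == side].reset_index(drop=True)


def fit_midline(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares walkway midline through a floor-plane path: returns
    (point on line, unit direction)."""
    mean = xy.mean(axis=0)
    c = xy - mean
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    d = vt[0]
    net = xy[-1] - xy[0]
    if np.dot(d, net) < 0:
        d = -d
    return mean, d / np.linalg.norm(d)


def _segment_bounds(xy: np.ndarray, piecewise: bool) -> list[slice]:
    """Frame ranges of straight path segments.  For turn-pivot style paths
    the trajectory is split at the extremum of progression along the
    principal axis."""
    if not piecewise:
        return [slice(0, len(xy))]
    _, d = fit_midline(xy)
    s = (xy - xy[0]) @ d
    split = int(np.argmax(s))
    if split < 10 or split > len(xy) - 10:
        return [slice(0, len(xy))]
    return [slice(0, split), slice(split, len(xy))]


def lateral_offsets(
    xy: np.ndarray, reference_xy: np.ndarray | None = None,
    piecewise: bool = False,
) -> np.ndarray:
    """Signed lateral offset (m) of each floor-plane point from the fitted
    walkway midline.  The midline is fitted to ``reference_xy`` (default:
    the points themselves); ``piecewise`` fits one line per straight leg of
    a there-and-back path.  When the reference path and the evaluated
    points differ in length, segments are mapped proportionally (both are
    time-ordered)."""
    ref = xy if reference_xy is None else reference_xy
    out = np.empty(len(xy))
    n_ref, n_xy = len(ref), len(xy)
    for sl in _segment_bounds(ref, piecewise):
        point, d = fit_midline(ref[sl])
        ml = ml_axis(d)
        if n_ref == n_xy:
            idx = sl
        else:
            lo = 0 if sl.start == 0 else int(round(sl.start * n_xy / n_ref))
            hi = n_xy if sl.stop >= n_ref else int(round(sl.stop * n_xy / n_ref))
            idx = slice(lo, hi)
        out[idx] = (xy[idx] - point) @ ml
    return out


def com_zone_score(
    com: ComTrajectory,
    zones: ZoneSpec = ZoneSpec(),
    piecewise: bool = False,
) -> float:
    """Zone score of the CoM path over the entire trial.

    Each lateral excursion out of zone 0 contributes the weight of the
    outermost zone it reaches, so repeated deviations and catch-up
    excursions accumulate.
    """
    xy = com.position[:, :2]
    z = zones.zone_of(lateral_offsets(xy, piecewise=piecewise))
    score = 0.0
    i, n = 0, len(z)
    while i < n:
        if z[i] == 0:
            i += 1
            continue
        j = i
        while j < n and z[j] > 0:
            j += 1
        score += zones.weights[int(z[i:j].max())]
        i = j
    return score


def foot_zone_score(
    trial: TrialRecord,
    zones: ZoneSpec = ZoneSpec(),
    reference_xy: np.ndarray | None = None,
    piecewise: bool = False,
) -> float:
    """Time-weighted zone score of the two heels.

    For each outer zone z the fraction of trial time during which BOTH
    heels lie in zone >= z contributes weight(z) to the score.
    """
    trial.require("LHEE", "RHEE")
    ref = reference_xy
    if ref is None:
        ref = 0.5 * (trial.markers["LHEE"][:, :2] + trial.markers["RHEE"][:, :2])
    zl = zones.zone_of(lateral_offsets(trial.markers["LHEE"][:, :2], ref,
                                       piecewise))
    zr = zones.zone_of(lateral_offsets(trial.markers["RHEE"][:, :2], ref,
                                       piecewise))
    both = np.minimum(zl, zr)
    score = 0.0
    for z in range(1, len(zones.weights)):
        score += zones.weights[z] * float(np.mean(both >= z))
    return score


def build_step_series(
    trial: TrialRecord,
    events: GaitEventTable,
    reference_xy: np.ndarray | None = None,
    piecewise: bool = False,
) -> StepSeries:
    """Heel placements at each foot strike, with midline-relative lateral
    offsets."""
    trial.require("LHEE", "RHEE")
    rows = []
    for side in ("left", "right"):
        heel = trial.markers[f"{side[0].upper()}HEE"][:, :2]
        for t in events.strikes(side):
            i = int(round(t * trial.rate))
            i = min(max(i, 0), trial.n_frames - 1)
            rows.append((t, side, heel[i, 0], heel[i, 1]))
    df = pd.DataFrame(rows, columns=["time", "side", "x", "y"])
    df = df.sort_values("time", kind="stable").reset_index(drop=True)
    if len(df):
        ref = reference_xy
        if ref is None:
            xy = df[["x", "y"]].to_numpy()
            # midpoints of consecutive opposite-side placements lie on the
            # walkway centerline exactly (a line fitted to the raw
            # alternating placements tilts on finite windows)
            alt = df["side"].to_numpy()[:-1] != df["side"].to_numpy()[1:]
            mids = 0.5 * (xy[:-1] + xy[1:])[alt]
            if len(mids) >= 4:
                # robust refit: catch-up steps must not tilt the centerline
                point, d = fit_midline(mids)
                res = (mids - point) @ ml_axis(d)
                mad = np.median(np.abs(res - np.median(res)))
                keep = np.abs(res - np.median(res)) <= max(3 * mad, 0.02)
                if keep.sum() >= 2:
                    mids = mids[keep]
            ref = mids if len(mids) >= 2 else xy
        df["lateral"] = lateral_offsets(df[["x", "y"]].to_numpy(), ref, piecewise)
    else:
        df["lateral"] = pd.Series(dtype=float)
    return StepSeries(df)


def step_width(steps: StepSeries) -> float:
    """Per-trial median medio-lateral distance between the heels at the
    leading-foot strike (leading heel at its strike, contralateral heel at
    its own previous strike)."""
    df = steps.steps
    widths = []
    for i in range(1, len(df)):
        lead = df.iloc[i]
        prev = df.iloc[i - 1]
        if prev["side"] == lead["side"]:
            continue
        widths.append(abs(lead["lateral"] - prev["lateral"]))
    if not widths:
        return float("nan")
    return float(np.median(widths))


def ml_step_distance(steps: StepSeries, side: str) -> float:
    """Maximum medio-lateral distance between two consecutive ipsilateral
    heel placements on the analysis side."""
    lat = steps.side(side)["lateral"].to_numpy()
    if len(lat) < 2:
        return float("nan")
    return float(np.max(np.abs(np.diff(lat))))


def tandem_step_count(
    trial: TrialRecord,
    events: GaitEventTable,
    line_tolerance: float = 0.05,
    line_offset: float = 0.0,
) -> int:
    """Number of consecutive heel-to-toe placements landing within
    ``line_tolerance`` of the tandem line before the first off-line
    placement (or trial end).

    The tandem line is the physical line on the floor, taken as the lab X
    axis at lateral position ``line_offset`` (the lab frame puts the
    walkway midline at y = 0); it is deliberately not fitted to the
    observed placements, which would absorb a systematic off-line drift.
    """
    if trial.task != "tandem_walk":
        raise ValueError(f"tandem_step_count requires a tandem trial, got "
                         f"{trial.task!r}")
    trial.require("LHEE", "RHEE")
    placements = []
    for side in ("left", "right"):
        heel = trial.markers[f"{side[0].upper()}HEE"][:, :2]
        for t in events.strikes(side):
            i = min(max(int(round(t * trial.rate)), 0), trial.n_frames - 1)
            placements.append((t, heel[i, 1]))
    placements.sort()
    count = 0
    for _, y in placements:
        if abs(y - line_offset) <= line_tolerance:
            count += 1
        else:
            break
    return count


def walking_speed(com: ComTrajectory, events: GaitEventTable) -> float:
    """Horizontal CoM path distance between the first and last foot strike
    divided by the elapsed time."""
    strikes = events.strikes()
    if len(strikes) < 2:
        return float("nan")
    t0, t1 = float(strikes.min()), float(strikes.max())
    i0 = int(round(t0 * com.rate))
    i1 = int(round(t1 * com.rate))
    xy = com.position[i0 : i1 + 1, :2]
    dist = float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))
    return dist / (t1 - t0)


def _stance_intervals(
    events: GaitEventTable, side: str, t_start: float, t_end: float
) -> list[tuple[float, float]]:
    """Closed stance intervals of one side within [t_start, t_end],
    assuming stance from trial start if the first event is a foot off."""
    sub = events.side(side)
    intervals = []
    current: float | None = None
    first = sub["kind"].iloc[0] if len(sub) else None
    if first == "foot_off":
        current = t_start
    for _, row in sub.iterrows():
        if row["kind"] == "foot_strike":
            current = row["time"]
        elif current is not None:
            intervals.append((current, row["time"]))
            current = None
    if current is not None:
        intervals.append((current, t_end))
    return intervals


def double_support_time(
    events: GaitEventTable, side: str = "left",
    t_start: float = 0.0, t_end: float | None = None,
) -> tuple[float, int]:
    """Per-cycle median double-support time (s).

    A cycle runs from one foot strike of the analysis side to the next;
    within it, double support is the total time both feet are in stance
    (two intervals per cycle in walking; zero with flight phases).
    Returns (median, n_cycles).
    """
    strikes = events.strikes(side)
    if len(strikes) < 2:
        return float("nan"), 0
    if t_end is None:
        t_end = float(events.events["time"].max()) + 1.0
    st_l = _stance_intervals(events, "left", t_start, t_end)
    st_r = _stance_intervals(events, "right", t_start, t_end)
    overlaps = [
        (max(a0, b0), min(a1, b1))
        for a0, a1 in st_l
        for b0, b1 in st_r
        if min(a1, b1) > max(a0, b0)
    ]
    per_cycle = []
    for c0, c1 in zip(strikes[:-1], strikes[1:]):
        total = 0.0
        for o0, o1 in overlaps:
            lo, hi = max(o0, c0), min(o1, c1)
            if hi > lo:
                total += hi - lo
        per_cycle.append(total)
    return float(np.median(per_cycle)), len(per_cycle)


def task_time(
    trial: TrialRecord, events: GaitEventTable | None = None,
    convention: str = "events",
) -> float:
    """Task duration (s): last minus first gait event when available under
    the ``events`` convention, else the full trial duration."""
    if convention == "events" and events is not None and len(events) >= 2:
        t = events.events["time"].to_numpy()
        return float(t.max() - t.min())
    return trial.duration


def aggregate_per_trial(values) -> tuple[float, int]:
    """Median of per-cycle values and the count of contributing cycles."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return float("nan"), 0
    return float(np.median(arr)), int(arr.size)
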