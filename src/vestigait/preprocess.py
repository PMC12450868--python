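"""Trial preprocessing: gap filling, low-pass filtering, virtual joint-center
markers, gait-event detection and walking-direction estimation.

The processing chain mirrors standard gait-lab practice: marker gaps are
reconstructed from inter-marker correlations (low-rank completion of the
marker matrix, spline-only for short gaps), trajectories are low-pass
filtered with a zero-phase 4th-order Butterworth at 6 Hz, joint centers are
added as virtual markers, and foot strikes / foot offs are detected from
foot-versus-pelvis progression extrema refined by a foot-quiescence
criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .trial_io import GaitEventTable, MissingMarkerError, TrialRecord

__all__ = [
    "FilterSpec",
    "GapReport",
    "GeometryError",
    "UnfillableGapError",
    "fill_gaps",
    "lowpass",
    "add_virtual_markers",
    "detect_gait_events",
    "estimate_walking_direction",
    "walking_direction_series",
]


class GeometryError(ValueError):
    """Raised when marker geometry is degenerate (e.g. collinear pelvis)."""


class UnfillableGapError(ValueError):
    """Raised when a gap spans all markers simultaneously."""


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter specification.

    ``order`` is the design order of each pass; with ``zero_phase`` the
    filter is applied forward and backward (``filtfilt``), preserving event
    timing at the cost of squaring the magnitude response.
    """

    order: int = 4
    cutoff: float = 6.0  # Hz
    zero_phase: bool = True


@dataclass
class GapReport:
    """Gaps found by :func:`fill_gaps`; ``unfilled`` lists gaps longer than
    ``max_gap`` as (marker, start_frame, end_frame_exclusive)."""

    filled: list[tuple[str, int, int]] = field(default_factory=list)
    unfilled: list[tuple[str, int, int]] = field(default_factory=list)


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a 1-D boolean mask as (start, stop)."""
    idx = np.flatnonzero(np.diff(np.r_[False, mask, False]))
    return list(zip(idx[::2], idx[1::2]))


def _spline_fill(series: np.ndarray) -> np.ndarray:
    """Cubic-spline interpolation over NaNs of an (n, 3) series, constant
    extrapolation at the edges."""
    out = series.copy()
    n = len(series)
    t = np.arange(n)
    for c in range(3):
        col = out[:, c]
        good = ~np.isnan(col)
        if good.sum() < 2:
            raise UnfillableGapError("fewer than 2 observed samples in a channel")
        if good.sum() < 4:
            out[:, c] = np.interp(t, t[good], col[good])
            continue
        cs = CubicSpline(t[good], col[good])
        bad = ~good
        filled = cs(t[bad])
        # clamp edge extrapolation to the nearest observed value
        first, last = t[good][0], t[good][-1]
        filled = np.where(t[bad] < first, col[good][0], filled)
        filled = np.where(t[bad] > last, col[good][-1], filled)
        out[bad, c] = filled
    return out


def fill_gaps(
    trial: TrialRecord,
    max_gap: int = 100,
    spline_max: int = 10,
    rank: int = 10,
    n_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[TrialRecord, GapReport]:
    """Fill NaN gaps in marker trajectories.

    Gaps of at most ``spline_max`` frames are filled per channel with a
    cubic spline.  Longer gaps (up to ``max_gap``) are reconstructed from
    marker inter-correlations: iterated principal-component (low-rank)
    estimation over the full marker matrix, initialized from the spline
    fill.  Gaps longer than ``max_gap`` are reported unfilled.  Observed
    samples are never modified.
    """
    labels = sorted(trial.markers)
    report = GapReport()
    raw = {lb: trial.markers[lb] for lb in labels}
    nan_mask = {lb: np.isnan(raw[lb]).any(axis=1) for lb in labels}
    if not any(m.any() for m in nan_mask.values()):
        return trial, report

    all_missing = np.logical_and.reduce([nan_mask[lb] for lb in labels])
    if all_missing.any():
        raise UnfillableGapError("all markers missing simultaneously")
    n_complete = sum(1 for lb in labels if not nan_mask[lb].any())
    if n_complete < 3:
        raise UnfillableGapError("need at least 3 fully observed markers")

    long_gap = {lb: np.zeros(trial.n_frames, bool) for lb in labels}
    needs_lowrank = False
    for lb in labels:
        for start, stop in _nan_runs(nan_mask[lb]):
            gap = (lb, int(start), int(stop))
            if stop - start > max_gap:
                report.unfilled.append(gap)
                long_gap[lb][start:stop] = True
            else:
                report.filled.append(gap)
                if stop - start > spline_max:
                    needs_lowrank = True

    filled = {lb: _spline_fill(raw[lb]) if nan_mask[lb].any() else raw[lb].copy()
              for lb in labels}

    if needs_lowrank:
        X = np.hstack([filled[lb] for lb in labels])
        miss = np.hstack([np.repeat(nan_mask[lb][:, None], 3, axis=1)
                          for lb in labels])
        spline_only = np.hstack([np.repeat(
            (nan_mask[lb] & (np.zeros(trial.n_frames, bool) |
                             _short_mask(nan_mask[lb], spline_max)))[:, None],
            3, axis=1) for lb in labels])
        target = miss & ~spline_only
        prev = X[target].copy()
        r = min(rank, min(X.shape) - 1)
        for _ in range(n_iter):
            mu = X.mean(axis=0)
            Xc = X - mu
            U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
            approx = (U[:, :r] * s[:r]) @ Vt[:r] + mu
            X[target] = approx[target]
            delta = np.max(np.abs(X[target] - prev)) if target.any() else 0.0
            prev = X[target].copy()
            if delta < tol:
                break
        for k, lb in enumerate(labels):
            filled[lb] = X[:, 3 * k : 3 * k + 3]

    markers = {}
    for lb in labels:
        out = filled[lb]
        out[long_gap[lb]] = np.nan  # long gaps stay unfilled
        obs = ~nan_mask[lb]
        out[obs] = raw[lb][obs]  # observed samples untouched
        markers[lb] = out
    return trial.copy_with(markers=markers), report


def _short_mask(mask: np.ndarray, spline_max: int) -> np.ndarray:
    out = np.zeros_like(mask)
    for start, stop in _nan_runs(mask):
        if stop - start <= spline_max:
            out[start:stop] = True
    return out


def lowpass(trial: TrialRecord, spec: FilterSpec = FilterSpec()) -> TrialRecord:
    """Low-pass filter every marker trajectory.

    Zero-phase filtering applies the designed filter forward and backward;
    series length is unchanged and there is no phase lag.
    """
    nyq = trial.rate / 2.0
    if spec.cutoff >= nyq:
        raise ValueError(f"cutoff {spec.cutoff} Hz >= Nyquist {nyq} Hz")
    for arr in trial.markers.values():
        if np.isnan(arr).any():
            raise ValueError("lowpass requires gap-free trajectories; run fill_gaps")
    b, a = signal.butter(spec.order, spec.cutoff / nyq)
    markers = {}
    for lb, arr in trial.markers.items():
        if spec.zero_phase:
            markers[lb] = signal.filtfilt(b, a, arr, axis=0)
        else:
            markers[lb] = signal.lfilter(b, a, arr, axis=0)
    return trial.copy_with(markers=markers)


# ---------------------------------------------------------------------------
# virtual markers
# ---------------------------------------------------------------------------

#: Bell-style hip joint-center regression fractions of inter-ASIS distance
#: (posterior, lateral, distal from the mid-ASIS point).  Overridable.
HIP_REGRESSION = {"posterior": 0.19, "lateral": 0.36, "distal": 0.30}

#: Joint widths (m) used for medial joint-center offsets.
JOINT_WIDTHS = {"knee": 0.10, "ankle": 0.07, "elbow": 0.07, "wrist": 0.05}

MARKER_RADIUS = 0.007  # m


def _unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n < 1e-12):
        raise GeometryError("degenerate (zero-length) marker geometry")
    return v / n


def _medial_offset_center(
    lateral_marker: np.ndarray,
    axis_a: np.ndarray,
    axis_b: np.ndarray,
    offset: float,
) -> np.ndarray:
    """Joint center at ``offset`` from a lateral marker toward the segment
    line (axis_a -> axis_b), perpendicular to that line."""
    axis = _unit(axis_b - axis_a)
    rel = lateral_marker - axis_a
    foot = axis_a + np.sum(rel * axis, axis=-1, keepdims=True) * axis
    medial = _unit(foot - lateral_marker)
    return lateral_marker + offset * medial


def add_virtual_markers(
    trial: TrialRecord,
    marker_radius: float = MARKER_RADIUS,
    joint_widths: dict[str, float] | None = None,
    hip_regression: dict[str, float] | None = None,
) -> TrialRecord:
    """Add virtual joint-center markers.

    Adds MIDASI, MIDPSI, hip centers (LHJC/RHJC, inter-ASIS regression),
    knee/ankle centers (LKJC/RKJC/LAJC/RAJC, medial offset of
    ``marker_radius + width/2`` from the lateral marker), shoulder centers
    (LSJC/RSJC, below the acromion marker), and elbow/wrist centers.
    """
    jw = dict(JOINT_WIDTHS, **(joint_widths or {}))
    hr = dict(HIP_REGRESSION, **(hip_regression or {}))
    trial.require("LASI", "RASI", "LPSI", "RPSI")
    m = dict(trial.markers)
    lasi, rasi, lpsi, rpsi = m["LASI"], m["RASI"], m["LPSI"], m["RPSI"]
    midasi = 0.5 * (lasi + rasi)
    midpsi = 0.5 * (lpsi + rpsi)

    ml = lasi - rasi  # points left
    ap_raw = midasi - midpsi  # points forward
    cross = np.cross(ap_raw, ml)
    if np.any(np.linalg.norm(cross, axis=-1) < 1e-9):
        raise GeometryError("pelvis markers are collinear")
    y = _unit(ml)
    x = _unit(ap_raw - np.sum(ap_raw * y, axis=-1, keepdims=True) * y)
    z = np.cross(x, y)

    d = np.linalg.norm(lasi - rasi, axis=-1, keepdims=True)
    for side, sign in (("L", 1.0), ("R", -1.0)):
        m[f"{side}HJC"] = (
            midasi
            - hr["posterior"] * d * x
            + sign * hr["lateral"] * d * y
            - hr["distal"] * d * z
        )
    m["MIDASI"], m["MIDPSI"] = midasi, midpsi

    for side in ("L", "R"):
        trial.require(f"{side}KNE", f"{side}ANK", f"{side}HEE", f"{side}TOE")
        hjc = m[f"{side}HJC"]
        kne, ank = m[f"{side}KNE"], m[f"{side}ANK"]
        m[f"{side}KJC"] = _medial_offset_center(
            kne, hjc, ank, marker_radius + jw["knee"] / 2
        )
        m[f"{side}AJC"] = _medial_offset_center(
            ank, m[f"{side}KJC"], m[f"{side}HEE"],
            marker_radius + jw["ankle"] / 2,
        )
    for side in ("L", "R"):
        if not all(f"{side}{s}" in m for s in ("SHO", "ELB", "WRI")):
            continue
        sho, elb, wri = m[f"{side}SHO"], m[f"{side}ELB"], m[f"{side}WRI"]
        up = np.zeros_like(sho)
        up[:, 2] = 1.0
        m[f"{side}SJC"] = sho - 0.05 * up  # acromion to glenohumeral center
        m[f"{side}EJC"] = _medial_offset_center(
            elb, m[f"{side}SJC"], wri, marker_radius + jw["elbow"] / 2
        )
        # no hand marker: offset the wrist along the elbow-center medial
        # direction scaled to the wrist width
        medial = _unit(m[f"{side}EJC"] - elb)
        m[f"{side}WJC"] = wri + (marker_radius + jw["wrist"] / 2) * medial
    return trial.copy_with(markers=m)


# ---------------------------------------------------------------------------
# walking direction
# ---------------------------------------------------------------------------

def _reference_path(trial: TrialRecord) -> np.ndarray:
    """Horizontal mid-pelvis path used for direction estimates."""
    if "MIDPSI" in trial.markers:
        ref = trial.markers["MIDPSI"]
    elif "LPSI" in trial.markers and "RPSI" in trial.markers:
        ref = 0.5 * (trial.markers["LPSI"] + trial.markers["RPSI"])
    else:
        ref = np.mean(list(trial.markers.values()), axis=0)
    return ref[:, :2]


def estimate_walking_direction(
    trial: TrialRecord,
    window: tuple[float, float] | None = None,
    min_displacement: float = 0.5,
) -> np.ndarray:
    """Unit vector (2,) in the floor plane maximizing progression variance.

    The direction is the principal axis of the horizontal mid-pelvis path
    over ``window`` (seconds; full trial by default), signed by the net
    displacement.  Trials with net displacement below ``min_displacement``
    fall back to the lab X axis with a warning.
    """
    xy = _reference_path(trial)
    if window is not None:
        i0 = max(0, int(round(window[0] * trial.rate)))
        i1 = min(trial.n_frames, int(round(window[1] * trial.rate)) + 1)
        xy = xy[i0:i1]
    net = xy[-1] - xy[0]
    if np.linalg.norm(net) < min_displacement:
        warnings.warn(
            "net displacement below threshold; falling back to lab X axis",
            stacklevel=2,
        )
        return np.array([1.0, 0.0])
    c = xy - xy.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    d = vt[0]
    if np.dot(d, net) < 0:
        d = -d
    return d / np.linalg.norm(d)


def walking_direction_series(
    trial: TrialRecord, smooth_cutoff: float = 1.0, min_speed: float = 0.1
) -> np.ndarray:
    """Per-frame unit walking direction (n, 2) from the smoothed horizontal
    mid-pelvis velocity; frames slower than ``min_speed`` reuse the nearest
    moving frame (or lab X if the whole trial is stationary)."""
    xy = _reference_path(trial)
    nyq = trial.rate / 2
    b, a = signal.butter(2, min(smooth_cutoff, 0.9 * nyq) / nyq)
    pad = min(3 * max(len(a), len(b)), xy.shape[0] - 1)
    smooth = signal.filtfilt(b, a, xy, axis=0, padlen=pad)
    v = np.gradient(smooth, axis=0) * trial.rate
    speed = np.linalg.norm(v, axis=1)
    moving = speed >= min_speed
    d = np.zeros_like(v)
    if not moving.any():
        d[:, 0] = 1.0
        return d
    d[moving] = v[moving] / speed[moving, None]
    idx = np.arange(len(d))
    nearest = np.interp(idx, idx[moving], idx[moving]).round().astype(int)
    d[~moving] = d[nearest[~moving]]
    return d


# ---------------------------------------------------------------------------
# gait events
# ---------------------------------------------------------------------------

def _impulse_refine(
    extremum: int,
    z_acc: np.ndarray,
    rate: float,
    max_shift: float = 0.15,
) -> int:
    """Refine an event candidate to the peak of upward vertical
    acceleration near it.

    At foot strike the downward heel velocity is arrested; at foot off the
    toe acquires upward velocity.  Both transients produce a sharp upward
    acceleration impulse whose peak stays at the event instant under
    symmetric (zero-phase) low-pass filtering, unlike progression extrema
    or speed-threshold crossings, which carry condition-dependent bias.
    """
    span = int(round(max_shift * rate))
    lo, hi = max(0, extremum - span), min(len(z_acc), extremum + span + 1)
    return int(lo + np.argmax(z_acc[lo:hi]))


def detect_gait_events(
    trial: TrialRecord,
    walking_direction: np.ndarray | None = None,
    min_step_interval: float = 0.55,
    prominence: float = 0.04,
) -> GaitEventTable:
    """Detect foot strikes and foot offs from marker kinematics.

    Foot strike candidates are maxima of the heel-minus-mid-PSIS coordinate
    along the local walking direction; foot offs are minima of the
    toe-minus-mid-PSIS coordinate.  Each candidate is refined to the peak
    of the foot marker's upward vertical acceleration (the landing /
    lift-off transient), which removes the timing bias of the raw
    progression extremum.  Trials without progression (standing) return an
    empty table.
    """
    for lb in ("LHEE", "RHEE", "LTOE", "RTOE"):
        if lb not in trial.markers:
            raise MissingMarkerError([lb])
    if "MIDPSI" in trial.markers:
        ref = trial.markers["MIDPSI"]
    else:
        trial.require("LPSI", "RPSI")
        ref = 0.5 * (trial.markers["LPSI"] + trial.markers["RPSI"])

    if walking_direction is not None:
        d = np.broadcast_to(
            np.asarray(walking_direction, float), (trial.n_frames, 2)
        )
    else:
        d = walking_direction_series(trial)

    dist = int(round(min_step_interval * trial.rate))
    records: list[tuple[float, str, str]] = []
    for side in ("left", "right"):
        s = side[0].upper()
        heel, toe = trial.markers[f"{s}HEE"], trial.markers[f"{s}TOE"]
        rel_heel = np.sum((heel[:, :2] - ref[:, :2]) * d, axis=1)
        rel_toe = np.sum((toe[:, :2] - ref[:, :2]) * d, axis=1)
        heel_zacc = np.gradient(np.gradient(heel[:, 2])) * trial.rate**2
        toe_zacc = np.gradient(np.gradient(toe[:, 2])) * trial.rate**2
        strikes, _ = signal.find_peaks(rel_heel, distance=dist, prominence=prominence)
        offs, _ = signal.find_peaks(-rel_toe, distance=dist, prominence=prominence)
        for i in strikes:
            j = _impulse_refine(i, heel_zacc, trial.rate)
            records.append((j / trial.rate, side, "foot_strike"))
        for i in offs:
            j = _impulse_refine(i, toe_zacc, trial.rate)
            records.append((j / trial.rate, side, "foot_off"))

    if not records:
        return GaitEventTable.empty()
    records.sort()
    table = _enforce_alternation(records)
    for side in ("left", "right"):
        if len(table.strikes(side)) < 2:
            warnings.warn(
                f"fewer than 2 {side} foot strikes detected; "
                "cycle-based parameters will be missing",
                stacklevel=2,
            )
    return table


def _enforce_alternation(
    records: list[tuple[float, str, str]]
) -> GaitEventTable:
    """Keep, per side, a strictly alternating strike/off sequence (greedy,
    earliest-first)."""
    kept: list[tuple[float, str, str]] = []
    last_kind: dict[str, str | None] = {"left": None, "right": None}
    for t, side, kind in records:
        if last_kind[side] == kind:
            continue
        kept.append((t, side, kind))
        last_kind[side] = kind
    return GaitEventTable.from_records(kept)
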