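"""Kinematic parameters: head/trunk orientation angles, head anchoring
indices, normalized angular-velocity RMS, and gait variability (GaitSD).

The anchoring index contrasts the variability of head orientation in
space against its variability relative to the trunk:
AI = (sigma_r - sigma_a) / (sigma_r + sigma_a), where sigma_a is the SD of
the head-in-lab angle and sigma_r the SD of the head-relative-to-trunk
angle in the same plane.  +1 means the head is stabilized in space while
the trunk moves; -1 means head and trunk move "in block".

GaitSD summarizes between-cycle variability: each of 9 lower-body
kinematic curves is time-normalized to 101 points per gait cycle, the
variance across cycles is taken at each point, and GaitSD is the square
root of the mean variance over variables and points (degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .preprocess import GeometryError
from .trial_io import GaitEventTable, TrialRecord

__all__ = [
    "SegmentAngles",
    "CycleAngleSet",
    "GAITSD_VARIABLES",
    "segment_orientations",
    "head_anchoring_index",
    "angular_velocity_rms",
    "joint_angle_signals",
    "extract_cycles",
    "gait_sd",
]

#: The 9 lower-body variables entering GaitSD (CGM-style set).
GAITSD_VARIABLES = (
    "pelvis_tilt",
    "pelvis_obliquity",
    "pelvis_rotation",
    "hip_flexion",
    "hip_abduction",
    "hip_rotation",
    "knee_flexion",
    "ankle_dorsiflexion",
    "foot_progression",
)

_PLANES = {"yaw": 0, "pitch": 1, "roll": 2}


def _orthonormal_frames(
    forward: np.ndarray, left: np.ndarray
) -> np.ndarray:
    """(n, 3, 3) rotation matrices with columns (x=forward, y=left, z=up)
    built by Gram-Schmidt from approximate forward/left vectors."""
    xn = np.linalg.norm(forward, axis=1, keepdims=True)
    if np.any(xn < 1e-9):
        raise GeometryError("degenerate marker triad (zero forward vector)")
    x = forward / xn
    z = np.cross(x, left)
    zn = np.linalg.norm(z, axis=1, keepdims=True)
    if np.any(zn < 1e-9):
        raise GeometryError("degenerate marker triad (collinear markers)")
    z = z / zn
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=2)


def _head_frames(trial: TrialRecord) -> np.ndarray:
    trial.require("LFHD", "RFHD", "LBHD", "RBHD")
    m = trial.markers
    forward = 0.5 * (m["LFHD"] + m["RFHD"]) - 0.5 * (m["LBHD"] + m["RBHD"])
    left = 0.5 * (m["LFHD"] + m["LBHD"]) - 0.5 * (m["RFHD"] + m["RBHD"])
    return _orthonormal_frames(forward, left)


def _trunk_frames(trial: TrialRecord) -> np.ndarray:
    trial.require("C7", "T10", "CLAV", "STRN")
    m = trial.markers
    up = 0.5 * (m["C7"] + m["CLAV"]) - 0.5 * (m["T10"] + m["STRN"])
    forward = 0.5 * (m["CLAV"] + m["STRN"]) - 0.5 * (m["C7"] + m["T10"])
    # build from up/forward: z up, x forward, y left
    zn = np.linalg.norm(up, axis=1, keepdims=True)
    if np.any(zn < 1e-9):
        raise GeometryError("degenerate trunk marker set")
    z = up / zn
    y = np.cross(z, forward)
    yn = np.linalg.norm(y, axis=1, keepdims=True)
    if np.any(yn < 1e-9):
        raise GeometryError("degenerate trunk marker set")
    y = y / yn
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=2)


def _walking_frame(direction: np.ndarray) -> np.ndarray:
    d = np.asarray(direction, float)
    x = np.array([d[0], d[1], 0.0])
    x /= np.linalg.norm(x)
    z = np.array([0.0, 0.0, 1.0])
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=1)


def _cardan_zyx(R: np.ndarray) -> np.ndarray:
    """Unwrapped yaw/pitch/roll (degrees, n x 3) of a rotation series,
    intrinsic Z-Y'-X'' (yaw about vertical, pitch about ML, roll about
    AP)."""
    ang = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
    return np.unwrap(ang, axis=0, period=360.0)


@dataclass
class SegmentAngles:
    """Head and trunk orientation angles (degrees), axes tied to the
    walking direction; columns are yaw, pitch, roll."""

    head_in_lab: np.ndarray  # (n, 3)
    trunk_in_lab: np.ndarray  # (n, 3)
    head_on_trunk: np.ndarray  # (n, 3)
    rate: float


def segment_orientations(
    trial: TrialRecord, direction: np.ndarray = (1.0, 0.0)
) -> SegmentAngles:
    """Cardan angles of head and trunk versus the walking-direction frame,
    and of the head relative to the trunk."""
    Rh = _head_frames(trial)
    Rt = _trunk_frames(trial)
    Rw = _walking_frame(direction)
    head_lab = _cardan_zyx(np.einsum("ij,njk->nik", Rw.T, Rh))
    trunk_lab = _cardan_zyx(np.einsum("ij,njk->nik", Rw.T, Rt))
    head_trunk = _cardan_zyx(np.einsum("nji,njk->nik", Rt, Rh))
    return SegmentAngles(head_lab, trunk_lab, head_trunk, trial.rate)


def head_anchoring_index(angles: SegmentAngles, plane: str) -> float:
    """Anchoring index in [-1, 1] for ``plane`` in {yaw, pitch, roll}.

    Returns NaN when there is no movement at all (both SDs zero).
    """
    k = _PLANES[plane]
    sigma_a = float(np.std(angles.head_in_lab[:, k]))
    sigma_r = float(np.std(angles.head_on_trunk[:, k]))
    denom = sigma_r + sigma_a
    if denom < 1e-12:
        return float("nan")
    return (sigma_r - sigma_a) / denom


def angular_velocity_rms(
    angles: SegmentAngles,
    segment: str,
    cycle_duration: float | None = None,
    normalization: str = "per_percent_cycle",
) -> float:
    """RMS of the segment's angular-velocity magnitude over the trial.

    The velocity is the time derivative of the three Cardan angles.  With
    the default normalization the velocity is expressed per percent of
    gait cycle (multiplied by cycle_duration / 100), removing cadence
    differences between participants; ``'none'`` reports deg/s.
    """
    series = {"head": angles.head_in_lab, "trunk": angles.trunk_in_lab}[segment]
    vel = np.gradient(series, axis=0) * angles.rate  # deg/s
    mag = np.linalg.norm(vel, axis=1)
    if normalization == "per_percent_cycle":
        if cycle_duration is None or not np.isfinite(cycle_duration):
            return float("nan")
        mag = mag * (cycle_duration / 100.0)  # deg per %cycle
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return float(np.sqrt(np.mean(mag**2)))


# ---------------------------------------------------------------------------
# GaitSD
# ---------------------------------------------------------------------------

def _signed_angle_about(v1: np.ndarray, v2: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Signed angle (deg) from v1 to v2 about ``axis`` (all (n,3))."""
    cross = np.cross(v1, v2)
    s = np.sum(cross * axis, axis=1)
    c = np.sum(v1 * v2, axis=1)
    return np.degrees(np.arctan2(s, c))


def joint_angle_signals(
    trial: TrialRecord, side: str, direction: np.ndarray = (1.0, 0.0)
) -> dict[str, np.ndarray]:
    """The 9 GaitSD angle signals (degrees) for the analysis side.

    Pelvis angles are Cardan angles of the pelvis frame versus the walking
    frame; hip angles of the thigh versus the pelvis; knee flexion is the
    thigh-shank long-axis angle; ankle dorsiflexion the shank-foot angle
    offset by 90 degrees; foot progression the foot yaw versus the walking
    direction.  Requires the virtual joint-center markers.
    """
    s = side[0].upper()
    trial.require("LASI", "RASI", "MIDASI", "MIDPSI",
                  f"{s}HJC", f"{s}KJC", f"{s}AJC",
                  f"{s}KNE", f"{s}ANK", f"{s}HEE", f"{s}TOE")
    m = trial.markers
    Rw = _walking_frame(direction)

    pel_forward = m["MIDASI"] - m["MIDPSI"]
    pel_left = m["LASI"] - m["RASI"]
    Rp = _orthonormal_frames(pel_forward, pel_left)
    pel = _cardan_zyx(np.einsum("ij,njk->nik", Rw.T, Rp))

    sign = 1.0 if s == "L" else -1.0
    thigh_up = m[f"{s}HJC"] - m[f"{s}KJC"]
    thigh_left = sign * (m[f"{s}KJC"] - m[f"{s}KNE"])
    # thigh frame: z up the segment, y flexion axis
    zt = thigh_up / np.linalg.norm(thigh_up, axis=1, keepdims=True)
    xt = np.cross(thigh_left, zt)
    xt /= np.linalg.norm(xt, axis=1, keepdims=True)
    yt = np.cross(zt, xt)
    Rt = np.stack([xt, yt, zt], axis=2)
    hip = _cardan_zyx(np.einsum("nji,njk->nik", Rp, Rt))

    shank_axis = m[f"{s}KJC"] - m[f"{s}AJC"]
    knee_flexion = _signed_angle_about(
        shank_axis / np.linalg.norm(shank_axis, axis=1, keepdims=True),
        thigh_up / np.linalg.norm(thigh_up, axis=1, keepdims=True),
        yt,
    )

    foot_axis = m[f"{s}TOE"] - m[f"{s}HEE"]
    fa = foot_axis / np.linalg.norm(foot_axis, axis=1, keepdims=True)
    sa = shank_axis / np.linalg.norm(shank_axis, axis=1, keepdims=True)
    ankle = 90.0 - np.degrees(np.arccos(np.clip(np.sum(fa * sa, axis=1), -1, 1)))

    d3 = np.array([direction[0], direction[1], 0.0])
    foot_prog = _signed_angle_about(
        np.broadcast_to(d3 / np.linalg.norm(d3), fa.shape),
        np.stack([fa[:, 0], fa[:, 1], np.zeros(len(fa))], axis=1),
        np.broadcast_to(np.array([0.0, 0.0, 1.0]), fa.shape),
    )

    return {
        "pelvis_tilt": pel[:, 1],
        "pelvis_obliquity": pel[:, 2],
        "pelvis_rotation": pel[:, 0],
        "hip_flexion": hip[:, 1],
        "hip_abduction": hip[:, 2],
        "hip_rotation": hip[:, 0],
        "knee_flexion": knee_flexion,
        "ankle_dorsiflexion": ankle,
        "foot_progression": foot_prog,
    }


@dataclass
class CycleAngleSet:
    """Per-cycle, time-normalized (101-point) kinematic curves; each entry
    is an (n_cycles, 101) array in degrees."""

    curves: dict[str, np.ndarray]

    @property
    def n_cycles(self) -> int:
        return next(iter(self.curves.values())).shape[0]


def extract_cycles(
    signals: dict[str, np.ndarray],
    events: GaitEventTable,
    side: str,
    rate: float,
    n_points: int = 101,
) -> CycleAngleSet:
    """Cut each signal into gait cycles (strike to next strike of the
    analysis side) and resample each cycle to ``n_points`` samples."""
    strikes = events.strikes(side)
    curves = {name: [] for name in signals}
    n_frames = len(next(iter(signals.values())))
    for t0, t1 in zip(strikes[:-1], strikes[1:]):
        i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
        if i1 - i0 < 4 or i1 >= n_frames:
            continue
        src_t = np.arange(i0, i1 + 1)
        dst_t = np.linspace(i0, i1, n_points)
        for name, sig in signals.items():
            curves[name].append(np.interp(dst_t, src_t, sig[i0 : i1 + 1]))
    return CycleAngleSet(
        {name: np.asarray(c).reshape(-1, n_points) for name, c in curves.items()}
    )


def gait_sd(cycles: CycleAngleSet) -> float:
    """GaitSD (degrees): sqrt of the mean across variables and cycle time
    points of the between-cycle variance.  NaN with fewer than 2 cycles."""
    if cycles.n_cycles < 2:
        return float("nan")
    variances = [np.var(c, axis=0, ddof=1) for c in cycles.curves.values()]
    return float(np.sqrt(np.mean(np.concatenate(variances))))
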