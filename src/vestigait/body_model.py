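"""Anthropometric segment models: whole-body center of mass (9 segments)
and whole-body angular momentum (13 segments).

Segment mass fractions, CoM ratios and gyration radii follow standard
adult anthropometric tables (de Leva / Dumas style) and are overridable.
The CoM model lumps head+trunk and both arms so that only the canonical
marker set is needed; the momentum model splits the trunk, head, and arms
(upper arm, forearm+hand per side).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trial_io import TrialRecord

__all__ = [
    "SegmentSpec",
    "BodyModel",
    "ComTrajectory",
    "ModelError",
    "build_com_model",
    "build_momentum_model",
    "compute_com",
    "compute_wbam",
]

G = 9.81  # m/s^2


class ModelError(ValueError):
    """Raised when a model landmark cannot be resolved in a trial."""


@dataclass(frozen=True)
class SegmentSpec:
    """One rigid segment.

    ``proximal``/``distal`` are tuples of marker labels averaged into the
    endpoint positions.  ``com_ratio`` locates the segment CoM as a
    fraction of the proximal-to-distal vector.  ``gyration`` holds the
    three radii of gyration about the segment CoM axes as fractions of
    segment length (x forward-ish, y flexion axis, z longitudinal).
    ``lateral`` is an optional landmark fixing the segment frame about its
    long axis (needed only for angular momentum).
    """

    name: str
    proximal: tuple[str, ...]
    distal: tuple[str, ...]
    mass_fraction: float
    com_ratio: float = 0.5
    gyration: tuple[float, float, float] = (0.3, 0.3, 0.15)
    lateral: tuple[str, ...] = ()

    def __post_init__(self):
        if not (0.0 <= self.com_ratio <= 1.0):
            raise ValueError(f"{self.name}: com_ratio outside [0, 1]")
        if self.mass_fraction <= 0 or any(g <= 0 for g in self.gyration):
            raise ValueError(f"{self.name}: fractions must be positive")


@dataclass
class BodyModel:
    """A list of segments with total mass and height."""

    segments: list[SegmentSpec]
    total_mass: float = 72.0  # kg
    height: float = 1.70  # m

    def __post_init__(self):
        total = sum(s.mass_fraction for s in self.segments)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"segment mass fractions sum to {total}, not 1")

    def landmarks(self) -> set[str]:
        out: set[str] = set()
        for s in self.segments:
            out.update(s.proximal, s.distal, s.lateral)
        return out


@dataclass
class ComTrajectory:
    """Whole-body CoM position and velocity series (m, m/s)."""

    position: np.ndarray  # (n, 3)
    velocity: np.ndarray  # (n, 3)
    rate: float

    @property
    def mean_height(self) -> float:
        return float(np.mean(self.position[:, 2]))


# mass fractions (sum to 1 within each model); de Leva-style adult values
_MOMENTUM_SEGMENTS: list[dict] = [
    dict(name="head", proximal=("LFHD", "RFHD", "LBHD", "RBHD"), distal=("C7",),
         mass_fraction=0.0694, com_ratio=0.5, gyration=(0.36, 0.36, 0.26),
         lateral=("LFHD", "LBHD")),
    dict(name="thorax", proximal=("C7", "CLAV"), distal=("T10", "STRN"),
         mass_fraction=0.3229, com_ratio=0.55, gyration=(0.32, 0.31, 0.28),
         lateral=("LSHO",)),
    dict(name="pelvis", proximal=("LASI", "RASI"), distal=("LPSI", "RPSI"),
         mass_fraction=0.1117, com_ratio=0.5, gyration=(0.55, 0.59, 0.59),
         lateral=("LASI",)),
    dict(name="left_upper_arm", proximal=("LSJC",), distal=("LEJC",),
         mass_fraction=0.0271, com_ratio=0.577, gyration=(0.28, 0.27, 0.16),
         lateral=("LELB",)),
    dict(name="right_upper_arm", proximal=("RSJC",), distal=("REJC",),
         mass_fraction=0.0271, com_ratio=0.577, gyration=(0.28, 0.27, 0.16),
         lateral=("RELB",)),
    dict(name="left_forearm_hand", proximal=("LEJC",), distal=("LWJC",),
         mass_fraction=0.0223, com_ratio=0.57, gyration=(0.30, 0.29, 0.13),
         lateral=("LWRI",)),
    dict(name="right_forearm_hand", proximal=("REJC",), distal=("RWJC",),
         mass_fraction=0.0223, com_ratio=0.57, gyration=(0.30, 0.29, 0.13),
         lateral=("RWRI",)),
    dict(name="left_thigh", proximal=("LHJC",), distal=("LKJC",),
         mass_fraction=0.1416, com_ratio=0.41, gyration=(0.33, 0.33, 0.15),
         lateral=("LKNE",)),
    dict(name="right_thigh", proximal=("RHJC",), distal=("RKJC",),
         mass_fraction=0.1416, com_ratio=0.41, gyration=(0.33, 0.33, 0.15),
         lateral=("RKNE",)),
    dict(name="left_shank", proximal=("LKJC",), distal=("LAJC",),
         mass_fraction=0.0433, com_ratio=0.44, gyration=(0.25, 0.25, 0.10),
         lateral=("LANK",)),
    dict(name="right_shank", proximal=("RKJC",), distal=("RAJC",),
         mass_fraction=0.0433, com_ratio=0.44, gyration=(0.25, 0.25, 0.10),
         lateral=("RANK",)),
    dict(name="left_foot", proximal=("LHEE",), distal=("LTOE",),
         mass_fraction=0.0137, com_ratio=0.44, gyration=(0.26, 0.25, 0.12),
         lateral=("LANK",)),
    dict(name="right_foot", proximal=("RHEE",), distal=("RTOE",),
         mass_fraction=0.0137, com_ratio=0.44, gyration=(0.26, 0.25, 0.12),
         lateral=("RANK",)),
]

_COM_SEGMENTS: list[dict] = [
    dict(name="head_trunk", proximal=("LFHD", "RFHD", "LBHD", "RBHD"),
         distal=("T10", "STRN"), mass_fraction=0.3923, com_ratio=0.55),
    dict(name="pelvis", proximal=("LASI", "RASI"), distal=("LPSI", "RPSI"),
         mass_fraction=0.1117, com_ratio=0.5),
    dict(name="arms", proximal=("LSHO", "RSHO"), distal=("LWRI", "RWRI"),
         mass_fraction=0.0988, com_ratio=0.53),
    dict(name="left_thigh", proximal=("LHJC",), distal=("LKJC",),
         mass_fraction=0.1416, com_ratio=0.41),
    dict(name="right_thigh", proximal=("RHJC",), distal=("RKJC",),
         mass_fraction=0.1416, com_ratio=0.41),
    dict(name="left_shank", proximal=("LKJC",), distal=("LAJC",),
         mass_fraction=0.0433, com_ratio=0.44),
    dict(name="right_shank", proximal=("RKJC",), distal=("RAJC",),
         mass_fraction=0.0433, com_ratio=0.44),
    dict(name="left_foot", proximal=("LHEE",), distal=("LTOE",),
         mass_fraction=0.0137, com_ratio=0.44),
    dict(name="right_foot", proximal=("RHEE",), distal=("RTOE",),
         mass_fraction=0.0137, com_ratio=0.44),
]


def build_com_model(total_mass: float = 72.0, height: float = 1.70) -> BodyModel:
    """The 9-segment CoM model (head+trunk, pelvis, lumped arms, thighs,
    shanks, feet)."""
    segs = [SegmentSpec(**d) for d in _COM_SEGMENTS]
    return BodyModel(segs, total_mass, height)


def build_momentum_model(total_mass: float = 72.0, height: float = 1.70) -> BodyModel:
    """The 13-segment whole-body angular momentum model."""
    segs = [SegmentSpec(**d) for d in _MOMENTUM_SEGMENTS]
    return BodyModel(segs, total_mass, height)


def _landmark(trial: TrialRecord, labels: tuple[str, ...], segment: str) -> np.ndarray:
    missing = [lb for lb in labels if lb not in trial.markers]
    if missing:
        raise ModelError(
            f"segment {segment!r}: missing landmark(s) {', '.join(missing)}"
        )
    return np.mean([trial.markers[lb] for lb in labels], axis=0)


def compute_com(trial: TrialRecord, model: BodyModel) -> ComTrajectory:
    """Whole-body CoM: mass-fraction-weighted sum of segment CoMs.

    Velocity is obtained by central differences at the trial rate.
    """
    com = np.zeros((trial.n_frames, 3))
    for seg in model.segments:
        p = _landmark(trial, seg.proximal, seg.name)
        d = _landmark(trial, seg.distal, seg.name)
        com += seg.mass_fraction * (p + seg.com_ratio * (d - p))
    vel = np.gradient(com, axis=0) * trial.rate
    return ComTrajectory(position=com, velocity=vel, rate=trial.rate)


def _segment_rotations(
    p: np.ndarray, d: np.ndarray, lat: np.ndarray
) -> np.ndarray:
    """Per-frame rotation matrices (n, 3, 3) of a segment frame:
    z longitudinal (distal->proximal), y toward the lateral landmark
    (flexion axis), x completing the right-handed triad."""
    z = p - d
    zn = np.linalg.norm(z, axis=1, keepdims=True)
    if np.any(zn < 1e-9):
        raise ModelError("segment with zero length")
    z = z / zn
    yraw = lat - d
    x = np.cross(yraw, z)
    xn = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(xn < 1e-9):
        raise ModelError("lateral landmark collinear with segment axis")
    x = x / xn
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=2)  # columns are the frame axes


def _angular_velocity(R: np.ndarray, rate: float) -> np.ndarray:
    """Lab-frame angular velocity (n, 3) from a rotation series via the
    skew-symmetric part of dR/dt R^T."""
    dR = np.gradient(R, axis=0) * rate
    W = np.einsum("nij,nkj->nik", dR, R)  # dR R^T
    W = 0.5 * (W - np.transpose(W, (0, 2, 1)))
    return np.stack([W[:, 2, 1], W[:, 0, 2], W[:, 1, 0]], axis=1)


def compute_wbam(
    trial: TrialRecord,
    model: BodyModel,
    com: ComTrajectory,
    normalize: str = "mass_height_speed",
    walking_speed: float | None = None,
) -> np.ndarray:
    """Whole-body angular momentum about the whole-body CoM, (n, 3) in lab
    axes.

    Each segment contributes a remote term m_i (r_i - r_com) x (v_i -
    v_com) and a spin term R_i I_i R_i^T w_i with the inertia tensor from
    the gyration radii.  With ``normalize='mass_height_speed'`` the result
    is made dimensionless by dividing by body mass x height x walking
    speed (trials slower than 0.1 m/s are left unnormalized in absolute
    units).
    """
    n = trial.n_frames
    L = np.zeros((n, 3))
    for seg in model.segments:
        p = _landmark(trial, seg.proximal, seg.name)
        d = _landmark(trial, seg.distal, seg.name)
        m_i = seg.mass_fraction * model.total_mass
        r = p + seg.com_ratio * (d - p)
        v = np.gradient(r, axis=0) * trial.rate
        L += m_i * np.cross(r - com.position, v - com.velocity)
        if seg.lateral:
            lat = _landmark(trial, seg.lateral, seg.name)
            R = _segment_rotations(p, d, lat)
            omega = _angular_velocity(R, trial.rate)
            length = float(np.median(np.linalg.norm(p - d, axis=1)))
            inertia = m_i * (np.asarray(seg.gyration) * length) ** 2
            omega_loc = np.einsum("nji,nj->ni", R, omega)
            L += np.einsum("nij,nj->ni", R, inertia * omega_loc)
    if normalize == "none":
        return L
    if normalize != "mass_height_speed":
        raise ValueError(f"unknown normalization {normalize!r}")
    if walking_speed is None:
        horiz = com.velocity[:, :2]
        walking_speed = float(np.linalg.norm(horiz.mean(axis=0)))
    if walking_speed < 0.1:
        return L
    return L / (model.total_mass * model.height * walking_speed)
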