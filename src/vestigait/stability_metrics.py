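"""Dynamic-stability parameters: medio-lateral CoM range of motion,
extrapolated CoM, margins of stability, and whole-body angular momentum
ranges per plane.

The extrapolated CoM follows the inverted-pendulum formulation
xCoM = CoM + v / omega0 with omega0 = sqrt(g / l), l the mean vertical CoM
height.  The margin of stability is the signed distance from the xCoM to
the base of support, here the lateral malleolar marker of the leading foot
at its foot strike; positive values indicate a mechanically stable
configuration (xCoM inside the base of support).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .body_model import ComTrajectory, G
from .trial_io import GaitEventTable, TrialRecord

__all__ = [
    "XcomParams",
    "MosResult",
    "ml_axis",
    "ml_com_rom",
    "extrapolated_com",
    "margin_of_stability",
    "wbam_range",
]


@dataclass(frozen=True)
class XcomParams:
    """Inverted-pendulum parameters for the extrapolated CoM."""

    l: float  # pendulum length: mean vertical CoM height (m)
    g: float = G

    def __post_init__(self):
        if self.l <= 0:
            raise ValueError("pendulum length must be positive")

    @property
    def omega0(self) -> float:
        return float(np.sqrt(self.g / self.l))

    @classmethod
    def from_com(cls, com: ComTrajectory, g: float = G) -> "XcomParams":
        return cls(l=com.mean_height, g=g)


@dataclass
class MosResult:
    """Per-cycle margins of stability and their per-trial median."""

    values: np.ndarray  # per-cycle MoS (m)
    times: np.ndarray  # leading-foot strike times (s)
    side: str
    plane: str  # 'ML' or 'AP'

    @property
    def median(self) -> float:
        if len(self.values) == 0:
            return float("nan")
        return float(np.median(self.values))


def ml_axis(direction: np.ndarray) -> np.ndarray:
    """Left-pointing medio-lateral unit axis for a floor-plane walking
    direction (rotation by +90 degrees about vertical)."""
    d = np.asarray(direction, float)
    return np.array([-d[1], d[0]])


def ml_com_rom(
    com: ComTrajectory, direction: np.ndarray, detrend: bool = True
) -> float:
    """Medio-lateral range of motion of the CoM: max minus min of the
    (linearly detrended) ML CoM coordinate over the trial."""
    ml = com.position[:, :2] @ ml_axis(direction)
    if detrend:
        ml = _signal.detrend(ml)
    return float(np.max(ml) - np.min(ml))


def extrapolated_com(com: ComTrajectory, params: XcomParams) -> np.ndarray:
    """Extrapolated CoM (n, 2): horizontal CoM plus horizontal velocity
    divided by the pendulum eigenfrequency."""
    return com.position[:, :2] + com.velocity[:, :2] / params.omega0


def _at_time(series: np.ndarray, t: float, rate: float) -> np.ndarray:
    """Linear interpolation of an (n, k) series at time t."""
    x = t * rate
    i = int(np.clip(np.floor(x), 0, series.shape[0] - 2))
    frac = x - i
    return (1 - frac) * series[i] + frac * series[i + 1]


def margin_of_stability(
    trial: TrialRecord,
    events: GaitEventTable,
    com: ComTrajectory,
    params: XcomParams,
    side: str,
    plane: str,
    direction: np.ndarray,
) -> MosResult:
    """Margin of stability at each leading-foot strike of ``side``.

    ML: positive when the xCoM is medial to the lateral malleolus of the
    leading foot.  AP: positive when the xCoM is behind the malleolus
    along the walking direction.  The per-trial value is the median over
    cycles.
    """
    if plane not in ("ML", "AP"):
        raise ValueError("plane must be 'ML' or 'AP'")
    marker = f"{side[0].upper()}ANK"
    trial.require(marker)
    xcom = extrapolated_com(com, params)
    strikes = events.strikes(side)
    strikes = strikes[(strikes >= 0) & (strikes <= trial.duration)]
    if len(strikes) == 0:
        warnings.warn(f"no {side} foot strikes; MoS missing", stacklevel=2)
        return MosResult(np.array([]), np.array([]), side, plane)
    d = np.asarray(direction, float)
    ml = ml_axis(d)
    values = []
    for t in strikes:
        bos = _at_time(trial.markers[marker][:, :2], t, trial.rate)
        xc = _at_time(xcom, t, trial.rate)
        if plane == "ML":
            sign = 1.0 if side == "left" else -1.0
            values.append(sign * float((bos - xc) @ ml))
        else:
            values.append(float((bos - xc) @ d))
    return MosResult(np.asarray(values), strikes, side, plane)


def wbam_range(
    wbam: np.ndarray, direction: np.ndarray, plane: str
) -> float:
    """Range (max minus min) of one plane's angular-momentum component.

    Components are taken about walking-direction-tied axes: sagittal about
    the ML axis, coronal about the AP (progression) axis, transverse about
    the vertical.  (The clinical literature sometimes names the coronal
    plane 'frontal'; they are synonyms and map to the same component.)
    """
    d = np.asarray(direction, float)
    axes = {
        "sagittal": np.array([-d[1], d[0], 0.0]),
        "coronal": np.array([d[0], d[1], 0.0]),
        "transverse": np.array([0.0, 0.0, 1.0]),
    }
    if plane not in axes:
        raise ValueError(f"plane must be one of {sorted(axes)}")
    comp = wbam @ axes[plane]
    return float(np.max(comp) - np.min(comp))
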