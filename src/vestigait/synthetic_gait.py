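"""Synthetic marker-trajectory walker with ground-truth sidecars.

The walker is purely kinematic: marker positions are analytic functions of
gait phase plus noise, which is sufficient because every analysed
parameter is positional/kinematic.  A cohort generator draws per-subject
gait parameters from group presets (walking speed anchored to the three
study groups' printed comfortable-gait means/SDs), couples a latent
severity to both the gait deviations and the simulated DHI score, and
renders each protocol task with task-specific modifiers (eyes closed:
sway/width multipliers; tandem: on-line heel-to-toe placements with an
off-line hazard; turn pivot: two straight legs joined by a 180-degree
turn; head-turn tasks: imposed head oscillation).

Every trial carries a ground-truth sidecar (event times, step placements,
programmed parameter values) sufficient to score each detector and
estimator in the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .trial_io import GaitEventTable, SubjectMeta, TrialRecord

__all__ = [
    "ImpairmentProfile",
    "SubjectDraw",
    "PRESETS",
    "generate_trial",
    "generate_cohort",
    "generate_standing_trial",
    "Cohort",
]

RATE = 100.0  # Hz


@dataclass(frozen=True)
class ImpairmentProfile:
    """Group-level generative gait parameters (means and between-subject
    SDs)."""

    walking_speed: tuple[float, float] = (1.29, 0.09)  # m/s
    cadence: tuple[float, float] = (112.0, 5.0)  # steps/min
    step_width: tuple[float, float] = (0.10, 0.015)  # m
    ml_sway: tuple[float, float] = (0.018, 0.004)  # m amplitude
    head_trunk_coupling: float = 0.35  # 1 = head rigidly follows trunk
    catchup_rate: float = 0.0  # events/min
    catchup_magnitude: float = 0.12  # m
    placement_noise_sd: float = 0.008  # m (ML per step)
    timing_noise_sd: float = 0.008  # s per step
    kinematic_noise_sd: float = 1.2  # deg, per-cycle amplitude jitter
    double_support_fraction: float = 0.24  # of the gait cycle
    tandem_offline_hazard: float = 0.0  # per-step prob of off-line step
    walk_drift_step: float = 0.004  # m/step lateral veer (random walk)
    eyes_closed_width_mult: float = 1.05
    eyes_closed_sway_mult: float = 1.10
    eyes_closed_drift_step: float = 0.010  # veer grows without vision
    dhi_intercept: float = 2.0
    dhi_slope: float = 30.0  # on latent severity in [0, 1]
    dhi_noise_sd: float = 4.0

    def __post_init__(self):
        for pair in (self.walking_speed, self.cadence, self.step_width,
                     self.ml_sway):
            if pair[0] <= 0 or pair[1] < 0:
                raise ValueError("means must be > 0 and SDs >= 0")
        if not 0.0 <= self.head_trunk_coupling <= 1.0:
            raise ValueError("head_trunk_coupling must be in [0, 1]")


#: Group presets.  Walking speed anchors to the study groups' printed
#: comfortable-gait summaries; widths, sway, coupling and catch-up rates
#: are synthetic values chosen to reproduce the qualitative group
#: contrasts (patients: slower, wider, swaying more, head and trunk moving
#: "in block", occasional lateral catch-up steps).
PRESETS: dict[str, ImpairmentProfile] = {
    "HS": ImpairmentProfile(),
    "UV": ImpairmentProfile(
        walking_speed=(1.05, 0.17), cadence=(106.0, 6.0),
        step_width=(0.12, 0.02), ml_sway=(0.024, 0.005),
        head_trunk_coupling=0.55, catchup_rate=1.0,
        placement_noise_sd=0.012, kinematic_noise_sd=1.8,
        tandem_offline_hazard=0.10, walk_drift_step=0.008,
        eyes_closed_width_mult=1.20, eyes_closed_sway_mult=1.40,
        eyes_closed_drift_step=0.030,
        dhi_intercept=5.0, dhi_slope=55.0, dhi_noise_sd=10.0,
    ),
    "BV": ImpairmentProfile(
        walking_speed=(1.09, 0.22), cadence=(108.0, 6.0),
        step_width=(0.16, 0.025), ml_sway=(0.032, 0.006),
        head_trunk_coupling=0.75, catchup_rate=2.0,
        catchup_magnitude=0.15, placement_noise_sd=0.015,
        kinematic_noise_sd=2.2, tandem_offline_hazard=0.25,
        walk_drift_step=0.012,
        eyes_closed_width_mult=1.35, eyes_closed_sway_mult=1.70,
        eyes_closed_drift_step=0.050,
        dhi_intercept=8.0, dhi_slope=60.0, dhi_noise_sd=12.0,
    ),
}


def null_presets() -> dict[str, ImpairmentProfile]:
    """Negative-control presets: all three groups share one profile and
    the simulated DHI is dispersed but unrelated to gait severity, so the
    cohort carries no discriminant and no convergent signal."""
    profile = replace(PRESETS["HS"], dhi_slope=0.0, dhi_intercept=30.0,
                      dhi_noise_sd=15.0)
    return {g: profile for g in ("BV", "UV", "HS")}


@dataclass
class SubjectDraw:
    """Realized per-subject gait parameters."""

    subject_id: str
    group: str
    severity: float  # latent, in [0, 1]
    speed: float
    cadence: float
    step_width: float
    ml_sway: float
    coupling: float
    height: float
    mass: float
    affected_side: str = "none"
    dhi: float | None = None


# task modifiers applied on top of a subject's comfortable-gait parameters
_TASK_SPEED = {
    "slow_gait": 0.70, "fast_gait": 1.25,
    "double_task_animal": 0.90, "double_task_letter": 0.90,
    "change_speed": 0.95, "horizontal_head_turns": 0.92,
    "vertical_head_turns": 0.92, "turn_pivot": 0.95,
    "step_obstacle": 0.95, "backwards": 0.55, "steps": 0.50,
}
_TASK_CADENCE = {
    "slow_gait": 0.85, "fast_gait": 1.12, "backwards": 0.75,
    "steps": 0.70, "tandem_walk": 0.60,
}


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _rot_z(theta: np.ndarray) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    zero, one = np.zeros_like(c), np.ones_like(c)
    return np.stack(
        [np.stack([c, -s, zero], -1),
         np.stack([s, c, zero], -1),
         np.stack([zero, zero, one], -1)], axis=-2)


def _rot_y(theta: np.ndarray) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    zero, one = np.zeros_like(c), np.ones_like(c)
    return np.stack(
        [np.stack([c, zero, s], -1),
         np.stack([zero, one, zero], -1),
         np.stack([-s, zero, c], -1)], axis=-2)


def _rot_x(theta: np.ndarray) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    zero, one = np.zeros_like(c), np.ones_like(c)
    return np.stack(
        [np.stack([one, zero, zero], -1),
         np.stack([zero, c, -s], -1),
         np.stack([zero, s, c], -1)], axis=-2)


def _two_link_ik(
    hip: np.ndarray, ankle: np.ndarray, forward: np.ndarray,
    l_thigh: float, l_shank: float,
) -> np.ndarray:
    """Knee center from hip and ankle positions: two-link inverse
    kinematics with the knee flexing toward ``forward``."""
    ha = ankle - hip
    d = np.linalg.norm(ha, axis=-1)
    d = np.clip(d, 1e-6, 0.999 * (l_thigh + l_shank))
    u = ha / d[..., None]
    a = (l_thigh**2 - l_shank**2 + d**2) / (2 * d)
    h = np.sqrt(np.maximum(l_thigh**2 - a**2, 0.0))
    perp = forward - np.sum(forward * u, axis=-1, keepdims=True) * u
    pn = np.linalg.norm(perp, axis=-1, keepdims=True)
    perp = np.where(pn > 1e-9, perp / np.maximum(pn, 1e-12),
                    np.broadcast_to([1.0, 0.0, 0.0], perp.shape))
    return hip + a[..., None] * u + h[..., None] * perp


def _interp_steps(t: np.ndarray, step_times: np.ndarray,
                  values: np.ndarray) -> np.ndarray:
    return np.interp(t, step_times, values)


def generate_standing_trial(
    subject_id: str = "calib", height: float = 1.70, mass: float = 72.0,
    duration: float = 10.0, seed: int = 0, noise_sd: float = 0.0003,
) -> TrialRecord:
    """A quiet-standing calibration trial (markers static plus tiny
    measurement noise)."""
    draw = SubjectDraw(subject_id, "HS", 0.0, 1.0, 110.0, 0.10, 0.0, 0.5,
                       height, mass)
    trial, _ = generate_trial(PRESETS["HS"], "comfortable_gait", draw, seed,
                              n_steps=2, standing=True, duration=duration,
                              marker_noise_sd=noise_sd)
    return trial.copy_with(task="standing")


def generate_trial(
    profile: ImpairmentProfile,
    task: str,
    draw: SubjectDraw,
    seed: int,
    n_steps: int = 12,
    standing: bool = False,
    duration: float | None = None,
    marker_noise_sd: float = 0.0003,
) -> tuple[TrialRecord, dict]:
    """Render one trial of ``task`` for a drawn subject.

    Returns the trial and a ground-truth sidecar with true event times,
    step placements and the programmed parameter values.
    """
    from .trial_io import TASKS  # local import to avoid cycle at import time

    if task not in TASKS and task != "standing":
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng(seed)
    H = draw.height

    speed = draw.speed * _TASK_SPEED.get(task, 1.0)
    cadence = draw.cadence * _TASK_CADENCE.get(task, 1.0)
    width = draw.step_width
    sway = draw.ml_sway
    coupling = draw.coupling
    if task == "eyes_closed":
        width *= profile.eyes_closed_width_mult
        sway *= profile.eyes_closed_sway_mult
    tandem = task == "tandem_walk"
    if tandem:
        width = 0.0

    t_step = 60.0 / cadence
    t_cycle = 2.0 * t_step
    step_length = 0.25 if tandem else speed * t_step
    if tandem:
        speed = step_length / t_step
    ds_half = profile.double_support_fraction * t_cycle / 2.0

    # --- step timeline and placements -------------------------------------
    lead_in = 0.6
    k = np.arange(n_steps)
    strike_times = lead_in + k * t_step + np.cumsum(
        rng.normal(0.0, profile.timing_noise_sd, n_steps))
    strike_times = np.maximum.accumulate(strike_times)  # keep ordered
    sides = np.where(k % 2 == 0, "left", "right")
    side_sign = np.where(sides == "left", 1.0, -1.0)

    # heading per step (turn-pivot: out, 180-degree turn, back)
    heading = np.zeros(n_steps)
    if task == "turn_pivot":
        half = n_steps // 2
        ramp = np.clip((k - (half - 2)) / 4.0, 0.0, 1.0)
        heading = math.pi * ramp
    elif task == "backwards":
        heading[:] = math.pi

    # centerline positions per step
    center = np.zeros((n_steps, 2))
    for i in range(1, n_steps):
        u = np.array([math.cos(heading[i]), math.sin(heading[i])])
        center[i] = center[i - 1] + step_length * u

    lateral = side_sign * width / 2.0
    lateral = lateral + rng.normal(0.0, profile.placement_noise_sd, n_steps)
    # slow lateral veer (random walk), amplified without vision
    drift_step = (profile.eyes_closed_drift_step if task == "eyes_closed"
                  else profile.walk_drift_step)
    if not tandem and drift_step > 0:
        lateral = lateral + np.cumsum(rng.normal(0.0, drift_step, n_steps))
    catchup_flags = np.zeros(n_steps, bool)
    p_catch = profile.catchup_rate / 60.0 * t_step
    offline_flags = np.zeros(n_steps, bool)
    if tandem:
        offline = rng.random(n_steps) < profile.tandem_offline_hazard
        first = np.argmax(offline) if offline.any() else n_steps
        if first < n_steps:
            offline_flags[first] = True
            lateral[first:] += side_sign[first] * 0.30
    else:
        catch = (rng.random(n_steps) < p_catch) & (k >= 2) & (k < n_steps - 1)
        for i in np.flatnonzero(catch):
            lateral[i] += side_sign[i] * profile.catchup_magnitude
            catchup_flags[i] = True

    normal = np.stack([-np.sin(heading), np.cos(heading)], axis=1)
    placements = center + lateral[:, None] * normal  # heel landing points

    total_dur = duration if duration is not None else (
        strike_times[-1] + t_step + lead_in)
    n_frames = int(round(total_dur * RATE)) + 1
    t = np.arange(n_frames) / RATE

    # --- pelvis trajectory -------------------------------------------------
    l_thigh = 0.275 * H
    l_shank = 0.275 * H
    ankle_h = 0.035 * H
    pelvis_h = l_thigh + l_shank + ankle_h + 0.30 * 0.24 - 0.012 * H
    phase = 2.0 * math.pi * t / t_cycle

    if standing:
        center_t = np.zeros((n_frames, 2))
        heading_t = np.zeros(n_frames)
        sway_t = np.zeros(n_frames)
    else:
        # extend the per-step centerline by one virtual step on each end so
        # the pelvis keeps progressing through lead-in and lead-out
        u0 = np.array([math.cos(heading[0]), math.sin(heading[0])])
        u1 = np.array([math.cos(heading[-1]), math.sin(heading[-1])])
        ext_times = np.r_[strike_times[0] - t_step, strike_times,
                          strike_times[-1] + t_step]
        ext_center = np.vstack([center[0] - step_length * u0, center,
                                center[-1] + step_length * u1])
        ext_heading = np.r_[heading[0], heading, heading[-1]]
        center_t = np.stack(
            [_interp_steps(t, ext_times, ext_center[:, 0]),
             _interp_steps(t, ext_times, ext_center[:, 1])], axis=1)
        heading_t = _interp_steps(t, ext_times, ext_heading)
        mid_steps = np.convolve(lateral, [0.5, 0.5], mode="same")
        mid_t = _interp_steps(t, ext_times,
                              np.r_[mid_steps[0], mid_steps, mid_steps[-1]])
        b, a = _signal.butter(2, 1.2 / (RATE / 2))
        mid_t = _signal.filtfilt(b, a, mid_t)
        # CoM sways toward the stance side each step
        sway_t = mid_t + sway * np.sin(
            2.0 * math.pi * (t - strike_times[0] - t_step / 2) / t_cycle)

    normal_t = np.stack([-np.sin(heading_t), np.cos(heading_t)], axis=1)
    u_t = np.stack([np.cos(heading_t), np.sin(heading_t)], axis=1)
    pelvis_xy = center_t + sway_t[:, None] * normal_t
    vert_amp = 0.0 if standing else 0.010 * (speed / 1.3 + 0.3)
    pelvis_z = pelvis_h + vert_amp * np.cos(2 * phase)
    pelvis = np.column_stack([pelvis_xy, pelvis_z])

    # --- feet ---------------------------------------------------------------
    foot_len = 0.15 * H
    lift = 0.05 if task != "step_obstacle" else 0.05
    obstacle_step = n_steps // 2 if task == "step_obstacle" else -1
    heel = {s: np.zeros((n_frames, 3)) for s in ("left", "right")}
    foot_heading = {s: np.zeros(n_frames) for s in ("left", "right")}
    off_times: list[tuple[float, str]] = []
    for s in ("left", "right"):
        idx = np.flatnonzero(sides == s)
        # initial stance position: mirror of the first placement
        if len(idx) == 0:
            continue
        first_k = idx[0]
        sign0 = 1.0 if s == "left" else -1.0
        start_pos = (center[0] - step_length *
                     np.array([math.cos(heading[0]), math.sin(heading[0])])
                     + sign0 * (width / 2.0) * normal[0])
        pos_xy = np.tile(start_pos, (n_frames, 1))
        pos_z = np.zeros(n_frames)
        head_f = np.full(n_frames, heading[0])
        prev_pos = start_pos
        prev_heading = heading[0]
        prev_strike = 0.0
        for j, kk in enumerate(idx):
            t_land = strike_times[kk]
            # this foot leaves the ground after the preceding contralateral
            # strike plus the double-support interval
            t_off = (strike_times[kk - 1] + ds_half if kk > 0
                     else max(t_land - 0.45 * t_cycle, 0.05))
            t_off = min(t_off, t_land - 0.08)
            off_times.append((t_off, s))
            tau = np.clip((t - t_off) / max(t_land - t_off, 1e-3), 0.0, 1.0)
            sstep = _smoothstep(tau)
            swing_lift = lift * (1.6 if kk == obstacle_step else 1.0)
            if standing:
                continue
            pos_xy[t > t_off] = (prev_pos[None, :]
                                 + sstep[t > t_off, None]
                                 * (placements[kk] - prev_pos)[None, :])
            pos_z = np.where((t > t_off) & (t < t_land),
                             swing_lift * np.sin(math.pi * tau), pos_z)
            head_f = np.where(t > t_off,
                              prev_heading + sstep * (heading[kk] - prev_heading),
                              head_f)
            pos_xy[t >= t_land] = placements[kk]
            pos_z[t >= t_land] = 0.0
            head_f[t >= t_land] = heading[kk]
            prev_pos = placements[kk]
            prev_heading = heading[kk]
            prev_strike = t_land
        heel[s] = np.column_stack([pos_xy, pos_z + 0.025])
        foot_heading[s] = head_f

    # --- trunk and head orientation ----------------------------------------
    n_cycles = int(np.ceil(total_dur / t_cycle)) + 2
    jit = profile.kinematic_noise_sd if not standing else 0.0
    cyc_edges = np.arange(n_cycles + 1) * t_cycle

    def per_cycle_amp(base: float, scale: float) -> np.ndarray:
        amps = base + rng.normal(0.0, jit * scale, n_cycles + 1)
        return np.interp(t, cyc_edges, amps)

    if standing:
        yaw_t = pitch_t = roll_t = np.zeros(n_frames)
    else:
        yaw_t = np.radians(per_cycle_amp(4.0, 0.5)) * np.sin(phase + math.pi)
        roll_t = np.radians(per_cycle_amp(2.5, 0.4)) * np.sin(phase)
        pitch_t = np.radians(per_cycle_amp(1.5, 0.3)) * np.sin(2 * phase)

    # independent, space-stabilized head motion (small)
    head_indep_yaw = np.radians(0.8) * np.sin(2 * math.pi * 0.7 * t + 1.0)
    head_indep_pitch = np.radians(0.6) * np.sin(2 * math.pi * 0.9 * t + 2.0)
    head_indep_roll = np.radians(0.5) * np.sin(2 * math.pi * 0.8 * t + 0.5)
    if standing:
        head_indep_yaw = head_indep_pitch = head_indep_roll = np.zeros(n_frames)
    head_yaw = coupling * yaw_t + (1 - coupling) * head_indep_yaw
    head_pitch = coupling * pitch_t + (1 - coupling) * head_indep_pitch
    head_roll = coupling * roll_t + (1 - coupling) * head_indep_roll
    if task == "horizontal_head_turns":
        head_yaw = head_yaw + np.radians(30.0) * np.sin(2 * math.pi * 0.4 * t)
    elif task == "vertical_head_turns":
        head_pitch = head_pitch + np.radians(25.0) * np.sin(2 * math.pi * 0.4 * t)

    def frame_matrix(yaw, pitch, roll, base_heading):
        return (_rot_z(base_heading + yaw) @ _rot_y(pitch) @ _rot_x(roll))

    R_pelvis = frame_matrix(0.6 * yaw_t, 0.4 * pitch_t, 0.8 * roll_t, heading_t)
    R_trunk = frame_matrix(yaw_t, pitch_t, roll_t, heading_t)
    R_head = frame_matrix(head_yaw, head_pitch, head_roll, heading_t)

    def attach(origin: np.ndarray, R: np.ndarray, offset) -> np.ndarray:
        return origin + np.einsum("nij,j->ni", R, np.asarray(offset, float))

    m: dict[str, np.ndarray] = {}
    scale = H / 1.70
    # pelvis markers
    m["LASI"] = attach(pelvis, R_pelvis, [0.09 * scale, 0.12 * scale, 0.0])
    m["RASI"] = attach(pelvis, R_pelvis, [0.09 * scale, -0.12 * scale, 0.0])
    m["LPSI"] = attach(pelvis, R_pelvis, [-0.11 * scale, 0.05 * scale, 0.02])
    m["RPSI"] = attach(pelvis, R_pelvis, [-0.11 * scale, -0.05 * scale, 0.02])
    # trunk
    trunk_o = attach(pelvis, R_pelvis, [0.0, 0.0, 0.28 * scale])
    m["C7"] = attach(trunk_o, R_trunk, [-0.06, 0.0, 0.22 * scale])
    m["CLAV"] = attach(trunk_o, R_trunk, [0.05, 0.0, 0.20 * scale])
    m["T10"] = attach(trunk_o, R_trunk, [-0.08, 0.0, 0.02])
    m["STRN"] = attach(trunk_o, R_trunk, [0.08, 0.0, 0.0])
    # head
    head_o = attach(trunk_o, R_trunk, [0.0, 0.0, 0.30 * scale])
    m["LFHD"] = attach(head_o, R_head, [0.09, 0.06, 0.10])
    m["RFHD"] = attach(head_o, R_head, [0.09, -0.06, 0.10])
    m["LBHD"] = attach(head_o, R_head, [-0.08, 0.07, 0.11])
    m["RBHD"] = attach(head_o, R_head, [-0.08, -0.07, 0.11])
    # arms (sagittal pendulum, anti-phase with the ipsilateral leg)
    arm_swing = np.zeros(n_frames) if standing else np.radians(12.0) * np.sin(phase)
    for s, sgn, ph in (("L", 1.0, 0.0), ("R", -1.0, math.pi)):
        sho = attach(trunk_o, R_trunk, [0.0, sgn * 0.19 * scale, 0.18 * scale])
        m[f"{s}SHO"] = sho
        swing = arm_swing * math.cos(ph)
        Rarm = R_trunk @ _rot_y(swing)
        elb = sho + np.einsum("nij,j->ni", Rarm, [0.0, sgn * 0.01, -0.30 * scale])
        m[f"{s}ELB"] = elb
        Rfore = R_trunk @ _rot_y(swing * 1.3 - 0.15)
        m[f"{s}WRI"] = elb + np.einsum("nij,j->ni", Rfore,
                                       [0.0, sgn * 0.01, -0.27 * scale])

    # legs
    d_asis = np.linalg.norm(m["LASI"][0] - m["RASI"][0])
    for s, side_name, sgn in (("L", "left", 1.0), ("R", "right", -1.0)):
        hjc = (0.5 * (m["LASI"] + m["RASI"])
               + np.einsum("nij,j->ni", R_pelvis,
                           [-0.19 * d_asis, sgn * 0.36 * d_asis,
                            -0.30 * d_asis]))
        hl = heel[side_name]
        fh = foot_heading[side_name]
        fu = np.stack([np.cos(fh), np.sin(fh), np.zeros(n_frames)], axis=1)
        lat3 = sgn * np.stack([-np.sin(fh), np.cos(fh), np.zeros(n_frames)],
                              axis=1)
        ankle_c = hl + np.array([0.0, 0.0, ankle_h - 0.025]) + 0.03 * fu
        fwd3 = np.stack([u_t[:, 0], u_t[:, 1], 0.35 * np.ones(n_frames)],
                        axis=1)
        knee_c = _two_link_ik(hjc, ankle_c, fwd3, l_thigh, l_shank)
        m[f"{s}KNE"] = knee_c + 0.057 * lat3
        m[f"{s}ANK"] = ankle_c + 0.042 * lat3
        m[f"{s}THI"] = 0.5 * (hjc + knee_c) + 0.06 * lat3
        m[f"{s}TIB"] = 0.5 * (knee_c + ankle_c) + 0.05 * lat3
        m[f"{s}HEE"] = hl
        m[f"{s}TOE"] = hl + foot_len * fu + np.array([0.0, 0.0, -0.005])

    if marker_noise_sd > 0:
        for lb in m:
            m[lb] = m[lb] + rng.normal(0.0, marker_noise_sd, m[lb].shape)

    events = None
    if not standing:
        records = [(float(tt), str(ss), "foot_strike")
                   for tt, ss in zip(strike_times, sides)]
        records += [(float(tt), ss, "foot_off") for tt, ss in off_times
                    if 0 < tt <= total_dur]
        records = [r for r in records if 0 <= r[0] <= total_dur]
        records.sort()
        events = GaitEventTable.from_records(records)

    sidecar = {
        "seed": seed,
        "strikes": [(float(tt), str(ss)) for tt, ss in zip(strike_times, sides)],
        "offs": [(float(tt), ss) for tt, ss in off_times],
        "placements": [
            dict(k=int(kk), side=str(sides[kk]), x=float(placements[kk, 0]),
                 y=float(placements[kk, 1]), lateral=float(lateral[kk]),
                 catchup=bool(catchup_flags[kk]),
                 offline=bool(offline_flags[kk]))
            for kk in range(n_steps)
        ],
        "programmed": dict(
            speed=float(speed), cadence=float(cadence),
            step_width=float(width), ml_sway=float(sway),
            coupling=float(coupling), step_length=float(step_length),
            double_support=float(2 * ds_half),
        ),
        "tandem_online_steps": (
            int(np.argmax(offline_flags)) if offline_flags.any() else n_steps
        ) if tandem else None,
    }
    trial = TrialRecord(
        subject_id=draw.subject_id,
        task=task if task != "standing" else "standing",
        markers=m,
        rate=RATE,
        events=None,  # detection is the pipeline's job; truth in sidecar
        ground_truth=sidecar,
        meta={"height": H, "mass": draw.mass,
              "true_events": "sidecar" if events is not None else "none"},
    )
    if events is not None:
        trial.ground_truth["event_table"] = events
    return trial, sidecar


@dataclass
class Cohort:
    """Generated trials plus subject metadata."""

    subjects: list[SubjectMeta]
    draws: list[SubjectDraw]
    trials: list[TrialRecord] = field(default_factory=list)

    def trials_of(self, subject_id: str) -> list[TrialRecord]:
        return [tr for tr in self.trials if tr.subject_id == subject_id]


def draw_subject(
    profile: ImpairmentProfile, group: str, subject_id: str,
    rng: np.random.Generator,
) -> SubjectDraw:
    """Draw per-subject parameters from a group preset.

    A latent severity couples the gait deviations to the simulated DHI so
    that convergent-validity correlations are recoverable: more severe
    subjects walk slower, wider, sway more, and report a higher DHI.
    """
    z = float(np.clip(rng.standard_normal(), -2.0, 2.0))
    severity = 0.5 + z / 4.0
    eps = rng.standard_normal(4)
    sp_m, sp_s = profile.walking_speed
    ca_m, ca_s = profile.cadence
    wd_m, wd_s = profile.step_width
    sw_m, sw_s = profile.ml_sway
    speed = max(0.3, sp_m - 0.6 * sp_s * z + 0.8 * sp_s * eps[0])
    cad = max(60.0, ca_m - 0.4 * ca_s * z + 0.9 * ca_s * eps[1])
    width = max(0.02, wd_m + 0.6 * wd_s * z + 0.8 * wd_s * eps[2])
    sway = max(0.004, sw_m + 0.6 * sw_s * z + 0.8 * sw_s * eps[3])
    coupling = float(np.clip(profile.head_trunk_coupling + 0.15 * z
                             + 0.05 * rng.standard_normal(), 0.0, 1.0))
    height = float(np.clip(rng.normal(1.70, 0.08), 1.5, 1.95))
    mass = float(np.clip(rng.normal(73.0, 11.0), 48.0, 110.0))
    dhi = float(np.clip(profile.dhi_intercept + profile.dhi_slope * severity
                        + rng.normal(0.0, profile.dhi_noise_sd), 0.0, 100.0))
    affected = "none"
    if group == "UV":
        affected = "left" if rng.random() < 0.5 else "right"
    elif group == "BV":
        affected = "both"
    return SubjectDraw(subject_id, group, severity, speed, cad, width, sway,
                       coupling, height, mass, affected, dhi)


def generate_cohort(
    presets: dict[str, ImpairmentProfile] | None = None,
    n_per_group: int = 10,
    seed: int = 42,
    tasks: list[str] | None = None,
    n_steps: int = 12,
) -> Cohort:
    """Generate a full synthetic cohort: per-subject draws from the group
    presets and one trial per requested task (default: the full protocol
    task set).  Same seed, same cohort, bit for bit."""
    from .trial_io import TASKS

    presets = presets or PRESETS
    tasks = list(tasks) if tasks is not None else list(TASKS)
    root = np.random.default_rng(seed)
    subjects: list[SubjectMeta] = []
    draws: list[SubjectDraw] = []
    trials: list[TrialRecord] = []
    for group in ("BV", "UV", "HS"):
        profile = presets[group]
        for i in range(n_per_group):
            sid = f"{group}{i + 1:02d}"
            draw = draw_subject(profile, group, sid, root)
            draws.append(draw)
            subjects.append(SubjectMeta(
                subject_id=sid, group=group, affected_side=draw.affected_side,
                dhi=draw.dhi, height=draw.height, mass=draw.mass,
            ))
            for task in tasks:
                t_seed = int(root.integers(0, 2**31 - 1))
                trial, _ = generate_trial(profile, task, draw, t_seed,
                                          n_steps=n_steps)
                trials.append(trial)
    return Cohort(subjects=subjects, draws=draws, trials=trials)
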