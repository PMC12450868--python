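"""End-to-end orchestration: trials -> parameter table -> validity grids
-> relevance matrix -> short-form task report.

The parameter battery covers four families: dynamic stability (ML CoM
range of motion, ML/AP margins of stability, angular-momentum ranges),
spatial (zone scores, step width, ML step distance, tandem step count),
temporal (walking speed, double support, task time) and kinematic (head
anchoring indices, head/trunk angular-velocity RMS, GaitSD).  Three tasks
contribute a single parameter each (tandem walk: step count; backwards:
walking speed; stairs: task time); every other cell of those tasks is
emitted as NR (not relevant).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import body_model as bm
from . import kinematic_metrics as km
from . import preprocess as pp
from . import spatiotemporal_metrics as sm
from . import stability_metrics as st
from . import synthetic_gait as sg
from . import validity_stats as vs
from .trial_io import (SINGLE_PARAMETER_TASKS, TASKS, SubjectMeta,
                       TrialRecord)

__all__ = [
    "PARAMETERS",
    "PipelineConfig",
    "compute_trial_parameters",
    "build_parameter_table",
    "run_pipeline",
    "shortform_fga_report",
    "export_heatmap",
]

#: All parameter columns, grouped by family.
PARAMETERS: tuple[str, ...] = (
    # dynamic stability
    "ML_CoM_rom", "MoS_ML", "MoS_AP", "WBAM_sag", "WBAM_cor", "WBAM_tra",
    # spatial
    "CoM_score", "Foot_score", "Step_width", "ML_step", "Step_number",
    # temporal
    "Walking_speed", "Double_support", "Task_time",
    # kinematic
    "HeadAI_pitch", "HeadAI_roll", "HeadAI_yaw", "Head_AV", "Trunk_AV",
    "GaitSD",
)


@dataclass
class PipelineConfig:
    """One config drives everything; every under-specified methodological
    choice is surfaced here and echoed into the run metadata."""

    seed: int = 42
    n_per_group: int = 10
    tasks: list[str] = field(default_factory=lambda: list(TASKS))
    n_steps: int = 12
    filter_cutoff: float = 6.0
    filter_order: int = 4
    zero_phase: bool = True
    zone_boundaries: tuple[float, ...] = (0.1524, 0.254, 0.381)
    zone_weights: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    tandem_line_tolerance: float = 0.05
    alpha: float = 0.05
    strict_alpha: float = 0.01
    quantile_convention: str = "linear"
    wbam_normalization: str = "mass_height_speed"
    av_normalization: str = "per_percent_cycle"
    anchoring_variant: str = "sd"  # 'sd' (default) or 'variance'
    applicability: dict = field(
        default_factory=lambda: dict(vs.DEFAULT_APPLICABILITY))
    output_dir: str = "vestigait_output"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if not (0.0 < cfg.alpha < 1.0 and 0.0 < cfg.strict_alpha < 1.0):
            raise ValueError("alpha thresholds must lie in (0, 1)")
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["zone_boundaries"] = list(self.zone_boundaries)
        data["zone_weights"] = list(self.zone_weights)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @property
    def filter_spec(self) -> pp.FilterSpec:
        return pp.FilterSpec(self.filter_order, self.filter_cutoff,
                             self.zero_phase)

    @property
    def zone_spec(self) -> sm.ZoneSpec:
        return sm.ZoneSpec(tuple(self.zone_boundaries),
                           tuple(self.zone_weights))


def _preprocess(trial: TrialRecord, config: PipelineConfig) -> TrialRecord:
    has_nan = any(np.isnan(a).any() for a in trial.markers.values())
    if has_nan:
        trial, _ = pp.fill_gaps(trial)
        clean = {lb: a for lb, a in trial.markers.items()
                 if not np.isnan(a).any()}
        trial = trial.copy_with(markers=clean)
    trial = pp.lowpass(trial, config.filter_spec)
    return pp.add_virtual_markers(trial)


def compute_trial_parameters(
    trial: TrialRecord,
    meta: SubjectMeta,
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """All parameters computable for one trial; NaN marks a parameter the
    trial cannot provide (insufficient cycles), absent keys mark
    parameters not defined for the task."""
    config = config or PipelineConfig()
    trial = _preprocess(trial, config)
    events = trial.events
    if events is None or len(events) == 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            events = pp.detect_gait_events(trial)
    side = meta.analysis_side
    piecewise = trial.task == "turn_pivot"

    if trial.task in SINGLE_PARAMETER_TASKS:
        name = SINGLE_PARAMETER_TASKS[trial.task]
        if name == "Step_number":
            return {name: float(sm.tandem_step_count(
                trial, events, config.tandem_line_tolerance))}
        if name == "Task_time":
            return {name: sm.task_time(trial, events)}
        com = bm.compute_com(trial, bm.build_com_model(meta.mass, meta.height))
        return {name: sm.walking_speed(com, events)}

    out: dict[str, float] = {}
    com = bm.compute_com(trial, bm.build_com_model(meta.mass, meta.height))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        direction = pp.estimate_walking_direction(trial)
    speed = sm.walking_speed(com, events)
    out["Walking_speed"] = speed
    out["Task_time"] = sm.task_time(trial, events)
    ds, _ = sm.double_support_time(events, side)
    out["Double_support"] = ds

    # dynamic stability
    if piecewise:
        ml = sm.lateral_offsets(com.position[:, :2], piecewise=True)
        from scipy.signal import detrend as _detrend
        out["ML_CoM_rom"] = float(np.ptp(_detrend(ml)))
    else:
        out["ML_CoM_rom"] = st.ml_com_rom(com, direction)
    xp = st.XcomParams.from_com(com)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["MoS_ML"] = st.margin_of_stability(
            trial, events, com, xp, side, "ML", direction).median
        out["MoS_AP"] = st.margin_of_stability(
            trial, events, com, xp, side, "AP", direction).median
    wbam = bm.compute_wbam(
        trial, bm.build_momentum_model(meta.mass, meta.height), com,
        normalize=config.wbam_normalization,
        walking_speed=speed if np.isfinite(speed) else None)
    out["WBAM_sag"] = st.wbam_range(wbam, direction, "sagittal")
    out["WBAM_cor"] = st.wbam_range(wbam, direction, "coronal")
    out["WBAM_tra"] = st.wbam_range(wbam, direction, "transverse")

    # spatial
    zones = config.zone_spec
    out["CoM_score"] = sm.com_zone_score(com, zones, piecewise=piecewise)
    out["Foot_score"] = sm.foot_zone_score(trial, zones, piecewise=piecewise)
    steps = sm.build_step_series(trial, events, piecewise=piecewise)
    out["Step_width"] = sm.step_width(steps)
    out["ML_step"] = sm.ml_step_distance(steps, side)

    # kinematic
    angles = km.segment_orientations(trial, direction)
    variant = config.anchoring_variant
    for plane in ("pitch", "roll", "yaw"):
        ai = km.head_anchoring_index(angles, plane)
        if variant == "variance" and np.isfinite(ai):
            # variance-based variant of the same contrast
            k = {"yaw": 0, "pitch": 1, "roll": 2}[plane]
            va = float(np.var(angles.head_in_lab[:, k]))
            vr = float(np.var(angles.head_on_trunk[:, k]))
            ai = (vr - va) / (vr + va) if (vr + va) > 0 else float("nan")
        out[f"HeadAI_{plane}"] = ai
    strikes = events.strikes(side)
    cycle_dur = float(np.median(np.diff(strikes))) if len(strikes) >= 2 else float("nan")
    out["Head_AV"] = km.angular_velocity_rms(
        angles, "head", cycle_dur, config.av_normalization)
    out["Trunk_AV"] = km.angular_velocity_rms(
        angles, "trunk", cycle_dur, config.av_normalization)
    signals = km.joint_angle_signals(trial, side, direction)
    cycles = km.extract_cycles(signals, events, side, trial.rate)
    out["GaitSD"] = km.gait_sd(cycles)
    return out


def build_parameter_table(
    trials: list[TrialRecord],
    subjects: list[SubjectMeta],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Long-form parameter table (subject, group, task, parameter, value),
    one row per subject x task x parameter, repeated trials of a task
    averaged by median."""
    config = config or PipelineConfig()
    meta = {s.subject_id: s for s in subjects}
    rows = []
    for trial in trials:
        s = meta[trial.subject_id]
        values = compute_trial_parameters(trial, s, config)
        for param, value in values.items():
            rows.append((trial.subject_id, s.group, trial.task, param, value))
    df = pd.DataFrame(rows, columns=["subject", "group", "task", "parameter",
                                     "value"])
    return (df.groupby(["subject", "group", "task", "parameter"],
                       as_index=False)["value"].median())


@dataclass
class PipelineResult:
    table: pd.DataFrame
    grid: list[vs.ComparisonCell]
    grid_frame: pd.DataFrame
    correlations: list[vs.ConvergentCell]
    relevance: pd.DataFrame
    report: pd.DataFrame
    metadata: dict


def _grid_frame(grid: list[vs.ComparisonCell]) -> pd.DataFrame:
    rows = []
    for c in grid:
        row = dict(task=c.task, parameter=c.parameter, kw_h=c.kw_h,
                   kw_p=c.kw_p, strict=c.strict_flag,
                   not_relevant=c.not_relevant)
        for pair in vs.PAIRS:
            row[f"dunn_{pair}"] = (c.dunn_p or {}).get(pair, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    cohort: sg.Cohort | None = None,
    output_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full chain on a synthetic cohort (generated from the config
    seed unless one is passed in) and optionally write all outputs."""
    if cohort is None:
        cohort = sg.generate_cohort(n_per_group=config.n_per_group,
                                    seed=config.seed, tasks=config.tasks,
                                    n_steps=config.n_steps)
    table = build_parameter_table(cohort.trials, cohort.subjects, config)
    grid = vs.build_discriminant_grid(
        table, alpha=config.alpha, strict_alpha=config.strict_alpha,
        all_parameters=list(PARAMETERS),
        all_tasks=sorted(set(t for t in config.tasks)),
    )
    corr = vs.convergent_correlations(table, cohort.subjects)
    relevance = vs.synthesize_relevance(grid, corr, config.applicability)
    report = shortform_fga_report(relevance, table)
    metadata = {
        "seed": config.seed,
        "n_per_group": config.n_per_group,
        "tasks": config.tasks,
        "filter": asdict(config.filter_spec),
        "zones": {"boundaries": list(config.zone_boundaries),
                  "weights": list(config.zone_weights)},
        "alpha": config.alpha,
        "strict_alpha": config.strict_alpha,
        "wbam_normalization": config.wbam_normalization,
        "wbam_com_reference": "9-segment CoM",
        "av_normalization": config.av_normalization,
        "anchoring_variant": config.anchoring_variant,
        "quantile_convention": config.quantile_convention,
        "plane_naming": {"sagittal": "about ML axis",
                         "coronal (a.k.a. frontal)": "about AP axis",
                         "transverse": "about vertical axis"},
    }
    result = PipelineResult(table, grid, _grid_frame(grid), corr, relevance,
                            report, metadata)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "parameters.csv", index=False)
        result.grid_frame.to_csv(out / "discriminant_grid.csv", index=False)
        pd.DataFrame([asdict(c) for c in corr]).to_csv(
            out / "convergent_correlations.csv", index=False)
        relevance.to_csv(out / "relevance_matrix.csv", index=False)
        report.to_csv(out / "shortform_report.csv", index=False)
        (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2))
        export_heatmap(relevance, out / "relevance_heatmap.png")
    return result


def shortform_fga_report(
    relevance: pd.DataFrame, table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Short-form task report: per retained task, its relevant parameters
    with a direction-of-effect note derived from group medians (e.g.
    'lower for patients')."""
    rel = relevance[relevance["tier"] == "relevant"]
    rows = []
    for _, cell in rel.iterrows():
        note = ""
        if table is not None:
            sub = table[(table["task"] == cell["task"])
                        & (table["parameter"] == cell["parameter"])]
            med = sub.groupby("group")["value"].median()
            if {"BV", "HS"}.issubset(med.index):
                if med["BV"] > med["HS"]:
                    note = "higher for patients"
                elif med["BV"] < med["HS"]:
                    note = "lower for patients"
                else:
                    note = "no direction"
        rows.append((cell["task"], cell["parameter"], note))
    return pd.DataFrame(rows, columns=["task", "parameter", "interpretation"])


_TIER_COLOR = {"relevant": 2.0, "interesting": 1.0, "not-relevant": 0.0}


def export_heatmap(relevance: pd.DataFrame, path: str | Path) -> None:
    """Matrix/heatmap rendering of the relevance tiers (task rows,
    parameter columns)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = relevance.pivot_table(
        index="task", columns="parameter", values="tier",
        aggfunc=lambda s: _TIER_COLOR.get(s.iloc[0], 0.0))
    fig, ax = plt.subplots(
        figsize=(max(6, 0.5 * len(pivot.columns)), max(4, 0.45 * len(pivot))))
    im = ax.imshow(pivot.to_numpy(float), cmap="YlGn", vmin=0, vmax=2,
                   aspect="auto")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=90,
                  fontsize=7)
    ax.set_yticks(range(len(pivot.index)), pivot.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="0 not-relevant / 1 interesting / 2 relevant")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
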