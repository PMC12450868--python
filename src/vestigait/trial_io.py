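"""Canonical data model and I/O for motion-capture trials and cohort metadata.

A trial is a set of named 3-D marker trajectories sampled at a fixed rate
(meters, lab frame), optionally carrying a gait-event table and, for
synthetic trials, a ground-truth sidecar.  The lab frame convention is
right-handed with X the nominal progression (antero-posterior) axis, Y the
medio-lateral axis (positive to the participant's left), and Z vertical,
origin on the floor at the walkway midline.

Trials can be read from C3D files (requires the optional ``ezc3d``
dependency) or from a plain-text fixture format that round-trips losslessly
and diffs cleanly under version control.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MARKER_SET",
    "TASKS",
    "WALKING_TASKS",
    "SINGLE_PARAMETER_TASKS",
    "GaitEventTable",
    "TrialRecord",
    "SubjectMeta",
    "FormatError",
    "MissingMarkerError",
    "ConsistencyError",
    "read_c3d",
    "read_fixture",
    "write_fixture",
    "load_cohort",
    "load_reference_cohort",
]

#: Canonical marker labels: CGM-style lower body, pelvis, trunk, 4 head
#: markers and bilateral shoulder/elbow/wrist so the 13-segment angular
#: momentum model can be assembled.
MARKER_SET: tuple[str, ...] = (
    # head
    "LFHD", "RFHD", "LBHD", "RBHD",
    # trunk
    "C7", "T10", "CLAV", "STRN",
    # pelvis
    "LASI", "RASI", "LPSI", "RPSI",
    # left leg
    "LTHI", "LKNE", "LTIB", "LANK", "LHEE", "LTOE",
    # right leg
    "RTHI", "RKNE", "RTIB", "RANK", "RHEE", "RTOE",
    # arms
    "LSHO", "LELB", "LWRI", "RSHO", "RELB", "RWRI",
)

#: The 14 protocol tasks.
TASKS: tuple[str, ...] = (
    "comfortable_gait",
    "slow_gait",
    "fast_gait",
    "double_task_animal",
    "double_task_letter",
    "change_speed",
    "horizontal_head_turns",
    "vertical_head_turns",
    "turn_pivot",
    "step_obstacle",
    "tandem_walk",
    "eyes_closed",
    "backwards",
    "steps",
)

#: Tasks analysed with the full parameter battery (everything except the
#: three single-parameter tasks below).
SINGLE_PARAMETER_TASKS: Mapping[str, str] = {
    "tandem_walk": "Step_number",
    "backwards": "Walking_speed",
    "steps": "Task_time",
}

WALKING_TASKS: tuple[str, ...] = tuple(
    t for t in TASKS if t not in SINGLE_PARAMETER_TASKS
)

GROUPS = ("BV", "UV", "HS")


class FormatError(ValueError):
    """Raised when a trial or cohort file cannot be parsed."""


class MissingMarkerError(KeyError):
    """Raised when required marker labels are absent from a trial."""

    def __init__(self, labels: Iterable[str]):
        self.labels = tuple(labels)
        super().__init__(f"missing required markers: {', '.join(self.labels)}")


class ConsistencyError(ValueError):
    """Raised when cohort metadata is internally inconsistent."""


@dataclass(frozen=True)
class GaitEventTable:
    """Ordered foot-strike / foot-off events.

    ``events`` is a DataFrame with columns ``time`` (s), ``side``
    (``left``/``right``) and ``kind`` (``foot_strike``/``foot_off``),
    sorted by time.
    """

    events: pd.DataFrame

    def __post_init__(self):
        df = self.events
        required = {"time", "side", "kind"}
        if not required.issubset(df.columns):
            raise FormatError(f"event table needs columns {sorted(required)}")
        if not df["side"].isin(["left", "right"]).all():
            raise FormatError("event side must be left or right")
        if not df["kind"].isin(["foot_strike", "foot_off"]).all():
            raise FormatError("event kind must be foot_strike or foot_off")
        df = df.sort_values("time", kind="stable").reset_index(drop=True)
        object.__setattr__(self, "events", df)

    def __len__(self) -> int:
        return len(self.events)

    def side(self, side: str) -> pd.DataFrame:
        return self.events[self.events["side"] == side].reset_index(drop=True)

    def strikes(self, side: str | None = None) -> np.ndarray:
        df = self.events[self.events["kind"] == "foot_strike"]
        if side is not None:
            df = df[df["side"] == side]
        return df["time"].to_numpy()

    def offs(self, side: str | None = None) -> np.ndarray:
        df = self.events[self.events["kind"] == "foot_off"]
        if side is not None:
            df = df[df["side"] == side]
        return df["time"].to_numpy()

    def validate(self, duration: float | None = None) -> None:
        """Check per-side alternation and bounds; raise FormatError on failure."""
        for side in ("left", "right"):
            sub = self.side(side)
            t = sub["time"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise FormatError(f"{side} event times not strictly increasing")
            kinds = sub["kind"].to_list()
            for a, b in zip(kinds, kinds[1:]):
                if a == b:
                    raise FormatError(f"{side} events do not alternate strike/off")
        if duration is not None and len(self.events):
            t = self.events["time"].to_numpy()
            if t.min() < -1e-9 or t.max() > duration + 1e-9:
                raise FormatError("event times outside trial duration")

    @classmethod
    def from_records(cls, records: Iterable[tuple[float, str, str]]) -> "GaitEventTable":
        df = pd.DataFrame(records, columns=["time", "side", "kind"])
        return cls(df)

    @classmethod
    def empty(cls) -> "GaitEventTable":
        return cls(pd.DataFrame(columns=["time", "side", "kind"]))


@dataclass
class TrialRecord:
    """One recorded or generated trial."""

    subject_id: str
    task: str
    markers: dict[str, np.ndarray]  # label -> (n_frames, 3) in meters
    rate: float  # Hz
    events: GaitEventTable | None = None
    ground_truth: dict | None = None
    meta: dict = field(default_factory=dict)  # e.g. height, mass

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.task not in TASKS and self.task != "standing":
            raise ValueError(f"unknown task {self.task!r}")
        lengths = {v.shape[0] for v in self.markers.values()}
        if len(lengths) > 1:
            raise ValueError("all marker series must have equal length")
        for label, arr in self.markers.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {label} must be an (n, 3) array")

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def require(self, *labels: str) -> None:
        missing = [lb for lb in labels if lb not in self.markers]
        if missing:
            raise MissingMarkerError(missing)

    def copy_with(self, **changes) -> "TrialRecord":
        return replace(self, **changes)

    def stack(self, labels: Iterable[str] | None = None) -> np.ndarray:
        """Markers stacked as an (n_frames, n_markers*3) matrix."""
        labels = list(labels) if labels is not None else sorted(self.markers)
        return np.hstack([self.markers[lb] for lb in labels])


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject clinical metadata."""

    subject_id: str
    group: str  # BV | UV | HS
    affected_side: str = "none"  # left | right | both | none
    dhi: float | None = None  # 0-100, None when not collected
    fga_items: tuple[int, ...] = ()
    fga_total: int | None = None
    height: float = 1.70  # m
    mass: float = 72.0  # kg

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ConsistencyError(f"{self.subject_id}: unknown group {self.group!r}")
        if self.group == "UV" and self.affected_side not in ("left", "right"):
            raise ConsistencyError(
                f"{self.subject_id}: UV requires affected_side left or right"
            )
        if self.fga_items:
            if len(self.fga_items) != 10 or not all(0 <= s <= 3 for s in self.fga_items):
                raise ConsistencyError(
                    f"{self.subject_id}: FGA needs 10 items scored 0-3"
                )
            total = sum(self.fga_items)
            if self.fga_total is not None and total != self.fga_total:
                raise ConsistencyError(
                    f"{self.subject_id}: fga_total {self.fga_total} != item sum {total}"
                )
        if self.dhi is not None and not (0 <= self.dhi <= 100):
            raise ConsistencyError(f"{self.subject_id}: DHI out of range")

    @property
    def analysis_side(self) -> str:
        """Side used for side-dependent parameters: left for BV and HS,
        pathological side for UV."""
        if self.group == "UV":
            return self.affected_side
        return "left"


# ---------------------------------------------------------------------------
# fixture format
# ---------------------------------------------------------------------------

_FIXTURE_MAGIC = "# vestigait trial v1"


def write_fixture(trial: TrialRecord, path: str | Path) -> None:
    """Write a trial to the plain-text fixture format (lossless round trip)."""
    labels = sorted(trial.markers)
    lines = [_FIXTURE_MAGIC]
    lines.append(f"subject_id: {trial.subject_id}")
    lines.append(f"task: {trial.task}")
    lines.append(f"rate: {trial.rate!r}")
    lines.append(f"n_frames: {trial.n_frames}")
    lines.append("markers: " + ",".join(labels))
    for key, val in sorted(trial.meta.items()):
        lines.append(f"meta.{key}: {val!r}")
    if trial.events is not None:
        lines.append("[events]")
        for _, row in trial.events.events.iterrows():
            lines.append(f"{row['time']!r},{row['side']},{row['kind']}")
    lines.append("[frames]")
    text = "\n".join(lines) + "\n"
    buf = io.StringIO()
    data = trial.stack(labels)
    np.savetxt(buf, data, fmt="%.10g", delimiter=",")
    Path(path).write_text(text + buf.getvalue())


def read_fixture(path: str | Path) -> TrialRecord:
    """Read a trial written by :func:`write_fixture`."""
    raw = Path(path).read_text().splitlines()
    if not raw or raw[0].strip() != _FIXTURE_MAGIC:
        raise FormatError(f"{path}: not a vestigait fixture file")
    header: dict[str, str] = {}
    meta: dict = {}
    events_rows: list[tuple[float, str, str]] = []
    i = 1
    section = "header"
    while i < len(raw):
        line = raw[i].strip()
        i += 1
        if line == "[events]":
            section = "events"
            continue
        if line == "[frames]":
            break
        if not line:
            continue
        if section == "header":
            key, _, val = line.partition(":")
            key, val = key.strip(), val.strip()
            if key.startswith("meta."):
                try:
                    meta[key[5:]] = eval(val, {"__builtins__": {}}, {"nan": math.nan})
                except Exception as exc:  # noqa: BLE001
                    raise FormatError(f"{path}: bad meta line {line!r}") from exc
            else:
                header[key] = val
        else:
            t, side, kind = line.split(",")
            events_rows.append((float(t), side, kind))
    try:
        labels = header["markers"].split(",") if header["markers"] else []
        rate = float(header["rate"])
        n_frames = int(header["n_frames"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing header field {exc}") from exc
    body = "\n".join(raw[i:])
    data = np.loadtxt(io.StringIO(body), delimiter=",", ndmin=2)
    if data.shape != (n_frames, 3 * len(labels)):
        raise FormatError(
            f"{path}: frame block shape {data.shape} does not match header"
        )
    markers = {
        lb: np.ascontiguousarray(data[:, 3 * k : 3 * k + 3])
        for k, lb in enumerate(labels)
    }
    events = GaitEventTable.from_records(events_rows) if events_rows else None
    return TrialRecord(
        subject_id=header.get("subject_id", ""),
        task=header.get("task", "comfortable_gait"),
        markers=markers,
        rate=rate,
        events=events,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# C3D
# ---------------------------------------------------------------------------

def read_c3d(path: str | Path, required: Iterable[str] | None = None) -> TrialRecord:
    """Read a C3D motion-capture file into a :class:`TrialRecord`.

    Requires the optional ``ezc3d`` dependency.  Millimeter data are
    converted to meters; the sampling rate is taken from the file header.
    ``required`` defaults to the canonical marker set; markers outside the
    canonical set are kept under their file labels.
    """
    try:
        import ezc3d  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "read_c3d requires the optional dependency ezc3d "
            "(pip install vestigait[c3d])"
        ) from exc
    try:
        c3d = ezc3d.c3d(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: unreadable C3D file: {exc}") from exc
    labels = [lb.strip().split(":")[-1] for lb in
              c3d["parameters"]["POINT"]["LABELS"]["value"]]
    points = c3d["data"]["points"]  # (4, n_markers, n_frames)
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    units = c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["mm"])
    scale = 0.001 if units and str(units[0]).lower().startswith("mm") else 1.0
    markers = {
        lb: np.ascontiguousarray(points[:3, k, :].T * scale)
        for k, lb in enumerate(labels)
    }
    trial = TrialRecord(
        subject_id="", task="comfortable_gait", markers=markers, rate=rate
    )
    req = tuple(required) if required is not None else MARKER_SET
    trial.require(*req)
    return trial


# ---------------------------------------------------------------------------
# cohort metadata
# ---------------------------------------------------------------------------

_FGA_COLUMNS = [
    "fga_gait_level_surface",
    "fga_change_speed",
    "fga_horizontal_head_turns",
    "fga_vertical_head_turns",
    "fga_turn_pivot",
    "fga_step_obstacle",
    "fga_tandem_walk",
    "fga_eyes_closed",
    "fga_backwards",
    "fga_steps",
]


def load_cohort(path: str | Path | io.IOBase) -> list[SubjectMeta]:
    """Load per-subject cohort metadata from a CSV table.

    Missing DHI (coded ``UN`` or ``NA`` or empty) becomes ``None``, never 0.
    A stated ``fga_total`` that contradicts the item sum raises
    :class:`ConsistencyError` naming the subject.
    """
    df = pd.read_csv(path, dtype=str)
    subjects = []
    for _, row in df.iterrows():
        dhi_raw = str(row.get("dhi", "")).strip()
        dhi = None if dhi_raw in ("", "UN", "NA", "nan", "None") else float(dhi_raw)
        items: tuple[int, ...] = ()
        if all(c in df.columns for c in _FGA_COLUMNS):
            items = tuple(int(row[c]) for c in _FGA_COLUMNS)
        total = None
        if "fga_total" in df.columns and str(row["fga_total"]).strip() not in ("", "nan"):
            total = int(row["fga_total"])
        side = str(row.get("affected_side", "none")).strip().lower()
        kwargs = {}
        for anthro in ("height", "mass"):
            if anthro in df.columns and str(row[anthro]).strip() not in ("", "nan"):
                kwargs[anthro] = float(row[anthro])
        subjects.append(
            SubjectMeta(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]).strip(),
                affected_side=side,
                dhi=dhi,
                fga_items=items,
                fga_total=total,
                **kwargs,
            )
        )
    return subjects


def load_reference_cohort() -> list[SubjectMeta]:
    """Load the bundled clinical reference cohort (10 BV, 10 UV, 10 HS
    participants with DHI and FGA item scores)."""
    with resources.files("vestigait.data").joinpath("clinical_scores.csv").open() as fh:
        return load_cohort(fh)
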