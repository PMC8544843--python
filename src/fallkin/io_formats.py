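"""Reading and writing marker-trajectory workbooks, canonical CSVs, and
run configuration.

Two on-disk layouts are supported:

* **Workbooks** (xlsx, one sheet per fall) in the style of motion-capture
  supplementary data: a key/value metadata block at the top of each sheet
  (direction, initiation, participant height, sample rate, and the
  annotated fall-initiation and fall-end frames), a blank row, then a
  header row of ``marker_AXIS`` columns (``head_X``, ``head_Y``,
  ``head_Z`` for the 3D side; ``head_X``, ``head_Z`` for the planar side)
  above the numeric frames.  The exact layout is configurable through
  :class:`WorkbookLayout`.
* **Canonical long CSV** — a ``# key: value`` metadata header block
  followed by ``frame,time_s,marker,axis,value`` rows in deterministic
  order.  NaN gaps serialize as empty fields and restore as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as _dc_fields
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import openpyxl
import yaml

from .trials import Trial2D, Trial3D, TrialMeta, normalize_marker

_AXES_3D = ("X", "Y", "Z")
_AXES_2D = ("X", "Z")  # planar horizontal / vertical column suffixes


class FormatError(ValueError):
    """Structural problem in a trajectory file."""


@dataclass(frozen=True)
class WorkbookLayout:
    """Declarative description of a workbook sheet's cell layout."""

    axis_separator: str = "_"
    metadata_keys: tuple = (
        "trial_id",
        "direction",
        "initiation",
        "participant_height",
        "fall_start_frame",
        "fall_end_frame",
        "sample_rate",
        "camera_angle",
        "unit",
    )


def _meta_from_dict(d: Dict[str, object], sheet: str) -> TrialMeta:
    required = (
        "direction",
        "initiation",
        "participant_height",
        "sample_rate",
    )
    for k in required:
        if k not in d:
            raise FormatError(f"sheet {sheet!r}: missing metadata key {k!r}")
    if "fall_start_frame" not in d or "fall_end_frame" not in d:
        raise FormatError(
            f"sheet {sheet!r}: events absent — fall_start_frame/fall_end_frame "
            "annotations are required (no silent defaults)"
        )
    return TrialMeta(
        trial_id=str(d.get("trial_id", sheet)),
        direction=str(d["direction"]),
        initiation=str(d["initiation"]),
        participant_height=float(d["participant_height"]),
        fall_start_frame=int(d["fall_start_frame"]),
        fall_end_frame=int(d["fall_end_frame"]),
        sample_rate=float(d["sample_rate"]),
    )


def read_trial_workbook(
    path: Union[str, Path],
    side: str,
    layout: WorkbookLayout | None = None,
) -> List[Union[Trial3D, Trial2D]]:
    """Read a one-sheet-per-fall workbook into trial objects.

    ``side`` is ``"3d"`` (X/Y/Z columns per marker) or ``"2d"``
    (X/Z columns).  Marker labels are normalized to the canonical
    vocabulary; unknown labels raise.
    """
    if side not in ("3d", "2d"):
        raise ValueError("side must be '3d' or '2d'")
    layout = layout or WorkbookLayout()
    axes = _AXES_3D if side == "3d" else _AXES_2D
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    trials: List[Union[Trial3D, Trial2D]] = []
    for ws in wb.worksheets:
        rows = list(ws.iter_rows(values_only=True))
        meta_d: Dict[str, object] = {}
        header_i = None
        for i, row in enumerate(rows):
            if row and row[0] == "frame":
                header_i = i
                break
            if row and row[0] is not None and len(row) > 1:
                meta_d[str(row[0])] = row[1]
        if header_i is None:
            raise FormatError(f"sheet {ws.title!r}: no header row starting with 'frame'")
        header = [c for c in rows[header_i] if c is not None]
        columns: Dict[str, tuple] = {}
        for j, name in enumerate(header[1:], start=1):
            parts = str(name).rsplit(layout.axis_separator, 1)
            if len(parts) != 2:
                raise FormatError(
                    f"sheet {ws.title!r}: column {name!r} does not match "
                    "'marker_AXIS' pattern"
                )
            marker, axis = normalize_marker(parts[0]), parts[1].upper()
            columns[f"{marker}|{axis}"] = (j, marker, axis)
        markers_present = sorted({m for _, m, _ in columns.values()})
        for m in markers_present:
            for ax in axes:
                if f"{m}|{ax}" not in columns:
                    raise FormatError(
                        f"sheet {ws.title!r}: marker {m!r} missing axis column {ax!r}"
                    )
        data_rows = [r for r in rows[header_i + 1 :] if r and r[0] is not None]
        n = len(data_rows)
        arrays = {m: np.full((n, len(axes)), np.nan) for m in markers_present}
        for i, row in enumerate(data_rows):
            for key, (j, marker, axis) in columns.items():
                if axis not in axes:
                    continue
                val = row[j] if j < len(row) else None
                if val is None or val == "":
                    continue
                try:
                    arrays[marker][i, axes.index(axis)] = float(val)
                except (TypeError, ValueError):
                    cell = f"{openpyxl.utils.get_column_letter(j + 1)}{header_i + 2 + i}"
                    raise FormatError(
                        f"sheet {ws.title!r}: non-numeric cell {cell} ({val!r})"
                    ) from None
        meta = _meta_from_dict(meta_d, ws.title)
        if side == "3d":
            trials.append(Trial3D(meta=meta, markers=arrays))
        else:
            trials.append(
                Trial2D(
                    meta=meta,
                    camera_angle=float(meta_d.get("camera_angle", 90.0)),
                    unit=str(meta_d.get("unit", "metre")),
                    markers=arrays,
                )
            )
    wb.close()
    return trials


def write_trial_workbook(
    trials: List[Union[Trial3D, Trial2D]], path: Union[str, Path]
) -> Path:
    """Write trials to a one-sheet-per-fall workbook (inverse of
    :func:`read_trial_workbook`)."""
    path = Path(path)
    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    for trial in trials:
        meta = trial.meta
        ws = wb.create_sheet(title=meta.trial_id[:31])
        items = [
            ("trial_id", meta.trial_id),
            ("direction", meta.direction),
            ("initiation", meta.initiation),
            ("participant_height", meta.participant_height),
            ("fall_start_frame", meta.fall_start_frame),
            ("fall_end_frame", meta.fall_end_frame),
            ("sample_rate", meta.sample_rate),
        ]
        if isinstance(trial, Trial2D):
            items += [("camera_angle", trial.camera_angle), ("unit", trial.unit)]
        for k, v in items:
            ws.append([k, v])
        ws.append([])
        axes = _AXES_3D if isinstance(trial, Trial3D) else _AXES_2D
        names = sorted(trial.markers)
        ws.append(["frame"] + [f"{m}_{ax}" for m in names for ax in axes])
        n = trial.n_frames
        # values stored as full-precision decimal strings: xlsx numeric
        # cells hold only 16 significant digits, which would break exact
        # round-tripping of doubles
        for i in range(n):
            row: List[object] = [i]
            for m in names:
                for k in range(len(axes)):
                    v = trial.markers[m][i, k]
                    row.append(None if np.isnan(v) else repr(float(v)))
            ws.append(row)
    wb.save(path)
    return path


def write_trial_csv(trial: Union[Trial3D, Trial2D], path: Union[str, Path]) -> Path:
    """Write one trial as canonical long CSV (deterministic row order)."""
    path = Path(path)
    meta = trial.meta
    axes = _AXES_3D if isinstance(trial, Trial3D) else _AXES_2D
    lines = [
        f"# trial_id: {meta.trial_id}",
        f"# side: {'3d' if isinstance(trial, Trial3D) else '2d'}",
        f"# direction: {meta.direction}",
        f"# initiation: {meta.initiation}",
        f"# participant_height: {meta.participant_height!r}",
        f"# fall_start_frame: {meta.fall_start_frame}",
        f"# fall_end_frame: {meta.fall_end_frame}",
        f"# sample_rate: {meta.sample_rate!r}",
    ]
    if isinstance(trial, Trial2D):
        lines.append(f"# camera_angle: {trial.camera_angle!r}")
        lines.append(f"# unit: {trial.unit}")
    lines.append("frame,time_s,marker,axis,value")
    dt = 1.0 / meta.sample_rate
    for m in sorted(trial.markers):
        arr = trial.markers[m]
        for i in range(arr.shape[0]):
            for k, ax in enumerate(axes):
                v = arr[i, k]
                sval = "" if np.isnan(v) else repr(float(v))
                lines.append(f"{i},{i * dt!r},{m},{ax},{sval}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trial_csv(path: Union[str, Path]) -> Union[Trial3D, Trial2D]:
    """Read one canonical long CSV back into a trial (inverse of
    :func:`write_trial_csv`, bit-identical for finite values)."""
    path = Path(path)
    meta_d: Dict[str, str] = {}
    data: Dict[str, Dict[str, Dict[int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta_d[k.strip()] = v.strip()
            elif line.startswith("frame,") or not line:
                continue
            else:
                frame, _, marker, axis, value = line.split(",")
                d = data.setdefault(marker, {}).setdefault(axis, {})
                d[int(frame)] = float(value) if value else np.nan
    side = meta_d.pop("side", "3d")
    axes = _AXES_3D if side == "3d" else _AXES_2D
    meta = _meta_from_dict(dict(meta_d), path.stem)
    markers = {}
    for m, per_axis in data.items():
        n = max(max(d) for d in per_axis.values()) + 1
        arr = np.full((n, len(axes)), np.nan)
        for ax, d in per_axis.items():
            for i, v in d.items():
                arr[i, axes.index(ax)] = v
        markers[normalize_marker(m)] = arr
    if side == "3d":
        return Trial3D(meta=meta, markers=markers)
    return Trial2D(
        meta=meta,
        camera_angle=float(meta_d.get("camera_angle", 90.0)),
        unit=meta_d.get("unit", "metre"),
        markers=markers,
    )


#: Video-side cutoffs examined by the pipeline; 14 Hz is the Nyquist-safe
#: ceiling for 30 Hz video.
DEFAULT_CUTOFFS = (3.0, 5.0, 7.0, 10.0, 12.0, 14.0)
MAX_VIDEO_CUTOFF = 14.0


@dataclass
class RunConfig:
    """Validated run configuration with study-condition defaults."""

    cutoffs: List[float] = field(default_factory=lambda: list(DEFAULT_CUTOFFS))
    ground_truth_cutoff: float = 20.0
    camera_angles: List[float] = field(default_factory=lambda: [30.0, 60.0, 90.0])
    calibration: str = "grid2d"
    grid_translation: float = 0.0
    grid_rotation: float = 0.0
    height_error: float = 0.0
    noise_px: float = 1.0
    n_per_cell: int = 6
    seed: int = 0
    output_dir: str = "out"

    def __post_init__(self) -> None:
        for c in self.cutoffs:
            if c > MAX_VIDEO_CUTOFF:
                raise ValueError(
                    f"cutoff {c} Hz exceeds Nyquist-safe {MAX_VIDEO_CUTOFF} Hz "
                    "for 30 Hz video"
                )
            if c <= 0:
                raise ValueError("cutoffs must be positive")
        if self.calibration not in ("grid2d", "line1d"):
            raise ValueError(f"unknown calibration {self.calibration!r}")


def load_config(path: Union[str, Path, None] = None) -> RunConfig:
    """Load a YAML/JSON config file; missing file or empty file gives all
    defaults, unknown keys are rejected by name."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in _dc_fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
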