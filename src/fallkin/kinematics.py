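"""Derived kinematic quantities: zeroed positions, segment angles, peaks,
and out-of-plane summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .signal_ops import Series, central_difference
from .trials import Trial3D


@dataclass(frozen=True)
class AngleSeries:
    """Absolute angle of a segment's distal-minus-proximal vector with
    respect to the horizontal, in degrees, unwrapped for continuity."""

    segment_name: str
    values: np.ndarray  # degrees
    sample_rate: float

    def as_series(self, start_time: float = 0.0) -> Series:
        return Series(self.values, self.sample_rate, start_time)


@dataclass(frozen=True)
class PeakRecord:
    """Signed peak (maximum-magnitude) velocity within the fall interval."""

    marker_or_segment: str
    quantity: str  # v_vertical | v_horizontal | v_angular
    peak_value: float
    peak_time: float  # s


class UndefinedAngleError(ValueError):
    """Proximal and distal markers coincide at some frame."""


def zero_initial(traj: Dict[str, np.ndarray], start_frame: int = 0) -> Dict[str, np.ndarray]:
    """Subtract each series' value at ``start_frame`` so positions start at 0.

    Applied to horizontal and vertical position data to remove the
    difference in coordinate-system origins between measurement systems.
    Works on (n,) or (n, k) arrays; every column is zeroed independently.
    """
    out = {}
    for m, v in traj.items():
        v = np.asarray(v, dtype=float)
        out[m] = v - v[start_frame]
    return out


def segment_angle_series(
    prox: np.ndarray,
    dist: np.ndarray,
    segment_name: str = "segment",
    sample_rate: float = 600.0,
) -> AngleSeries:
    """Absolute segment angle via the two-argument inverse tangent.

    ``prox`` and ``dist`` are (n, 2) arrays of (horizontal, vertical)
    positions.  The angle of the distal-minus-proximal vector is computed
    with atan2(dvertical, dhorizontal) in degrees and unwrapped so no
    inter-sample jump exceeds 180 deg.
    """
    prox = np.asarray(prox, dtype=float)
    dist = np.asarray(dist, dtype=float)
    if prox.shape != dist.shape:
        raise ValueError("proximal and distal series must have equal shapes")
    d = dist - prox
    norms = np.hypot(d[:, 0], d[:, 1])
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise UndefinedAngleError(
            f"segment {segment_name!r}: coincident markers at frame {bad[0]}"
        )
    ang = np.degrees(np.unwrap(np.arctan2(d[:, 1], d[:, 0])))
    return AngleSeries(segment_name, ang, sample_rate)


def peak_velocity(
    v: Series,
    interval: Tuple[int, int],
    name: str = "",
    quantity: str = "v_vertical",
    mode: str = "magnitude",
) -> PeakRecord:
    """Peak velocity within a half-open frame interval.

    Default ``mode="magnitude"``: the sample of maximal absolute value,
    sign preserved (a purely downward velocity yields a negative peak).
    ``mode="signed"`` returns the signed maximum instead.
    """
    i0, i1 = interval
    if not (0 <= i0 < i1 <= len(v)):
        raise ValueError(f"interval {interval} invalid for series of length {len(v)}")
    seg = v.values[i0:i1]
    if mode == "magnitude":
        k = int(np.argmax(np.abs(seg)))
    elif mode == "signed":
        k = int(np.argmax(seg))
    else:
        raise ValueError(f"unknown peak mode {mode!r}")
    return PeakRecord(
        marker_or_segment=name,
        quantity=quantity,
        peak_value=float(seg[k]),
        peak_time=float(v.start_time + (i0 + k) * v.dt),
    )


def out_of_plane_summary(
    trial: Trial3D, interval: Tuple[int, int] | None = None
) -> Dict[str, Tuple[float, float]]:
    """Per-marker peak |Y - Y0| displacement (m) and peak |dY/dt| (m/s).

    Y is the horizontal axis perpendicular to the fall plane — motion a
    single fall-plane camera cannot observe.  Y is zeroed at the start of
    the interval (default: the annotated fall interval).
    """
    if interval is None:
        interval = (trial.meta.fall_start_frame, trial.meta.fall_end_frame)
    i0, i1 = interval
    rate = trial.meta.sample_rate
    out = {}
    for m, xyz in trial.markers.items():
        y = xyz[:, 1]
        vy = central_difference(Series(y, rate)).values
        seg = y[i0:i1] - y[i0]
        out[m] = (float(np.max(np.abs(seg))), float(np.max(np.abs(vy[i0:i1]))))
    return out


def resultant_xy(
    trial: Trial3D, interval: Tuple[int, int] | None = None
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """In-plane-only vs resultant horizontal displacement per marker.

    Returns, per marker, the in-plane displacement magnitude |X - X0| and
    the resultant horizontal displacement sqrt((X-X0)^2 + (Y-Y0)^2), both
    zeroed at the start of the fall interval.  Magnitudes are compared so
    that the difference between the two series reflects only out-of-plane
    motion; the resultant dominates pointwise by construction.
    """
    if interval is None:
        interval = (trial.meta.fall_start_frame, trial.meta.fall_end_frame)
    i0 = interval[0]
    out = {}
    for m, xyz in trial.markers.items():
        dx = xyz[:, 0] - xyz[i0, 0]
        dy = xyz[:, 1] - xyz[i0, 1]
        out[m] = (np.abs(dx), np.hypot(dx, dy))
    return out
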