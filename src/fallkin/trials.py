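"""Core trial containers and the marker/segment vocabulary.

Coordinate conventions used throughout the package:

* 3D (motion-capture side): X = horizontal position in the plane of the
  fall, Y = horizontal position perpendicular to that plane (out-of-plane),
  Z = vertical, up positive.  Units are metres, nominal rate 600 Hz.
* 2D (video side): (horizontal, vertical) with vertical up positive once
  calibrated to metres.  Pixel-unit trials use image coordinates
  (column, row) on a 640 x 480 sensor.
* Frame indices are 0-based; the fall interval is half-open
  ``[fall_start_frame, fall_end_frame)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Tuple

import numpy as np

Direction = Literal["forward", "backward", "sideways"]
Initiation = Literal["perturbation", "self_initiated"]

#: Canonical marker vocabulary.  ``GT`` (greater trochanter) is the pelvis
#: marker for forward/backward falls, ``ASIS`` (anterior superior iliac
#: spine) for sideways falls.
CANONICAL_MARKERS = (
    "head",
    "shoulder",
    "sternum",
    "elbow",
    "wrist",
    "GT",
    "ASIS",
    "knee",
    "ankle",
)

_MARKER_SYNONYMS = {
    "head": "head",
    "shoulder": "shoulder",
    "acromion": "shoulder",
    "sternum": "sternum",
    "manubrium": "sternum",
    "elbow": "elbow",
    "humeral_epicondyle": "elbow",
    "wrist": "wrist",
    "radial_styloid": "wrist",
    "gt": "GT",
    "greater_trochanter": "GT",
    "trochanter": "GT",
    "hip": "GT",
    "asis": "ASIS",
    "iliac_spine": "ASIS",
    "knee": "knee",
    "femoral_condyle": "knee",
    "ankle": "ankle",
    "malleolus": "ankle",
}


class UnknownMarkerError(KeyError):
    """A marker label outside the canonical vocabulary."""


def normalize_marker(label: str) -> str:
    """Map a raw marker label onto the canonical vocabulary.

    Idempotent over canonical names; unknown labels raise
    :class:`UnknownMarkerError` rather than being dropped.
    """
    key = label.strip().lower().replace(" ", "_").replace("-", "_")
    try:
        return _MARKER_SYNONYMS[key]
    except KeyError:
        raise UnknownMarkerError(f"unknown marker label: {label!r}") from None


@dataclass(frozen=True)
class TrialMeta:
    """Per-fall metadata shared by the 2D and 3D sides."""

    trial_id: str
    direction: Direction
    initiation: Initiation
    participant_height: float  # m
    fall_start_frame: int
    fall_end_frame: int
    sample_rate: float  # Hz

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward", "sideways"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.initiation not in ("perturbation", "self_initiated"):
            raise ValueError(f"invalid initiation {self.initiation!r}")
        if not (1.0 < self.participant_height < 2.5):
            raise ValueError(
                f"participant_height {self.participant_height} m outside (1.0, 2.5)"
            )
        if self.fall_start_frame >= self.fall_end_frame:
            raise ValueError("fall_start_frame must precede fall_end_frame")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def with_rate(self, rate: float, rescale_events: bool = True) -> "TrialMeta":
        """Copy with a new sample rate, event frames rescaled to match."""
        if not rescale_events:
            return replace(self, sample_rate=rate)
        factor = rate / self.sample_rate
        return replace(
            self,
            sample_rate=rate,
            fall_start_frame=int(round(self.fall_start_frame * factor)),
            fall_end_frame=int(round(self.fall_end_frame * factor)),
        )


def _check_equal_lengths(markers: Dict[str, np.ndarray], ncol: int) -> None:
    lengths = {m: np.asarray(v).shape for m, v in markers.items()}
    for m, shape in lengths.items():
        if len(shape) != 2 or shape[1] != ncol:
            raise ValueError(f"marker {m!r}: expected (n, {ncol}) array, got {shape}")
    n = {shape[0] for shape in lengths.values()}
    if len(n) > 1:
        raise ValueError(f"marker series lengths differ: {lengths}")


@dataclass
class Trial3D:
    """One fall's 3D marker trajectories (ground-truth side)."""

    meta: TrialMeta
    markers: Dict[str, np.ndarray]  # label -> (n, 3) array of (X, Y, Z) in m

    def __post_init__(self) -> None:
        self.markers = {m: np.asarray(v, dtype=float) for m, v in self.markers.items()}
        if not self.markers:
            raise ValueError("trial has no markers")
        _check_equal_lengths(self.markers, 3)

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def marker_names(self) -> List[str]:
        return list(self.markers)


@dataclass
class Trial2D:
    """One fall's planar marker trajectories from a single camera view."""

    meta: TrialMeta
    camera_angle: float  # degrees to the fall plane (90 = perpendicular)
    unit: Literal["pixel", "metre"]
    markers: Dict[str, np.ndarray]  # label -> (n, 2) array (horizontal, vertical)
    out_of_frame: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.markers = {m: np.asarray(v, dtype=float) for m, v in self.markers.items()}
        if not self.markers:
            raise ValueError("trial has no markers")
        _check_equal_lengths(self.markers, 2)
        if self.unit not in ("pixel", "metre"):
            raise ValueError(f"invalid unit {self.unit!r}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def marker_names(self) -> List[str]:
        return list(self.markers)


#: Direction-specific segment definitions as (segment, proximal, distal)
#: marker pairs.  Segment angles are measured for the distal-minus-proximal
#: vector with respect to the horizontal.  The pelvis marker is GT for
#: forward/backward falls and ASIS for sideways falls; the head segment uses
#: the shoulder for forward/backward and the sternum for sideways falls.
SEGMENT_DEFINITIONS: Dict[str, List[Tuple[str, str, str]]] = {
    "forward": [
        ("head", "shoulder", "head"),
        ("torso", "GT", "shoulder"),
        ("thigh", "GT", "knee"),
        ("upper_arm", "elbow", "shoulder"),
        ("forearm", "elbow", "wrist"),
        ("shank", "knee", "ankle"),
    ],
    "sideways": [
        ("head", "sternum", "head"),
        ("torso", "ASIS", "shoulder"),
        ("thigh", "ASIS", "knee"),
        ("upper_arm", "elbow", "shoulder"),
        ("forearm", "elbow", "wrist"),
        ("shank", "knee", "ankle"),
    ],
}
SEGMENT_DEFINITIONS["backward"] = SEGMENT_DEFINITIONS["forward"]


def segment_map(direction: Direction) -> List[Tuple[str, str, str]]:
    """Return the (segment, proximal, distal) triples for a fall direction."""
    try:
        return list(SEGMENT_DEFINITIONS[direction])
    except KeyError:
        raise ValueError(f"invalid direction {direction!r}") from None
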