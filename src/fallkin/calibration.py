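"""Camera projection and pixel-to-metre calibration geometry.

The fall plane is the world X-Z plane at Y = 0 (X in-plane horizontal,
Z vertical up).  A camera at angle ``a`` to the fall plane sits at distance
``d`` from the scene centre along the direction (cos a, sin a, 0): a 90 deg
camera looks along -Y, perpendicular to the plane, like the ideal
surveillance placement; 30 and 60 deg cameras view the plane obliquely.

Two calibration models convert digitized pixel coordinates to fall-plane
metres, mirroring the two techniques available in planar-video digitization
software:

* ``grid2d`` — a plane homography fitted to the image of a 1.6 x 1.6 m
  board with a 5 x 5 array of dots spaced 0.40 m, nominally standing in
  the fall plane.  Translating or rotating the board away from that plane
  biases the mapping; those perturbations are first-class parameters.
* ``line1d`` — a single isotropic metres-per-pixel scale from the imaged
  standing height of the participant (foot to head), with an optional
  error in the assumed height.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np
from skimage.transform import ProjectiveTransform

from .trials import Trial2D


@dataclass(frozen=True)
class CameraModel:
    """Ideal pinhole camera observing the fall plane.

    Defaults: 3.5 m from the scene centre, focal length 560 px (a 4 m wide
    scene fills the 640 px sensor at that range), principal point at the
    image centre, no lens distortion.
    """

    angle_to_fall_plane: float = 90.0  # degrees
    distance: float = 3.5  # m from scene centre
    focal_length: float = 560.0  # px
    principal_point: Tuple[float, float] = (320.0, 240.0)
    resolution: Tuple[int, int] = (640, 480)
    scene_centre: Tuple[float, float, float] = (0.0, 0.0, 0.8)

    def __post_init__(self) -> None:
        if not (0 < self.angle_to_fall_plane <= 90):
            raise ValueError("camera angle must be in (0, 90] degrees")
        if self.distance <= 0 or self.focal_length <= 0:
            raise ValueError("distance and focal length must be positive")

    @property
    def position(self) -> np.ndarray:
        a = np.radians(self.angle_to_fall_plane)
        c = np.asarray(self.scene_centre, dtype=float)
        return c + self.distance * np.array([np.cos(a), np.sin(a), 0.0])

    @property
    def rotation(self) -> np.ndarray:
        """World-to-camera rotation (rows: image right, image down, forward)."""
        c = np.asarray(self.scene_centre, dtype=float)
        fwd = c - self.position
        fwd = fwd / np.linalg.norm(fwd)
        up = np.array([0.0, 0.0, 1.0])
        right = np.cross(fwd, up)
        right = right / np.linalg.norm(right)
        down = np.cross(fwd, right)
        return np.vstack([right, down, fwd])


class BehindCameraError(ValueError):
    """A scene point lies at or behind the camera plane."""


def project_point(
    cam: CameraModel, p: np.ndarray, quantize: bool = False
) -> np.ndarray:
    """Perspective projection of world point(s) to (column, row) pixels.

    Accepts a single 3-vector or an (n, 3) array.  ``quantize`` rounds to
    integer pixels (adding at most 0.5 px error per axis).
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    pc = (p - cam.position) @ cam.rotation.T
    if np.any(pc[:, 2] <= 1e-9):
        raise BehindCameraError("point at or behind the camera plane")
    u = cam.focal_length * pc[:, 0] / pc[:, 2] + cam.principal_point[0]
    v = cam.focal_length * pc[:, 1] / pc[:, 2] + cam.principal_point[1]
    px = np.column_stack([u, v])
    if quantize:
        px = np.round(px)
    return px[0] if single else px


@dataclass(frozen=True)
class GridSpec:
    """The 2D calibration board: 5 x 5 dots spaced 0.40 m (1.6 x 1.6 m).

    ``translation_from_fall_plane`` is signed along world +Y, positive
    toward the camera (cameras sit at positive Y); ``rotation_about_vertical``
    turns the board about the vertical axis through its centre.
    """

    size: float = 1.6  # m
    n_dots: int = 5
    spacing: float = 0.4  # m
    centre: Tuple[float, float] = (0.0, 0.8)  # (X, Z) of board centre
    translation_from_fall_plane: float = 0.0  # m, +toward camera
    rotation_about_vertical: float = 0.0  # degrees

    def __post_init__(self) -> None:
        if abs(self.translation_from_fall_plane) > 0.5 + 1e-12:
            raise ValueError("|grid translation| beyond supported 0.5 m")
        if abs(self.rotation_about_vertical) > 45 + 1e-12:
            raise ValueError("|grid rotation| beyond supported 45 degrees")

    def nominal_plane_coords(self) -> np.ndarray:
        """(25, 2) nominal (X, Z) fall-plane coordinates of the dots —
        the coordinates the calibration software is told the dots occupy."""
        half = (self.n_dots - 1) / 2
        offs = (np.arange(self.n_dots) - half) * self.spacing
        gx, gz = np.meshgrid(offs, offs, indexing="xy")
        pts = np.column_stack([gx.ravel() + self.centre[0], gz.ravel() + self.centre[1]])
        return pts

    def world_points(self) -> np.ndarray:
        """(25, 3) actual 3D dot positions after translation/rotation."""
        nom = self.nominal_plane_coords()
        lx = nom[:, 0] - self.centre[0]
        th = np.radians(self.rotation_about_vertical)
        x = self.centre[0] + lx * np.cos(th)
        y = lx * np.sin(th) + self.translation_from_fall_plane
        z = nom[:, 1]
        return np.column_stack([x, y, z])


def perturb_grid(g: GridSpec, translation: float = 0.0, rotation: float = 0.0) -> GridSpec:
    """Return a copy of the board translated/rotated out of the fall plane.

    Supported ranges follow the experimental sweeps: |translation| <= 0.5 m,
    |rotation| <= 45 deg (validated by GridSpec itself).
    """
    return replace(
        g,
        translation_from_fall_plane=translation,
        rotation_about_vertical=rotation,
    )


@dataclass
class CalibrationMapping:
    """Pixel -> fall-plane-metre transform.

    ``kind="grid2d"``: 3x3 homography mapping homogeneous pixel coordinates
    to (X, Z) fall-plane metres.  ``kind="line1d"``: isotropic scale about
    an origin pixel, image vertical flipped so Z is up.
    """

    kind: str  # grid2d | line1d
    matrix: np.ndarray | None = None  # 3x3, grid2d
    scale: float | None = None  # m/px, line1d
    origin_px: Tuple[float, float] | None = None  # line1d
    horizontal_sign: int = 1  # line1d: +1 if image u grows with world X
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "grid2d":
            m = np.asarray(self.matrix, dtype=float)
            if m.shape != (3, 3):
                raise ValueError("grid2d mapping needs a 3x3 matrix")
            if abs(np.linalg.det(m)) < 1e-15:
                raise ValueError("homography is singular")
            self.matrix = m
        elif self.kind == "line1d":
            if self.scale is None or self.scale <= 0:
                raise ValueError("line1d mapping needs a positive scale")
            if self.origin_px is None:
                raise ValueError("line1d mapping needs an origin pixel")
        else:
            raise ValueError(f"unknown calibration kind {self.kind!r}")

    def pixels_to_metres(self, px: np.ndarray) -> np.ndarray:
        """Map (n, 2) pixel coordinates to (horizontal, vertical) metres."""
        px = np.asarray(px, dtype=float)
        if self.kind == "grid2d":
            h = np.column_stack([px, np.ones(len(px))]) @ self.matrix.T
            return h[:, :2] / h[:, 2:3]
        u0, v0 = self.origin_px
        out = np.empty_like(px)
        out[:, 0] = self.horizontal_sign * (px[:, 0] - u0) * self.scale
        out[:, 1] = -(px[:, 1] - v0) * self.scale  # image rows grow downward
        return out

    def to_json(self) -> str:
        d = {"kind": self.kind, "provenance": self.provenance}
        if self.kind == "grid2d":
            d["matrix"] = self.matrix.tolist()
        else:
            d["scale"] = self.scale
            d["origin_px"] = list(self.origin_px)
            d["horizontal_sign"] = self.horizontal_sign
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "CalibrationMapping":
        d = json.loads(s)
        return cls(
            kind=d["kind"],
            matrix=np.asarray(d["matrix"]) if "matrix" in d else None,
            scale=d.get("scale"),
            origin_px=tuple(d["origin_px"]) if "origin_px" in d else None,
            horizontal_sign=d.get("horizontal_sign", 1),
            provenance=d.get("provenance", {}),
        )


def fit_grid_homography(
    image_dots: np.ndarray, world_dots: np.ndarray, provenance: dict | None = None
) -> CalibrationMapping:
    """Least-squares plane homography (normalized DLT) from dot
    correspondences: image pixels -> nominal fall-plane (X, Z) metres.

    Needs at least 4 non-collinear correspondences; with the full 5 x 5
    board the fit is overdetermined and noise-robust.
    """
    image_dots = np.asarray(image_dots, dtype=float)
    world_dots = np.asarray(world_dots, dtype=float)
    if image_dots.shape != world_dots.shape or image_dots.shape[0] < 4:
        raise ValueError("need >= 4 matching image/world points")
    for pts, name in ((image_dots, "image"), (world_dots, "world")):
        s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise ValueError(f"degenerate (collinear) {name} dot configuration")
    tf = ProjectiveTransform.from_estimate(image_dots, world_dots)
    if not tf or not np.all(np.isfinite(tf.params)):
        raise ValueError("degenerate dot configuration (collinear points?)")
    return CalibrationMapping(
        kind="grid2d", matrix=tf.params, provenance=provenance or {}
    )


def image_grid(cam: CameraModel, grid: GridSpec, noise_px: float = 0.0,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Project the board's dots through a camera, optionally with seeded
    digitization noise, giving the (25, 2) pixel observations."""
    px = project_point(cam, grid.world_points())
    if noise_px > 0:
        if rng is None:
            rng = np.random.default_rng()
        px = px + rng.normal(0.0, noise_px, size=px.shape)
    return px


def calibrate_from_grid(
    cam: CameraModel, grid: GridSpec, noise_px: float = 0.0,
    rng: np.random.Generator | None = None,
) -> CalibrationMapping:
    """Image the board with ``cam`` and fit the grid2d mapping, exactly as
    done in the laboratory: the same camera pose images board and fall."""
    px = image_grid(cam, grid, noise_px=noise_px, rng=rng)
    prov = {
        "grid": {
            "translation_m": grid.translation_from_fall_plane,
            "rotation_deg": grid.rotation_about_vertical,
        },
        "camera_angle_deg": cam.angle_to_fall_plane,
    }
    return fit_grid_homography(px, grid.nominal_plane_coords(), provenance=prov)


def fit_height_scale(
    head_pixel: Tuple[float, float],
    foot_pixel: Tuple[float, float],
    assumed_height: float,
    horizontal_sign: int = 1,
) -> CalibrationMapping:
    """1D calibration: metres-per-pixel from the imaged standing height.

    ``assumed_height`` is the height entered by the analyst (m); an error
    of ±0.10 m relative to the true value scales every reconstructed linear
    measure proportionally while leaving angles untouched.
    """
    head = np.asarray(head_pixel, dtype=float)
    foot = np.asarray(foot_pixel, dtype=float)
    dist = float(np.linalg.norm(head - foot))
    if dist == 0:
        raise ValueError("head and foot pixels coincide")
    if assumed_height <= 0:
        raise ValueError("assumed height must be positive")
    return CalibrationMapping(
        kind="line1d",
        scale=assumed_height / dist,
        origin_px=(float(foot[0]), float(foot[1])),
        horizontal_sign=horizontal_sign,
        provenance={"assumed_height_m": assumed_height, "pixel_distance": dist},
    )


def apply_calibration(mapping: CalibrationMapping, t: Trial2D) -> Trial2D:
    """Convert a pixel-unit 2D trial to fall-plane metres."""
    if t.unit != "pixel":
        raise ValueError("calibration applies to pixel-unit trials only")
    markers = {m: mapping.pixels_to_metres(v) for m, v in t.markers.items()}
    return Trial2D(
        meta=t.meta,
        camera_angle=t.camera_angle,
        unit="metre",
        markers=markers,
        out_of_frame=dict(t.out_of_frame),
    )
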