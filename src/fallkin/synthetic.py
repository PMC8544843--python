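"""Synthetic fall generator and simulated camera observation.

The generator is a kinematic template, not a dynamic simulation: a planar
linked-segment body (ankle-knee-pelvis-shoulder-head chain plus
shoulder-elbow-wrist arm and a sternum marker on the torso) whose absolute
segment angles follow minimum-jerk transitions from a standing posture to a
direction-appropriate landed posture over the fall duration.  This keeps
the frequency content controllable (falls are ~1 s events with essentially
all signal energy below 10 Hz) and the landing time exact, at the cost of
physical realism — documented as such.

Study-condition defaults baked into the generator:

* perturbation-induced falls start with a support-surface translation that
  accelerates at 10 m/s^2 to 2.2 m/s, holds, then decelerates, all within
  0.6 s (the platform protocol used to simulate slips/trips);
* self-initiated falls start from a slow 0.5 Hz pre-fall sway;
* head peak vertical velocity lands near 3 m/s;
* out-of-plane (Y) excursions are low-frequency half-sines with per-marker
  amplitudes calibrated to the reported fall-direction means (largest at
  the knee/elbow/pelvis in sideways falls, up to ~0.21 m);
* motion-capture markers sit on the camera-facing body surface, by default
  0.05 m toward the camera from the fall mid-plane where the calibration
  grid stands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import signal as _sig

from .calibration import CameraModel, project_point
from .trials import Trial2D, Trial3D, TrialMeta

RATE_3D = 600.0  # Hz
RATE_2D = 30.0  # Hz


@dataclass(frozen=True)
class PerturbationProfile:
    """Trapezoidal support-surface translation used to induce falls."""

    acceleration: float = 10.0  # m/s^2
    plateau_velocity: float = 2.2  # m/s
    total_duration: float = 0.6  # s

    def __post_init__(self) -> None:
        if self.acceleration <= 0 or self.plateau_velocity <= 0:
            raise ValueError("acceleration and plateau velocity must be positive")
        if 2 * self.ramp_time > self.total_duration:
            raise ValueError("ramp phases exceed total duration")

    @property
    def ramp_time(self) -> float:
        return self.plateau_velocity / self.acceleration


def platform_profile(
    p: PerturbationProfile, t: np.ndarray | float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(displacement, velocity, acceleration) of the platform at time t >= 0.

    Accelerate / constant-velocity / decelerate; velocity is zero for
    t >= total_duration and the platform stays at its final displacement.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    ta = p.ramp_time
    tp = p.total_duration - 2 * ta  # plateau duration
    a, v = p.acceleration, p.plateau_velocity
    t1, t2, t3 = ta, ta + tp, p.total_duration
    d1 = 0.5 * a * ta**2
    d2 = d1 + v * tp

    disp = np.where(
        t < t1,
        0.5 * a * t**2,
        np.where(
            t < t2,
            d1 + v * (t - t1),
            np.where(
                t < t3,
                d2 + v * (t - t2) - 0.5 * a * (t - t2) ** 2,
                d2 + v * ta - 0.5 * a * ta**2,
            ),
        ),
    )
    vel = np.where(
        t < t1, a * t, np.where(t < t2, v, np.where(t < t3, v - a * (t - t2), 0.0))
    )
    acc = np.where(t < t1, a, np.where(t < t2, 0.0, np.where(t < t3, -a, 0.0)))
    return disp, vel, acc


#: Standing marker heights as fractions of participant height.
MARKER_HEIGHT_FRACTIONS = {
    "ankle": 0.039,
    "knee": 0.285,
    "GT": 0.530,
    "ASIS": 0.585,
    "sternum": 0.720,
    "shoulder": 0.818,
    "head": 0.936,
    "elbow": 0.630,
    "wrist": 0.485,
}

# Landed-posture absolute segment angles (deg from horizontal) for a fall in
# the +X direction; backward falls mirror X.  Chosen so the head drops by
# roughly its standing height minus knee/hip flexion, matching the reported
# mean head descent (~1.1 m) and peak vertical velocity (~3 m/s) for ~1 s
# falls.
_END_ANGLES = {
    "shank": 32.0,
    "thigh": 18.0,
    "torso": 2.0,
    "head_seg": -2.0,
    "upper_arm": 40.0,  # shoulder -> elbow; arms thrown out protectively
    "forearm": 60.0,  # elbow -> wrist
}
_START_ANGLES = {
    "shank": 90.0,
    "thigh": 90.0,
    "torso": 90.0,
    "head_seg": 90.0,
    "upper_arm": -90.0,
    "forearm": -90.0,
}
# Movement irregularity is not uniform across the body: the trunk and head
# fall relatively smoothly while the limbs carry the stepping corrections
# and protective arm responses (multipliers on FallParams.irregularity).
_IRREGULARITY_WEIGHTS = {
    "shank": 1.0,
    "thigh": 1.0,
    "torso": 0.7,
    "head_seg": 0.7,
    "upper_arm": 2.4,
    "forearm": 3.2,
}

# Distal segments start their transition slightly later (fraction of fall
# duration); everything lands together.
_SEGMENT_DELAYS = {
    "torso": 0.00,
    "head_seg": 0.00,
    "thigh": 0.05,
    "shank": 0.10,
    "upper_arm": 0.10,
    "forearm": 0.10,
}

#: Default out-of-plane half-sine amplitudes (m) per marker, by direction,
#: calibrated to the reported per-direction means (backward 0.089 m,
#: forward 0.099 m, sideways 0.158 m across body parts; wrist largest in
#: backward falls, elbow/pelvis/knee largest in sideways falls).
DEFAULT_Y_AMPLITUDES: Dict[str, Dict[str, float]] = {
    "backward": {
        "head": 0.06, "shoulder": 0.07, "sternum": 0.07, "elbow": 0.09,
        "wrist": 0.161, "GT": 0.07, "knee": 0.08, "ankle": 0.05,
    },
    "forward": {
        "head": 0.07, "shoulder": 0.08, "sternum": 0.08, "elbow": 0.12,
        "wrist": 0.13, "GT": 0.09, "knee": 0.10, "ankle": 0.06,
    },
    "sideways": {
        "head": 0.12, "shoulder": 0.13, "sternum": 0.12, "elbow": 0.195,
        "wrist": 0.15, "ASIS": 0.172, "knee": 0.207, "ankle": 0.08,
    },
}


@dataclass
class FallParams:
    """Parameters for one synthetic fall."""

    trial_id: str = "fall"
    direction: str = "forward"
    initiation: str = "perturbation"
    participant_height: float = 1.70  # m
    duration: Optional[float] = None  # s; sampled in [1.0, 1.3] if None
    out_of_plane_amplitudes: Optional[Dict[str, float]] = None  # m per marker
    out_of_plane_scale: float = 1.0
    marker_plane_offset: float = 0.05  # m toward the camera (+Y)
    irregularity: float = 0.30  # movement-irregularity velocity RMS, as a
    # fraction of each segment's peak angular velocity (times the
    # per-segment weight table)
    jitter: float = 0.10  # relative seeded variability of timings/amplitudes
    pre_s: float = 0.4
    post_s: float = 0.4
    perturbation: PerturbationProfile = field(default_factory=PerturbationProfile)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration is not None:
            if self.initiation == "perturbation" and self.duration <= self.perturbation.total_duration:
                raise ValueError("fall duration must exceed the perturbation duration")
        if self.out_of_plane_scale < 0:
            raise ValueError("out_of_plane_scale must be >= 0")


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _fall_profile(
    tau: np.ndarray,
    accel_frac: float = 0.4,
    rise_ratio: float = 1.5,
    brake_frac: float = 0.07,
) -> np.ndarray:
    """Normalized descent profile with an impact-like landing.

    Unlike a minimum-jerk reach, a fall gathers speed all the way to
    ground contact and then stops abruptly.  Three phases: a cubic
    acceleration from rest over ``accel_frac`` of the transition; a
    continued linear velocity rise to ``rise_ratio`` times the phase-1
    exit velocity (the descent keeps accelerating under gravity); and a
    linear velocity ramp-down to zero over the final ``brake_frac`` (the
    impact, ~0.07 s for ~1 s falls).  Position and velocity are
    continuous; s(1) = 1, s'(1) = 0.  Velocity therefore peaks *at*
    impact, and the sharp corner there carries the 3-10 Hz content that
    low filter cutoffs visibly clip — the behaviour real falls show.
    """
    tau = np.clip(tau, 0.0, 1.0)
    ta, r, h = accel_frac, rise_ratio, brake_frac
    tc = 1.0 - h
    amp = 1.0 / (ta**3 + 3 * ta**2 * ((1 + r) * (tc - ta) / 2 + r * h / 2))
    v1 = 3 * amp * ta**2
    v_p = r * v1
    p_a = amp * ta**3
    p_c = p_a + (v1 + v_p) * (tc - ta) / 2
    mid = tau - ta
    brake = tau - tc
    return np.where(
        tau < ta,
        amp * tau**3,
        np.where(
            tau < tc,
            p_a + v1 * mid + (v_p - v1) * mid**2 / (2 * (tc - ta)),
            p_c + v_p * brake - (v_p / (2 * h)) * brake**2,
        ),
    )


def _pelvis_marker(direction: str) -> str:
    return "ASIS" if direction == "sideways" else "GT"


def _movement_irregularity(
    n: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-scale angular-velocity irregularity (rad/s before scaling).

    Falls are not smooth single-arc movements: stepping corrections,
    protective arm responses and soft-tissue motion put broadband content
    into the 2-15 Hz band, peaking around 3-5 Hz and declining as ~f^-2
    above.  Modeled as white noise band-shaped by two first-order
    low-pass stages at 4 Hz and a second-order high-pass at 2.5 Hz,
    normalized to unit RMS.  The caller integrates it into the angle
    trajectory and scales it per segment.
    """
    w = rng.standard_normal(n)
    nyq = rate / 2.0
    b, a = _sig.butter(1, 4.0 / nyq, btype="low")
    v = _sig.lfilter(b, a, _sig.lfilter(b, a, w))
    bh, ah = _sig.butter(2, 2.5 / nyq, btype="high")
    v = _sig.lfilter(bh, ah, v)
    rms = np.sqrt(np.mean(v**2))
    return v / rms if rms > 0 else v


def simulate_fall(params: FallParams) -> Trial3D:
    """Generate one fall's 3D marker trajectories at 600 Hz.

    Deterministic under a fixed seed.  Event frames mark the fall onset
    (platform-motion onset, or start of descent for self-initiated falls)
    and the landing time.
    """
    rng = np.random.default_rng(params.seed)
    h = params.participant_height
    if not (1.0 < h < 2.5):
        raise ValueError("participant height outside (1.0, 2.5) m")
    D = params.duration
    if D is None:
        D = float(rng.uniform(1.0, 1.3))
        if params.initiation == "perturbation" and D <= params.perturbation.total_duration:
            raise ValueError("sampled duration below perturbation duration")

    pelvis = _pelvis_marker(params.direction)
    frac = MARKER_HEIGHT_FRACTIONS
    # chain segment lengths derived from standing marker heights
    L = {
        "shank": (frac["knee"] - frac["ankle"]) * h,
        "thigh": (frac[pelvis] - frac["knee"]) * h,
        "torso": (frac["shoulder"] - frac[pelvis]) * h,
        "head_seg": (frac["head"] - frac["shoulder"]) * h,
        "upper_arm": (frac["shoulder"] - frac["elbow"]) * h,
        "forearm": (frac["elbow"] - frac["wrist"]) * h,
    }
    sternum_frac = (frac["sternum"] - frac[pelvis]) / (frac["shoulder"] - frac[pelvis])

    dt = 1.0 / RATE_3D
    t_fall = params.pre_s
    # movement ceases once the post-impact rebound has decayed
    t_end = params.pre_s + D + 0.25
    n = int(round((params.pre_s + D + params.post_s) * RATE_3D)) + 1
    t = np.arange(n) * dt

    jit = params.jitter
    # per-segment staggered descent profiles with an impact rebound: on
    # ground contact each segment bounces back briefly on the compliant
    # landing surface (damped ~4 Hz oscillation, velocity-continuous)
    angles = {}
    for seg, a0 in _START_ANGLES.items():
        a1 = _END_ANGLES[seg]
        a1 = a0 + (a1 - a0) * (1.0 + jit * rng.uniform(-1, 1))
        delay = _SEGMENT_DELAYS[seg] * (1.0 + jit * rng.uniform(-1, 1)) * D
        tau = (t - (t_fall + delay)) / max(D - delay, 1e-9)
        brake = 0.07 * (1.0 + jit * rng.uniform(-1, 1))
        ang = a0 + (a1 - a0) * _fall_profile(tau, brake_frac=brake)
        # rebound: amplitude set as a fraction of the segment's peak
        # angular velocity at contact, opposing the direction of travel
        f_r = rng.uniform(3.5, 5.0)
        tau_r = 0.10 * (1.0 + jit * rng.uniform(-1, 1))
        ratio = 0.25 * (1.0 + jit * rng.uniform(-1, 1))
        omega = 2 * np.pi * f_r
        omega_pk = 1.77 * abs(np.radians(a1 - a0)) / max(D - delay, 1e-9)
        b = ratio * omega_pk / omega
        tp = np.clip(t - (t_fall + D), 0.0, None)
        ang = ang - np.degrees(
            np.sign(np.radians(a1 - a0))
            * b
            * (1 - np.cos(omega * tp))
            * np.exp(-tp / tau_r)
        )
        # movement irregularity: corrective/protective responses during
        # the fall, scaled to the segment's peak angular velocity and
        # windowed to the fall interval
        v_irr = _movement_irregularity(n, RATE_3D, rng)
        window = np.sin(np.pi * np.clip((t - t_fall) / (D + 0.25), 0.0, 1.0)) ** 2
        sigma_v = params.irregularity * _IRREGULARITY_WEIGHTS[seg] * omega_pk
        theta_irr = np.cumsum(v_irr * window) / RATE_3D
        angles[seg] = np.radians(ang) + sigma_v * theta_irr

    # pre-fall sway (self-initiated falls): a slow whole-body lean about the
    # ankle, faded out over the first fifth of the fall
    if params.initiation == "self_initiated":
        sway_amp = np.radians(2.0 * (1.0 + jit * rng.uniform(-1, 1)))
        fade = np.clip(1.0 - (t - t_fall) / (0.2 * D), 0.0, 1.0)
        sway = sway_amp * np.sin(2 * np.pi * 0.5 * t) * fade
        for seg in ("shank", "thigh", "torso", "head_seg"):
            angles[seg] = angles[seg] + sway

    # support-point horizontal motion
    base_x = np.zeros(n)
    if params.initiation == "perturbation":
        tp = np.clip(t - t_fall, 0.0, None)
        disp, _, _ = platform_profile(params.perturbation, tp)
        base_x = -disp  # platform slides opposite the fall direction

    # assemble the planar chain (fall in +X, vertical Z).  The feet are
    # anything but still: they kick up and drop back sharply (most of all
    # when falling backward, as the body tips away from them) and attempt
    # a rapid recovery step early in the descent.
    lift_amp = {"forward": 0.10, "backward": 0.25, "sideways": 0.16}[params.direction]
    tau_lift = np.clip((t - t_fall) / D, 0.0, 1.0)
    lift_profile = _fall_profile(tau_lift, brake_frac=0.08)
    ankle_lift = (
        lift_amp * (1.0 + jit * rng.uniform(-1, 1)) * np.sin(np.pi * lift_profile)
    )
    step_len = 0.20 * (1.0 + jit * rng.uniform(-1, 1))
    step_start = (0.25 + 0.1 * jit * rng.uniform(-1, 1)) * D
    step_dur = 0.30 * D
    foot_slide = step_len * _minimum_jerk((t - (t_fall + step_start)) / step_dur)
    # the foot excursion is local (absorbed by knee flexion): it moves the
    # ankle marker, not the chain above it
    pos = {}
    root = np.column_stack([base_x, np.full(n, frac["ankle"] * h)])
    pos["ankle"] = root + np.column_stack([foot_slide, ankle_lift])
    knee = root + L["shank"] * np.column_stack(
        [np.cos(angles["shank"]), np.sin(angles["shank"])]
    )
    pos["knee"] = knee
    pelv = knee + L["thigh"] * np.column_stack(
        [np.cos(angles["thigh"]), np.sin(angles["thigh"])]
    )
    pos[pelvis] = pelv
    shoulder = pelv + L["torso"] * np.column_stack(
        [np.cos(angles["torso"]), np.sin(angles["torso"])]
    )
    pos["shoulder"] = shoulder
    pos["sternum"] = pelv + sternum_frac * (shoulder - pelv)
    pos["head"] = shoulder + L["head_seg"] * np.column_stack(
        [np.cos(angles["head_seg"]), np.sin(angles["head_seg"])]
    )
    # angles["upper_arm"] is the shoulder->elbow direction (hanging = -90)
    elbow = shoulder + L["upper_arm"] * np.column_stack(
        [np.cos(angles["upper_arm"]), np.sin(angles["upper_arm"])]
    )
    pos["elbow"] = elbow
    pos["wrist"] = elbow + L["forearm"] * np.column_stack(
        [np.cos(angles["forearm"]), np.sin(angles["forearm"])]
    )

    if params.direction == "backward":
        for m in pos:
            pos[m] = pos[m] * np.array([-1.0, 1.0])

    # out-of-plane half-sine excursions during the fall, on top of the
    # constant marker-surface offset toward the camera
    amps = params.out_of_plane_amplitudes
    if amps is None:
        amps = DEFAULT_Y_AMPLITUDES[params.direction]
    tau_fall = np.clip((t - t_fall) / D, 0.0, 1.0)
    y_wave = np.sin(np.pi * tau_fall)
    markers = {}
    for m, xz in pos.items():
        a = amps.get(m, 0.0) * params.out_of_plane_scale
        a = a * (1.0 + jit * rng.uniform(-1, 1))
        y = params.marker_plane_offset + a * y_wave
        markers[m] = np.column_stack([xz[:, 0], y, xz[:, 1]])

    meta = TrialMeta(
        trial_id=params.trial_id,
        direction=params.direction,
        initiation=params.initiation,
        participant_height=h,
        fall_start_frame=int(round(t_fall * RATE_3D)),
        fall_end_frame=int(round(t_end * RATE_3D)),
        sample_rate=RATE_3D,
    )
    return Trial3D(meta=meta, markers=markers)


def observe_with_camera(
    t3d: Trial3D,
    cam: CameraModel,
    noise_px: float = 1.0,
    seed: int = 0,
    quantize: bool = False,
) -> Trial2D:
    """Project a 3D trial through a camera into a 30 Hz pixel-unit trial.

    Marker positions are projected at the native 600 Hz and decimated by
    sampling every 20th frame (video cameras sample instantaneously; no
    anti-alias filter is applied, matching a real sensor).  Seeded
    zero-mean isotropic Gaussian pixel noise stands in for human
    digitization error; optional integer quantization mimics pixel-grid
    snapping.  Markers leaving the frame are flagged (and a warning is
    issued) but their continuous coordinates are retained.
    """
    rng = np.random.default_rng(seed)
    step = int(round(t3d.meta.sample_rate / RATE_2D))
    markers = {}
    flags = {}
    w, hpx = cam.resolution
    for m, xyz in t3d.markers.items():
        px = project_point(cam, xyz[::step])
        if noise_px > 0:
            px = px + rng.normal(0.0, noise_px, size=px.shape)
        if quantize:
            px = np.round(px)
        out = (px[:, 0] < 0) | (px[:, 0] > w) | (px[:, 1] < 0) | (px[:, 1] > hpx)
        if out.any():
            warnings.warn(
                f"marker {m!r} outside the frame for {int(out.sum())} samples",
                RuntimeWarning,
                stacklevel=2,
            )
        markers[m] = px
        flags[m] = out
    meta = t3d.meta.with_rate(RATE_2D)
    return Trial2D(
        meta=meta,
        camera_angle=cam.angle_to_fall_plane,
        unit="pixel",
        markers=markers,
        out_of_frame=flags,
    )


def make_batch(
    n_per_cell: int = 6,
    seed: int = 0,
    **overrides,
) -> list[Trial3D]:
    """Generate a full study batch: ``n_per_cell`` falls in each direction x
    initiation cell (the laboratory protocol used 6, i.e. 36 falls)."""
    rng = np.random.default_rng(seed)
    trials = []
    for direction in ("forward", "backward", "sideways"):
        for initiation in ("perturbation", "self_initiated"):
            for k in range(n_per_cell):
                params = FallParams(
                    trial_id=f"{direction[:4]}_{initiation[:4]}_{k:02d}",
                    direction=direction,
                    initiation=initiation,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    **overrides,
                )
                trials.append(simulate_fall(params))
    return trials
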