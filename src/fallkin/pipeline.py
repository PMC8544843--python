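"""End-to-end orchestration: ground-truth construction, video-side
processing, accuracy comparison, sweeps, and summary tables.

The processing chain mirrors the laboratory analysis:

1. Ground truth: 3D marker positions low-pass filtered at 20 Hz (dual-pass
   4th-order Butterworth) at 600 Hz; velocities by central differences;
   a QC report records the share of unfiltered vertical-velocity traces
   with less than 4% of their spectral energy above 20 Hz.
2. Video side: pixels calibrated to fall-plane metres (2D grid homography
   or 1D height scale) -> low-pass filtered at the test cutoff at the
   native 30 Hz -> upsampled to 600 Hz by cubic spline -> synchronized to
   ground truth by cross-correlation of head vertical velocity -> zeroed
   at fall initiation -> segment angles and velocities.
3. Accuracy: RMSE, NRMSE and signed peak-velocity differences per fall x
   body part x outcome, over the annotated fall interval of the
   ground-truth trial; percent measures averaged per fall first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import accuracy as acc
from .calibration import (
    CalibrationMapping,
    CameraModel,
    GridSpec,
    calibrate_from_grid,
    fit_height_scale,
    apply_calibration,
    perturb_grid,
    project_point,
)
from .kinematics import peak_velocity, segment_angle_series
from .signal_ops import (
    FilterSpec,
    Series,
    central_difference,
    energy_fraction_above,
    lowpass_dualpass,
    resample_to,
    shift_series,
    sync_lag,
)
from .synthetic import MARKER_HEIGHT_FRACTIONS, RATE_2D, RATE_3D, observe_with_camera
from .trials import Trial2D, Trial3D, segment_map

ENERGY_CRITERION_HZ = 20.0
ENERGY_CRITERION_FRACTION = 0.04


@dataclass(frozen=True)
class ComparisonSpec:
    """One comparison condition, e.g. Q20-K10 at the 90 degree camera."""

    label: str
    test_source: str  # kinovea | qualisys
    test_cutoff: float  # Hz
    ground_truth_cutoff: float = 20.0
    camera_angle: float = 90.0
    calibration: str = "grid2d"  # grid2d | line1d
    grid_translation: float = 0.0  # m, + toward camera
    grid_rotation: float = 0.0  # degrees
    height_error: float = 0.0  # m added to the true height for line1d

    def __post_init__(self) -> None:
        if self.test_source not in ("kinovea", "qualisys"):
            raise ValueError(f"unknown test source {self.test_source!r}")
        if self.calibration not in ("grid2d", "line1d"):
            raise ValueError(f"unknown calibration {self.calibration!r}")


@dataclass
class SignalSet:
    """Processed per-trial signals on the 600 Hz ground-truth timeline."""

    trial_id: str
    interval: Tuple[int, int]  # half-open frames at 600 Hz
    pos: Dict[str, Dict[str, Series]]  # marker -> {"v": ..., "h": ...}
    vel: Dict[str, Dict[str, Series]]
    ang: Dict[str, Series] = field(default_factory=dict)  # segment -> degrees
    angvel: Dict[str, Series] = field(default_factory=dict)


def _angles_from_positions(
    pos: Dict[str, Dict[str, Series]], direction: str, rate: float
) -> Tuple[Dict[str, Series], Dict[str, Series]]:
    ang, angvel = {}, {}
    for seg, prox, dist in segment_map(direction):
        if prox not in pos or dist not in pos:
            continue
        p = np.column_stack([pos[prox]["h"].values, pos[prox]["v"].values])
        d = np.column_stack([pos[dist]["h"].values, pos[dist]["v"].values])
        a = segment_angle_series(p, d, seg, rate)
        s = Series(a.values, rate)
        ang[seg] = s
        angvel[seg] = central_difference(s)
    return ang, angvel


def build_ground_truth(
    trials: List[Trial3D], cutoff: float = 20.0
) -> Tuple[Dict[str, SignalSet], pd.DataFrame]:
    """Filter 3D trials into ground-truth signal sets, with a QC report.

    The QC report has one row per vertical-velocity trace (marker x trial,
    computed from *unfiltered* positions) giving its spectral energy
    fraction above 20 Hz and whether it meets the 4% criterion.
    """
    out: Dict[str, SignalSet] = {}
    qc_rows = []
    for trial in trials:
        rate = trial.meta.sample_rate
        spec = FilterSpec(cutoff=cutoff)
        i0, i1 = trial.meta.fall_start_frame, trial.meta.fall_end_frame
        pos: Dict[str, Dict[str, Series]] = {}
        vel: Dict[str, Dict[str, Series]] = {}
        raw_pos: Dict[str, Dict[str, Series]] = {}
        for m, xyz in trial.markers.items():
            raw_v = central_difference(Series(xyz[:, 2], rate))
            frac = energy_fraction_above(raw_v, ENERGY_CRITERION_HZ)
            qc_rows.append(
                {
                    "trial_id": trial.meta.trial_id,
                    "marker": m,
                    "energy_fraction_above_20hz": frac,
                    "passes_4pct": frac < ENERGY_CRITERION_FRACTION,
                }
            )
            fh = lowpass_dualpass(Series(xyz[:, 0], rate), spec)
            fv = lowpass_dualpass(Series(xyz[:, 2], rate), spec)
            raw_pos[m] = {"h": fh, "v": fv}
            fh0 = Series(fh.values - fh.values[i0], rate)
            fv0 = Series(fv.values - fv.values[i0], rate)
            pos[m] = {"h": fh0, "v": fv0}
            vel[m] = {"h": central_difference(fh0), "v": central_difference(fv0)}
        # angles come from the un-zeroed positions (zeroing each marker
        # separately would destroy inter-marker geometry)
        ang, angvel = _angles_from_positions(raw_pos, trial.meta.direction, rate)
        out[trial.meta.trial_id] = SignalSet(
            trial_id=trial.meta.trial_id,
            interval=(i0, i1),
            pos=pos,
            vel=vel,
            ang=ang,
            angvel=angvel,
        )
    return out, pd.DataFrame(qc_rows)


def default_camera(angle: float) -> CameraModel:
    return CameraModel(angle_to_fall_plane=angle)


def line1d_mapping(
    trial3d: Trial3D, cam: CameraModel, assumed_height: float,
    standing_frame: int = 0,
) -> CalibrationMapping:
    """1D height calibration from the imaged standing posture.

    The calibration line spans from the ground point below the ankle to
    the top of the head (head marker plus the residual head height
    fraction), as an analyst would draw it on a standing frame, and is set
    equal to the assumed participant height.
    """
    ankle = trial3d.markers["ankle"][standing_frame]
    head = trial3d.markers["head"][standing_frame]
    h_true = trial3d.meta.participant_height
    foot_w = np.array([ankle[0], ankle[1], 0.0])
    head_top_w = head + np.array(
        [0.0, 0.0, (1.0 - MARKER_HEIGHT_FRACTIONS["head"]) * h_true]
    )
    foot_px = project_point(cam, foot_w)
    head_px = project_point(cam, head_top_w)
    # image u decreases with world X for a camera on the +Y side
    return fit_height_scale(head_px, foot_px, assumed_height, horizontal_sign=-1)


def build_mapping(
    spec: ComparisonSpec,
    cam: CameraModel,
    trial3d: Trial3D,
    noise_px: float,
    rng: np.random.Generator,
) -> CalibrationMapping:
    if spec.calibration == "grid2d":
        grid = perturb_grid(
            GridSpec(), translation=spec.grid_translation, rotation=spec.grid_rotation
        )
        return calibrate_from_grid(cam, grid, noise_px=noise_px, rng=rng)
    assumed = trial3d.meta.participant_height + spec.height_error
    return line1d_mapping(trial3d, cam, assumed)


def process_test_side(
    trial: Trial2D | Trial3D,
    spec: ComparisonSpec,
    gt: SignalSet,
    mapping: Optional[CalibrationMapping] = None,
) -> SignalSet:
    """Process one test-side trial onto the ground-truth timeline."""
    if spec.test_source == "qualisys":
        return _process_qualisys(trial, spec, gt)
    return _process_kinovea(trial, spec, gt, mapping)


def _process_qualisys(trial: Trial3D, spec: ComparisonSpec, gt: SignalSet) -> SignalSet:
    rate = trial.meta.sample_rate
    fspec = FilterSpec(cutoff=spec.test_cutoff)
    i0 = gt.interval[0]
    pos, vel, raw_pos = {}, {}, {}
    for m, xyz in trial.markers.items():
        fh = lowpass_dualpass(Series(xyz[:, 0], rate), fspec)
        fv = lowpass_dualpass(Series(xyz[:, 2], rate), fspec)
        raw_pos[m] = {"h": fh, "v": fv}
        fh0 = Series(fh.values - fh.values[i0], rate)
        fv0 = Series(fv.values - fv.values[i0], rate)
        pos[m] = {"h": fh0, "v": fv0}
        vel[m] = {"h": central_difference(fh0), "v": central_difference(fv0)}
    ang, angvel = _angles_from_positions(raw_pos, trial.meta.direction, rate)
    return SignalSet(trial.meta.trial_id, gt.interval, pos, vel, ang, angvel)


def _match_length(values: np.ndarray, n: int) -> np.ndarray:
    if len(values) == n:
        return values
    if len(values) > n:
        return values[:n]
    return np.concatenate([values, np.full(n - len(values), values[-1])])


def _process_kinovea(
    trial: Trial2D,
    spec: ComparisonSpec,
    gt: SignalSet,
    mapping: Optional[CalibrationMapping],
) -> SignalSet:
    if "head" not in trial.markers:
        raise ValueError("cannot synchronize: head marker missing")
    if trial.unit == "pixel":
        if mapping is None:
            raise ValueError("pixel-unit trial requires a calibration mapping")
        trial = apply_calibration(mapping, trial)
    fspec = FilterSpec(cutoff=spec.test_cutoff)
    n_gt = len(gt.pos["head"]["v"])
    # calibrate -> filter at 30 Hz -> upsample to 600 Hz
    up: Dict[str, Dict[str, Series]] = {}
    for m, hv in trial.markers.items():
        fh = lowpass_dualpass(Series(hv[:, 0], RATE_2D), fspec)
        fv = lowpass_dualpass(Series(hv[:, 1], RATE_2D), fspec)
        up[m] = {
            "h": resample_to(fh, RATE_3D),
            "v": resample_to(fv, RATE_3D),
        }
    # synchronize on head vertical velocity
    head_v_test = central_difference(up["head"]["v"])
    head_v_ref = gt.vel["head"]["v"]
    lag = sync_lag(
        Series(_match_length(head_v_ref.values, n_gt), RATE_3D),
        Series(_match_length(head_v_test.values, n_gt), RATE_3D),
    )
    i0 = gt.interval[0]
    pos, vel, raw_pos = {}, {}, {}
    for m, hv in up.items():
        ph = shift_series(hv["h"], -lag)
        pv = shift_series(hv["v"], -lag)
        ph = Series(_match_length(ph.values, n_gt), RATE_3D)
        pv = Series(_match_length(pv.values, n_gt), RATE_3D)
        raw_pos[m] = {"h": ph, "v": pv}
        ph0 = Series(ph.values - ph.values[i0], RATE_3D)
        pv0 = Series(pv.values - pv.values[i0], RATE_3D)
        pos[m] = {"h": ph0, "v": pv0}
        vel[m] = {"h": central_difference(ph0), "v": central_difference(pv0)}
    direction = trial.meta.direction
    ang, angvel = _angles_from_positions(raw_pos, direction, RATE_3D)
    return SignalSet(trial.meta.trial_id, gt.interval, pos, vel, ang, angvel)


def compare_signal_sets(
    test: SignalSet, gt: SignalSet
) -> Tuple[List[acc.AccuracyRecord], List[dict]]:
    """Accuracy records and peak pairs for one trial.

    Linear outcomes per marker (vertical/horizontal position and velocity)
    and angular outcomes per segment, all over the ground-truth fall
    interval.  Peak differences are reported for velocities.
    """
    interval = gt.interval
    records: List[acc.AccuracyRecord] = []
    peaks: List[dict] = []

    def add(body: str, outcome: str, s_test: Series, s_ref: Series,
            with_peaks: bool, quantity: str = "") -> None:
        r = acc.rmse(s_test.values, s_ref.values, interval)
        nr = acc.nrmse(s_test.values, s_ref.values, interval)
        raw = pct = float("nan")
        if with_peaks:
            pk_t = peak_velocity(s_test, interval, body, quantity)
            pk_r = peak_velocity(s_ref, interval, body, quantity)
            # compare peak magnitudes so downward (negative) peaks follow
            # the overestimate-positive convention
            raw, pct = acc.peak_difference(
                abs(pk_t.peak_value), abs(pk_r.peak_value)
            )
            peaks.append(
                {
                    "trial_id": gt.trial_id,
                    "body_part": body,
                    "quantity": quantity,
                    "test_peak": pk_t.peak_value,
                    "ref_peak": pk_r.peak_value,
                }
            )
        records.append(
            acc.AccuracyRecord(gt.trial_id, body, outcome, r, nr, raw, pct)
        )

    for m in gt.pos:
        if m not in test.pos:
            continue
        add(m, "pos_v", test.pos[m]["v"], gt.pos[m]["v"], False)
        add(m, "pos_h", test.pos[m]["h"], gt.pos[m]["h"], False)
        add(m, "vel_v", test.vel[m]["v"], gt.vel[m]["v"], True, "v_vertical")
        add(m, "vel_h", test.vel[m]["h"], gt.vel[m]["h"], True, "v_horizontal")
    for seg in gt.ang:
        if seg not in test.ang:
            continue
        # remove whole-turn offsets from independent unwrapping
        a_t, a_r = test.ang[seg], gt.ang[seg]
        k = round((a_r.values[interval[0]] - a_t.values[interval[0]]) / 360.0)
        a_t = Series(a_t.values + 360.0 * k, a_t.sample_rate)
        add(seg, "pos_ang", a_t, a_r, False)
        add(seg, "vel_ang", test.angvel[seg], gt.angvel[seg], True, "v_angular")
    return records, peaks


def process_batch(
    batch3d: List[Trial3D],
    spec: ComparisonSpec,
    noise_px: float = 1.0,
    seed: int = 0,
    gt: Optional[Dict[str, SignalSet]] = None,
    observations: Optional[Dict[str, Trial2D]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run one comparison condition over a batch of 3D trials.

    Returns (records, peak pairs) as tidy DataFrames.  For video-side
    comparisons, each trial is observed through the condition's camera
    (unless precomputed ``observations`` are supplied), a calibration is
    fitted per trial, and the full processing chain runs.
    """
    if gt is None:
        gt, _ = build_ground_truth(batch3d, cutoff=spec.ground_truth_cutoff)
    rng = np.random.default_rng(seed)
    cam = default_camera(spec.camera_angle)
    all_records: List[acc.AccuracyRecord] = []
    all_peaks: List[dict] = []
    for trial in batch3d:
        g = gt[trial.meta.trial_id]
        if spec.test_source == "qualisys":
            test = _process_qualisys(trial, spec, g)
        else:
            if observations is not None:
                t2d = observations[trial.meta.trial_id]
            else:
                t2d = observe_with_camera(
                    trial, cam, noise_px=noise_px,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            mapping = build_mapping(
                spec, cam, trial, noise_px, rng
            )
            test = _process_kinovea(t2d, spec, g, mapping)
        recs, pks = compare_signal_sets(test, g)
        all_records.extend(recs)
        all_peaks.extend(pks)
    rec_df = acc.records_frame(all_records)
    rec_df.insert(0, "label", spec.label)
    return rec_df, pd.DataFrame(all_peaks)


SWEEP_DIMENSIONS = (
    "cutoff",
    "camera_angle",
    "grid_translation",
    "grid_rotation",
    "height_error",
    "fall_direction",
)


def run_sweep(
    batch3d: List[Trial3D],
    dimension: str,
    values: List[float] | List[str],
    base: Optional[ComparisonSpec] = None,
    noise_px: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep one methodological dimension, re-processing the batch at each
    value; returns tidy records with a ``sweep_value`` column."""
    if dimension not in SWEEP_DIMENSIONS:
        raise ValueError(f"unknown sweep dimension {dimension!r}")
    if not batch3d:
        raise ValueError("empty batch")
    base = base or ComparisonSpec(
        label="base", test_source="kinovea", test_cutoff=10.0
    )
    gt, _ = build_ground_truth(batch3d, cutoff=base.ground_truth_cutoff)
    frames = []
    rng = np.random.default_rng(seed)
    # one observation per trial per camera angle, shared across sweep values
    obs_cache: Dict[float, Dict[str, Trial2D]] = {}

    def observations_for(angle: float) -> Dict[str, Trial2D]:
        if angle not in obs_cache:
            cam = default_camera(angle)
            obs_cache[angle] = {
                t.meta.trial_id: observe_with_camera(
                    t, cam, noise_px=noise_px, seed=int(rng.integers(0, 2**31 - 1))
                )
                for t in batch3d
            }
        return obs_cache[angle]

    for v in values:
        kwargs = dict(
            label=f"{dimension}={v}",
            test_source=base.test_source,
            test_cutoff=base.test_cutoff,
            ground_truth_cutoff=base.ground_truth_cutoff,
            camera_angle=base.camera_angle,
            calibration=base.calibration,
            grid_translation=base.grid_translation,
            grid_rotation=base.grid_rotation,
            height_error=base.height_error,
        )
        subset = batch3d
        if dimension == "cutoff":
            kwargs["test_cutoff"] = float(v)
        elif dimension == "camera_angle":
            kwargs["camera_angle"] = float(v)
        elif dimension == "grid_translation":
            kwargs["grid_translation"] = float(v)
        elif dimension == "grid_rotation":
            kwargs["grid_rotation"] = float(v)
        elif dimension == "height_error":
            kwargs["height_error"] = float(v)
            kwargs["calibration"] = "line1d"
        elif dimension == "fall_direction":
            subset = [t for t in batch3d if t.meta.direction == v]
        spec = ComparisonSpec(**kwargs)
        obs = (
            observations_for(spec.camera_angle)
            if base.test_source == "kinovea"
            else None
        )
        sub_gt = {t.meta.trial_id: gt[t.meta.trial_id] for t in subset}
        rec, _ = process_batch(
            subset, spec, noise_px=noise_px, seed=seed, gt=sub_gt, observations=obs
        )
        rec.insert(1, "sweep_dimension", dimension)
        rec.insert(2, "sweep_value", v)
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)


def table_one(
    batch3d: List[Trial3D],
    cutoffs: List[float] = (14.0, 12.0, 10.0, 7.0, 5.0, 3.0),
    noise_px: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean ± SE error table: video (Q20-K*) and motion-capture (Q20-Q*)
    rows across filter cutoffs, averaged over all body parts and falls.

    Video rows use the 90 degree camera with the grid in the fall plane —
    the reference condition of the laboratory table.
    """
    gt, _ = build_ground_truth(batch3d)
    rng = np.random.default_rng(seed)
    cam = default_camera(90.0)
    observations = {
        t.meta.trial_id: observe_with_camera(
            t, cam, noise_px=noise_px, seed=int(rng.integers(0, 2**31 - 1))
        )
        for t in batch3d
    }
    rows = []
    for source, prefix in (("kinovea", "K"), ("qualisys", "Q")):
        for c in cutoffs:
            spec = ComparisonSpec(
                label=f"Q20-{prefix}{c:g}", test_source=source, test_cutoff=c
            )
            rec, _ = process_batch(
                batch3d, spec, noise_px=noise_px, seed=seed, gt=gt,
                observations=observations if source == "kinovea" else None,
            )
            agg = acc.aggregate(rec[rec.outcome.isin(["pos_v", "pos_h", "vel_v", "vel_h"])],
                                ["outcome"])
            row = {"comparison": spec.label}
            for _, r in agg.iterrows():
                o = r["outcome"]
                row[f"{o}_rmse"] = r["rmse_mean"]
                row[f"{o}_rmse_se"] = r["rmse_se"]
                row[f"{o}_nrmse"] = r["nrmse_mean"]
                row[f"{o}_nrmse_se"] = r["nrmse_se"]
                if o.startswith("vel"):
                    row[f"{o}_peak_raw"] = r["peak_diff_raw_mean"]
                    row[f"{o}_peak_raw_se"] = r["peak_diff_raw_se"]
                    row[f"{o}_peak_pct"] = r["peak_diff_pct_mean"]
                    row[f"{o}_peak_pct_se"] = r["peak_diff_pct_se"]
            rows.append(row)
    return pd.DataFrame(rows)


def format_table_one(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the reporting convention: position values below 0.001 m and
    velocity values below 0.01 m/s round up to those floors."""
    out = table.copy()
    for col in out.columns:
        if col == "comparison":
            continue
        floor = None
        if col.startswith("pos") and ("rmse" in col) and not col.endswith("_se"):
            if "nrmse" not in col:
                floor = 0.001
        if col.startswith("vel") and ("rmse" in col or "peak_raw" in col) \
                and not col.endswith("_se") and "nrmse" not in col and "pct" not in col:
            floor = 0.01
        if floor is not None:
            out[col] = np.where(np.abs(out[col]) < floor, floor, out[col])
    return out
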