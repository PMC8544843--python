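# fallkin

**Validation toolkit for 2D video-digitized fall kinematics against 3D
motion capture.**

Video footage of real-life falls (surveillance cameras: ~30 Hz, 640×480)
is increasingly used with manual digitization software to extract the
kinematics of the body during a fall — impact velocities for protective
gear design, segment orientations for fall-detection algorithms, pelvis
velocities for hip-fracture research. How accurate are those estimates,
and how does the accuracy depend on camera angle, pixel-to-metre
calibration, and the low-pass filter cutoff applied to the digitized
positions? `fallkin` implements the full validation pipeline for
answering these questions, for researchers in fall biomechanics and
movement analysis.

## What it computes

Ground truth is a set of 3D marker trajectories sampled at 600 Hz
(X = in-plane horizontal, Y = out-of-plane horizontal, Z = vertical),
low-pass filtered with a 4th-order dual-pass (zero-phase) Butterworth
filter at 20 Hz — a cutoff justified by the observation that less than 4%
of the spectral energy of vertical-velocity traces lies above 20 Hz. The
test signal is the planar video side: digitized marker positions at 30 Hz
in pixels, converted to metres by either

* a **2D grid homography** — a plane projective mapping fitted by
  normalized DLT to the image of a 1.6 × 1.6 m board carrying a 5 × 5
  array of dots at 0.40 m spacing, nominally in the plane of the fall
  (with controlled translation/rotation perturbations of the board), or
* a **1D height scale** — metres-per-pixel from the imaged standing
  height of the participant,

then filtered (dual-pass Butterworth, cutoffs 3–14 Hz), upsampled to
600 Hz by cubic spline, synchronized to ground truth by normalized
cross-correlation of head vertical velocity, and zeroed at fall
initiation. Velocities come from first-order central differences;
segment angles (head, torso, thigh, upper arm, forearm, shank) are
absolute orientations w.r.t. the horizontal via the two-argument inverse
tangent, unwrapped.

Accuracy per fall × body part × outcome, over the annotated fall
interval:

* **RMSE** — root-mean-square error between test and reference;
* **NRMSE** — RMSE as a percent of the reference signal's peak-to-peak
  amplitude;
* **peak-velocity differences** — signed raw and percent differences of
  peak (maximum-magnitude) velocities, overestimate positive;
* **agreement** — OLS slope, R², and mean signed error of test vs
  reference peaks.

A synthetic fall generator (linked-segment kinematic template with a
platform-perturbation profile, impact braking and rebound, out-of-plane
excursions, seeded movement irregularity) plus an ideal pinhole camera
make every stage runnable with no laboratory data — and make the
generator's injected quantities recoverable end to end.

## Worked example

```python
import fallkin as fk

# one synthetic sideways fall, observed by a 90-degree camera
trial = fk.simulate_fall(fk.FallParams(trial_id="demo", direction="sideways", seed=42))
gt, qc = fk.build_ground_truth([trial])

spec = fk.ComparisonSpec(label="Q20-K10", test_source="kinovea", test_cutoff=10.0)
records, peaks = fk.process_batch([trial], spec, noise_px=1.0, seed=0, gt=gt)
summary = fk.aggregate(records, ["outcome"])
print(summary[["outcome", "rmse_mean", "nrmse_mean"]].round(3).to_string(index=False))

oop = fk.out_of_plane_summary(trial)
print(f"knee out-of-plane excursion: {oop['knee'][0]:.3f} m")
```

prints

```
outcome  rmse_mean  nrmse_mean
pos_ang      1.863       2.353
  pos_h      0.021       2.439
  pos_v      0.014       3.503
vel_ang     38.825      13.275
  vel_h      0.191       4.723
  vel_v      0.179      10.301
knee out-of-plane excursion: 0.208 m
```

Reading this: with a 90° camera, in-plane grid calibration, 1 px
digitization noise and 10 Hz filtering, this sideways fall's vertical
positions are recovered to 0.014 m (3.5% of signal amplitude) and
vertical velocities to 0.18 m/s (10%); angular velocity errors are
larger (39 °/s), driven by the 0.21 m out-of-plane excursion of the knee
that a single fall-plane camera cannot see.

The same analyses run from the shell:

```bash
fallkin simulate --n-per-cell 6 --seed 0 --out falls.xlsx
fallkin qc falls.xlsx --out qc.csv
fallkin process falls.xlsx --cutoff 10 --camera-angle 90 --out records.csv
fallkin sweep falls.xlsx --dimension camera_angle --values 30,60,90 --out sweep.csv
fallkin table1 falls.xlsx --out table1.csv
```

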