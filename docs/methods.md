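# Methods

This note documents the models, conventions and numerical choices behind
`fallkin`, and what the synthetic data can and cannot tell you about
real video digitization.

## Processing model

**Ground truth.** 3D marker positions (600 Hz) are low-pass filtered
with a 4th-order Butterworth applied forward and backward (`filtfilt`),
cutoff 20 Hz. The dual pass cancels phase and squares the magnitude
response, so the gain at the nominal cutoff is 0.5 in power; no cutoff
pre-warping is applied to restore the −3 dB point — the stated cutoff is
the per-pass cutoff, the common convention in movement analysis. Edge
transients are suppressed by reflective (even) padding of three filter
lengths, discarded after filtering. A QC report records, per
vertical-velocity trace computed from *unfiltered* positions, the
fraction of spectral energy (squared DFT magnitude, DC excluded) above
20 Hz and whether it is below 4% — the premise that justifies the 20 Hz
ground-truth cutoff.

**Video side.** Order of operations is fixed: calibrate (pixels →
fall-plane metres) → filter at the test cutoff at the native 30 Hz →
upsample to 600 Hz → synchronize → zero → differentiate. Calibration
precedes filtering because the projective grid mapping is nonlinear and
does not commute with temporal filtering (for the fronto-parallel case
the order is immaterial). Upsampling uses a cubic spline on positions so
that differentiated velocities are continuous; linear interpolation is
available as an option. Synchronization maximizes the per-window Pearson
(zero-normalized) cross-correlation of head vertical velocity over
integer sample lags at 600 Hz within ±2 s, with at least 50% overlap;
ties break toward the smaller |lag|. The per-window normalization
matters: plain correlation of finite records is biased toward small lags
by the record means. Velocities and angular velocities use first-order
central differences (one-sided at the endpoints).

**Angles.** Segment angles are absolute orientations of the
distal-minus-proximal marker vector w.r.t. the horizontal,
atan2-based, unwrapped so no inter-sample jump exceeds 180°. Segment
definitions are direction-specific: the pelvis marker is the greater
trochanter (GT) for forward/backward falls and the anterior superior
iliac spine (ASIS) for sideways falls; the head segment uses the
shoulder (forward/backward) or the sternum (sideways). Because the two
sides of a comparison always use the same convention, any 180°
direction ambiguity cancels in RMSE. Before comparison, whole-turn
(360°·k) offsets from independent unwrapping are removed by matching
the value at fall initiation.

**Accuracy metrics.** All metrics are computed over the ground-truth
trial's annotated fall interval, a half-open 0-based frame range
[start, end). NRMSE normalizes by the *reference* signal's peak-to-peak
range over that interval — "signal amplitude" is not otherwise pinned
down, and the reference is the stable side of every comparison; this
choice scales all NRMSE outputs and is therefore stated prominently.
Peak velocity is the sample of maximal absolute value with sign
preserved (a signed-maximum mode exists); peak differences compare peak
*magnitudes*, test − reference, so an overestimate is positive
regardless of whether the underlying peak points up or down. Percent
measures are computed per fall, then averaged across falls. Group
summaries report mean ± SE (SD/√n); a single-member group reports SE 0
with n = 1.

## Camera and calibration geometry

The fall plane is the world X–Z plane at Y = 0. A camera at angle α to
that plane sits `distance` (default 3.5 m) from the scene centre along
(cos α, sin α, 0), looking at the centre: α = 90° is the ideal
perpendicular view; 30° and 60° are oblique. Default intrinsics: focal
length 560 px (a 4 m-wide scene fills the 640 px sensor at 3.5 m),
principal point at the image centre, no lens distortion (a hook exists
but defaults to none). All intrinsics are configurable; nothing in the
defaults is calibrated to a particular laboratory.

The 2D grid calibration images the 5 × 5 dot board through the *same*
camera pose that images the fall, adds the same digitization noise to
the dot pixels, and fits a plane homography (normalized DLT via
scikit-image) from image pixels to the board's *nominal* fall-plane
coordinates. Translating the board toward/away from the camera or
rotating it about the vertical therefore biases the mapping exactly as
it would in an experiment. Degenerate (collinear) dot configurations are
rejected explicitly. The 1D calibration scales isotropically by
assumed-height / pixel-height of the standing participant, measured from
the ground point below the ankle to the top of the head; an error in the
assumed height scales all linear outcomes proportionally and provably
leaves angular outcomes untouched.

One geometric subtlety: motion-capture markers sit on the camera-facing
surface of the body, not on the body midline where the grid stands. The
generator places markers 0.05 m toward the camera by default. This
offset is what makes grid translation *away* from the camera hurt more
than equal translation toward it (the marker plane is already slightly
toward the camera, so small toward-translations partially cancel), and
it slightly favours the height line — which self-calibrates at the
marker plane — on position outcomes.

**Digitization noise** is zero-mean isotropic Gaussian in pixels
(default σ = 1 px; optional integer quantization), seeded. It stands in
for human frame-by-frame digitization. Real human digitization error is
larger and temporally correlated (slow drifts of the clicked landmark on
the body), which white noise does not capture; consequences are listed
under Limitations.

## The synthetic fall generator

A kinematic template, not a dynamic simulation: prescribed absolute
segment-angle trajectories for a planar chain
(ankle–knee–pelvis–shoulder–head, plus shoulder–elbow–wrist and a
sternum marker on the torso), with segment lengths derived from
participant height via standard anthropometric fractions (configurable).
The template was chosen over forward dynamics for controllable frequency
content and exact landing times; it is non-physical and documented as
such.

Each segment's transition from standing to the direction-specific landed
posture follows a three-phase descent profile: cubic acceleration from
rest, a continued linear velocity rise (the body keeps gaining speed
under gravity), and a linear velocity ramp-down over the final ~7% of
the fall — the impact. A damped ~4 Hz rebound (velocity-continuous)
follows ground contact, and movement ceases 0.25 s after landing, which
is where the fall-end event is annotated. Distal segments start their
transitions slightly later than the trunk. On top of the smooth
template, each segment receives a seeded *movement-irregularity*
component: white noise band-shaped to a ~f⁻² angular-velocity amplitude
spectrum above ~3 Hz (two first-order low-pass stages at 4 Hz, a
second-order high-pass at 2.5 Hz), integrated into the angle, windowed
to the fall, weighted toward the limbs (stepping corrections and
protective arm responses; trunk weight 0.7, forearm weight 3.2), and
scaled to 0.30 of the segment's peak angular velocity. The feet kick up
and drop back sharply (largest in backward falls) and attempt a rapid
recovery step; both foot excursions are local to the ankle marker.

Study conditions baked into the defaults:

| quantity | default | basis |
|---|---|---|
| perturbation profile | 10 m/s² to 2.2 m/s, 0.6 s total | platform protocol for slip/trip-induced falls |
| fall duration | U[1.0, 1.3] s | ~1 s falls; with the impact-peaked profile this centres head peak vertical velocity near 3 m/s |
| sample rates | 600 Hz (3D), 30 Hz / 640×480 (video) | instrument conventions |
| out-of-plane amplitudes | per-marker half-sine, means ≈ 0.09/0.10/0.15 m (backward/forward/sideways), knee 0.207 m in sideways falls | reported out-of-plane statistics |
| irregularity scale | 0.30 | calibrated once so the motion-capture-side filter-distortion ladder (NRMSE ≈ 7.5/4.4/2.7/1.5% at 3/5/7/10 Hz cutoffs) matches the reported lower-bound comparisons |
| digitization noise | σ = 1 px | stated noise model |
| marker plane offset | 0.05 m toward camera | body-surface marker placement |

Self-initiated falls replace the platform with a slow 0.5 Hz pre-fall
sway, faded out over the first fifth of the descent. Backward falls
mirror the in-plane axis. All variability (durations, landed angles,
timings, amplitudes: ±10% relative) is drawn from a single seeded
generator; a fixed seed reproduces a trial bit-identically.

**What the generator emulates and what it does not.** It reproduces the
reported summary kinematics (head drop ~1.2 m, peak vertical/horizontal
velocities ~3.0/2.7 m/s), the spectral premises (position energy above
10 Hz < 5%, vertical-velocity energy above 20 Hz < 4%), the per-direction
out-of-plane magnitudes, and a realistic mid-band (3–10 Hz) velocity
content whose removal by low cutoffs mirrors the published
filter-distortion ladder. It does not reproduce: human digitization
drift (see noise model above), marker occlusion and soft-tissue
artifact, multi-impact landings (stairs, furniture), axial rotation
during descent, or inter-participant anthropometric variation beyond
height scaling. Passing tests on synthetic data therefore validate the
*pipeline* — geometry, filtering, synchronization, metrics — under the
stated statistical structure; they do not certify accuracy levels for
any particular real camera or rater.

## Numerical choices and degenerate inputs

* Filter: `scipy.signal.filtfilt`, even padding, padlen 3(order+1);
  series shorter than the padding are rejected, as are cutoffs at or
  above Nyquist. Video cutoffs above 14 Hz are rejected at the
  configuration level (Nyquist-safe ceiling for 30 Hz data).
* Resampling reproduces original sample instants exactly when the target
  rate is an integer multiple of the source rate; duration is preserved.
* Cross-correlation of a zero-variance signal raises; lags violating the
  50% overlap requirement are excluded.
* Spectral fractions with the threshold at/above Nyquist return 0 with a
  warning. Records shorter than 8 samples are rejected.
* Coincident proximal/distal markers raise an error naming the frame.
* Zero-amplitude reference signals make NRMSE undefined and raise; the
  generator consequently gives every marker genuine motion.
* NaN gaps: CSV serialization round-trips NaN as empty fields. Gap
  interpolation is deliberately not performed beyond what filtering
  tolerates; trials with gaps should be repaired upstream.
* Workbook cells store full-precision decimal strings because xlsx
  numeric cells carry only 16 significant digits, which would break
  exact round-tripping of doubles.
* Table rendering floors position values below 0.001 m and velocity
  values below 0.01 m/s at those values (reporting convention);
  underlying data frames keep full precision.

## Known limitations

* With white 1 px noise, synthetic position errors at the reference
  condition (~0.01–0.02 m RMSE) are several-fold smaller than published
  laboratory values (~0.05 m), and maximum-magnitude peak picking on a
  white-noise floor inflates peak velocities of slower body parts by
  several percent on average — both signatures of the difference between
  white pixel noise and correlated human digitization error. Velocity
  RMSEs, which are noise-bandwidth-dominated, match published magnitudes
  closely (~0.18 vs 0.16–0.22 m/s).
* The kinematic template has a single impact per fall and planar chain
  geometry; angular errors induced purely by out-of-plane motion are
  milder than in real sideways falls, where limbs leave the plane in
  more complex ways.
* The pinhole camera has no lens distortion and perfect synchronization
  between board imaging and fall imaging.
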