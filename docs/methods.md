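# Methods

This note documents the models, conventions, numerical choices and known
limitations of `ankleaxis`. All angles at public surfaces are degrees; all
lengths are millimetres; internal trigonometry is in radians.

## Frames and sign conventions

The lab/reference frame is right-handed with **x = anterior** (walking
direction), **y = medial**, **z = up**, defined for a right foot;
left-foot data must be mirrored before entering the pipeline. Each bone's
technical frame coincides with the lab frame in relaxed standing, with its
origin at the marker-triad centroid, so the standing configuration is the
identity pose and the standing-trial mean marker cloud is the reference
for all pose fits.

With this frame the attitude-vector components θ·**u** are directly the
clinically signed planar angles: rotation about +y is plantarflexion
(dorsiflexion negative), about +x inversion, about +z adduction. Axis
**inclination** is asin(u_z) after canonicalizing **u** to u_y ≥ 0
(tie-breaks: u_y = 0 → require u_z > 0; both zero → u_x > 0);
**deviation** is atan2(u_y, u_x) ∈ [0°, 180°], undefined (error) for a
vertical axis. Canonicalization happens before any averaging or reporting
because an FHA direction is sign-ambiguous and flips between dorsiflexing
and plantarflexing windows.

## Pose estimation and screw decomposition

`fit_rigid_transform` solves the orthogonal Procrustes problem on centred
marker coordinates by SVD, with the reflection corrected so det R = +1
(this also handles near-planar triads). The reported residual is the RMS
of per-marker misfits; its per-trial maximum feeds the quality-control
rule.

`helical_parameters` extracts the screw axis of a rigid transform. The
rotation angle comes from atan2 of the antisymmetric-part norm (sin θ) and
(trace−1)/2 (cos θ), which is well conditioned over (0°, 180°). The axis
direction uses the antisymmetric part wherever sin θ is resolvable
(> 1e-5); only in the immediate vicinity of 180°, where it vanishes, does
the symmetric-part extraction take over (the symmetric square root limits
near-zero axis components to ~1e-8, which is why it is not used at
moderate angles). Below a caller threshold (`min_theta_deg`, default 0.1°
for raw extraction) the rotation is treated as unresolvable and the axis
undefined; the analysis-level 2° reliability gate is separate and lives in
the windowing stage. The axis translation is d = t·**u**; the axis point
closest to the origin is the least-norm solution of (I − R)s = t − d**u**.
Planar angles are attitude-vector components, not Cardan angles.

## Preprocessing defaults

| parameter | default | meaning |
|---|---|---|
| `max_gap_frames` | 10 | longest marker gap filled by PCHIP (shape-preserving cubic) per coordinate; boundary gaps stay missing |
| `lowpass_cutoff_hz` / order | 10 Hz / 4 | zero-phase (forward–backward) Butterworth on marker coordinates; the stated order is the designed order before the double pass; `None` disables |
| `contact_threshold_N` | 10 N | stance = longest episode with vertical GRF ≥ threshold |
| stance samples | 101 | markers (linear interpolation) and GRF (scaled to body weight) resampled to 0–100 % stance; poses fitted *after* resampling |
| QC rule | Q3 + 1.5·IQR | per bone, against linear-interpolation quantiles of the *other* trials' residual maxima; exclusion on strictly greater |

Resample-then-fit was chosen over fit-then-interpolate so that poses are
solved once per normalized instant directly from marker data; linear
marker interpolation avoids inventing a pose-interpolation scheme, and for
a fixed-axis motion it leaves the fitted axis exact. Gait speed is the
mean calcaneal-marker displacement between the instrumented heel strike
and the next one, divided by the elapsed time; the next heel strike is the
most negative local minimum of the foot-marker-centroid vertical velocity
after stance (kinematic event detection). The GRF is interpolated onto
stance instants without an anti-alias filter.

## Windowed FHA analysis

Windows span `window_pct` = 10 % of stance and advance by `step_pct` = 1 %
(the step is not dictated by the data model; 1 % is the default because an
11-point closed period then holds at most 11 windows, and it is
configurable). A window is *valid* when its rotation exceeds `gate_deg`
(default 2°); invalid windows carry no orientation. Period membership is a
closed interval on the midpoint (15 ≤ m ≤ 25 for dorsiflexion, 85–95 for
plantarflexion). Per-trial period means are normalized vector sums of
canonicalized window axes — not averages of inclination/deviation angles —
to avoid wrap-around and weighting artifacts. Pooled period statistics
report the grand mean, min, 5th/95th percentile (linear interpolation) and
max of the planar window increments, axial translation, rotation,
inclination and deviation.

The quasi-static-style comparison computes FHAs between a 0° and a ±5°
flexion configuration. Crossing instants are the nearest normalized
samples (no sub-sample pose interpolation; the residual flexion mismatch
is at most half the per-sample flexion change); both instants must lie in
10–30 % or both in 80–100 % of stance and at most 20 percentage points
apart. Pairs are labelled by direction (DF = −5°, PF = +5°) and by whether
the movement starts or ends at the 0° configuration.

The per-window planar increment is the attitude-vector decomposition of
the window's relative transform (not a difference of cumulative planar
angles; the two differ slightly for non-planar motion).

## Morphology axes

Section planes are defined by three seed points (configuration input
standing in for interactive picking); the plane normal must lie within 45°
of the medio-lateral axis. Vertices within `slab_mm` = 2 of the plane are
projected onto it; the profile may be trimmed along the anterior in-plane
axis (the anterior/posterior extent of the trochlea is a subjective call,
so it is exposed as configuration, not guessed); the upper envelope (most
cranial point per 0.5 mm anterior bin — below the CT pixel scale of the
source imaging, keeping dome tracing dense) makes the section trace the
articular dome. The profile is split at its most cranial point, included
in both subsets. The Taubin fit minimizes the gradient-normalized
algebraic circle distance via the smallest singular vector, near-unbiased
on partial arcs; collinear input is rejected by the leading-coefficient
magnitude. Fitted 2D centres are lifted to 3D through their planes; axes
connecting centres closer than 5 mm are rejected as ill-conditioned. The
medial and lateral planes are treated as independent (no parallelism
constraint). A convenience routine re-runs the estimate with seeded jitter
of the seed points (each displaced by a random vector of length ≤ 1 mm),
mirroring a repeated-manual-selection protocol.

Known sensitivity: three seed points on a circular arc form a triangle of
limited height, so ~1 mm of seed-point displacement can roll the plane by
several degrees about the profile chord; the oblique section of the dome
is then slightly elliptical and the partial-arc circle fit shifts its
centre. Typical inclination changes under 1 mm jitter are ~0.3–0.5°, with
single repetitions occasionally reaching ~1.5° — the same order as the
repeat-selection variability such protocols report.

## Synthetic data

The walking generator produces the structure the analysis assumes: rigid
marker triads (50 mm equilateral, tilted out of the bone planes) on a
tibia translating at gait speed and a talus rotating relative to it; a
two-marker calcaneus for gait events; and a double-hump vertical GRF.
Defaults are representative of barefoot walking of healthy adults: speed
1.45 m/s, stance 0.64 s at 240 Hz markers / 960 Hz GRF, body weight 736 N,
GRF landmarks 1.24 / 0.68 / 1.15 BW at 25 / 50 / 75 % stance, flexion
keyframes spanning −7° (dorsiflexion) to +8° (plantarflexion) (sagittal
ROM 15°, within the 11–19° range reported for skeletal ankle kinematics),
and an axis schedule running from −10° inclination (early stance) to +12°
(late stance) at 80–85° deviation.

Construction details that matter for ground truth:

* The joint rotation is built **incrementally**: each step rotates about
  the scheduled axis at the step midpoint by the amount that brings the
  sagittal attitude component onto the flexion keyframe spline (a
  per-step correction, so the planar flexion angle tracks the keyframes
  exactly without compounding composition error). Because every increment
  is exactly about the scheduled axis, a window's screw axis matches the
  schedule at the window midpoint — exactly for a constant axis, to
  within the flexion-weighted axis variation inside one window (≲ 1°
  for the default schedule) otherwise. The stored planar-angle truth is
  computed from the generated rotation matrices themselves.
* The GRF curve is a monotone cubic through the landmark points with a
  small non-zero boundary value, so the whole configured stance is
  supra-threshold and contact detection recovers the interval to one
  force-plate sample. Landmark percents on the integer grid are recovered
  exactly by the landmark extractor.
* Exactness checks use a stance spanning an integer number of camera
  frames per stance percent (e.g. 200 frames), so time normalization does
  not interpolate between frames; under that condition the noise-free
  pipeline reproduces a constant axis to < 1e-6° (in practice ~1e-12°).
* The trochlea generator lofts between a single-arc lateral profile and a
  two-arc medial profile meeting at their upper intersection, holding
  each profile pure over the outer 20 % of the width so that sagittal
  sections near the faces are exactly circular. Profiles are sampled
  uniformly in arc length at a CT-like 0.6 mm vertex spacing on both
  sides; identical sampling density means the envelope's max-selection
  noise bias is common to the medial and lateral sections and largely
  cancels in the inclination. True axes follow from the configured circle
  centres in closed form.

What the generator does **not** emulate: soft-tissue artifact (markers are
pin-mounted by assumption), pin vibration spectra (noise is i.i.d.
Gaussian per coordinate), joint translation (the synthetic joint is a pure
rotor, so axial translation d ≈ 0), asymmetric GRF shapes, multi-segment
foot coupling, and any muscle/ligament mechanics. Passing tests therefore
show that the *pipeline* recovers known kinematic and morphological
structure at realistic noise levels — not that real ankles behave like the
generator.

## Problem sizes used in the shipped checks

The packaged verification runs use: 100 random screws against the
matrix-logarithm oracle; one noise-free commensurate hinge trial; 50
seeded trials at 0.2 mm marker noise for the inclination RMSE; 100 seeded
trials for the dorsiflexion-below-plantarflexion ordering rate; one
noise-free and 20 jittered (0.3 mm) trochleae for morphology recovery,
with the jitter result summarised as the mean absolute inclination error
over the 20 seeds.

## Limitations

* The standing global frame is taken as the anatomical proxy (the 0°
  reference); no separate anatomical calibration is modelled.
* FHA spatial location is computed (axis point nearest the origin) but
  not analysed or reported in summaries.
* The C3D capture format is not read; trials are exchanged as TSV
  (bit-exact round trip) with a JSON metadata sidecar.
* Statistical inference across participants is out of scope; outputs are
  tidy tables meant for descriptive comparison and plotting.
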