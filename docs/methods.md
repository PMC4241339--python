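# Methods

This note documents the models, numerical choices and limitations behind
`osteotrack`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pipeline model

A longitudinal study consists of a day-0 post-surgery reference scan and
follow-up scans on a fixed schedule (default days 0, 7, 14, 21, 30, 35,
44, 57, 78). Each session co-scans water and air phantom tubes. The
pipeline stages are:

**HU calibration.** Raw intensities are mapped to Hounsfield units with
the two-point affine map HU(v) = 1000·(v − w̄)/(w̄ − ā), where w̄ and ā are
the mean raw intensities of the water and air tube cores. Although a
single water anchor is sometimes quoted for CT normalization, one point
cannot fix both parameters of a linear map; air is the standard second
anchor and an air phantom is scanned in every session anyway. Tube cores
are eroded 2 voxels inward from the wall to exclude partial-volume rims.
On measured (noisy) data a 5% trimmed mean guards against streaks; on
noise-free synthetic data the plain mean is exact, and the map sends
water to 0 HU and air to −1000 HU to machine precision.

**Femur extraction.** Voxels above a bone threshold (default +1200 HU)
are labeled; the largest 26-connected component's bounding box, padded
by 10 voxels, is cropped out with an adjusted origin. This isolates the
femur from the calibration tubes and defines the registration domain.

**Rigid registration.** Each follow-up scan is registered to the
*extracted day-0 reference* with a 6-DOF rigid transform
y = R(x − c) + c + t, R = R₀(a₀)R₁(a₁)R₂(a₂) (intrinsic rotations about
world axes 0, 1, 2 in that order; angles in degrees, translations in mm,
center c = the fixed volume's geometric center). The metric is mean
squared intensity difference (normalized cross-correlation selectable)
minimized with Powell's derivative-free method over a 3-level pyramid
(local-mean ×2 downsampling; initial line-search steps 2°/1 mm, halved
per level; xtol 10⁻³). Numerical choices that proved necessary:

* *Gaussian pre-smoothing* (σ = 1.5 voxels per level) of both images:
  with sharp-edged volumes the interpolation aliasing of edge voxels
  creates a pose-dependent noise floor that hides the true minimum.
* *Bone-masked metric*: the metric samples only fixed-image voxels
  within 0.7 mm of bone. Structures that are static in the scanner frame
  (bed, calibration tubes) otherwise leak into the residual through the
  animal-pose transform and bias the fit.
* *Axial sweep*: a long bone is nearly rotation-symmetric about its
  shaft, so that angle has a shallow, multi-welled profile along which
  the coarsest level drifts freely. At each finer level the current
  transform is pre-composed with trial rotations about the fixed shaft
  axis (full circle at the first refinement, ±10° later, 2° steps) and
  restarted from the best; sweeping the raw Euler angle instead would
  also tilt the shaft, because the angle parameters interact. Sweep and
  Powell alternate up to three times per level.

Non-convergence (optimizer failure or a final metric above the
identity-transform metric) is flagged, not raised.

**ROI propagation and classification.** The day-0 defect ROI voxel
centers are pushed through each day-0→timepoint transform and snapped to
the nearest voxel of the follow-up scan in its native grid, so voxel
counts stay integral, masks stay binary, and no interpolation touches
the classified intensities. Samples landing outside a scan are counted
as *unclassified* and flagged. Bands (configurable, defaults fixed):
soft/empty [−1000, +800] HU, woven [+1200, +1900] HU, compact
(> 2700) HU, each closed on its printed bounds and compact open on the
left; the two gaps are reported as the explicit unclassified fraction
rather than silently re-binned. Healing is relative to the day-0
baseline, healing(t) = 1 − soft(t)/soft(0), and X%-healing times are
linearly interpolated between scheduled scans (which is why a half-time
of day 11 is read as ~11.4 from 7- and 14-day scans). A
threshold-assisted helper (`suggest_defect_roi`: flood fill over
HU ≤ +800 from a seed, clipped to a ball) produces a starting mask meant
for manual editing; it deliberately does not attempt the final irregular
contour against the cortical surface.

## Statistics

* **Bland–Altman**: mean difference ± 1.96·SD (n−1 denominator); for
  three observers all pairs (A–B, B–C, C–A) are reported plus pooled
  limits over the stacked differences. The pooled half-width as a
  percent of the grand mean is emitted as a secondary descriptive
  column, not asserted against.
* **ICC**: from the two-way mean squares (MSR, MSC, MSE). Default
  ICC(3,1) (two-way mixed, consistency); ICC(2,1) (absolute agreement)
  selectable; single- and average-measure forms are both emitted because
  published values rarely say which was used. Cronbach's α = 1 − MSE/MSR
  (identical to the average-measure consistency coefficient) is reported
  alongside, with the F = MSR/MSE test (df n−1, (n−1)(k−1)).
* **Sample size**: n = ⌈2 + C(s/d)²⌉ with C = 7.85 encoding 80% power at
  α = 0.05; the ceiling reflects that animals are whole.
* **Two-way ANOVA + Šidák**: balanced two-group × time decomposition
  computed directly from cell means (unbalanced tables are rejected, not
  reweighted); per-timepoint contrasts are t tests on cell means pooled
  over the residual MS, adjusted by p' = 1 − (1 − p)^m with m = number
  of timepoints — the family used for per-time post hoc comparisons.
* **Dose ledger**: cumulative = per-scan dose × number of scans; the
  default protocol (1 pre-surgery control + 9 follow-ups at 11.7 cGy)
  totals 117 cGy.

## Synthetic data generator

The generator renders, directly in reconstructed image space, the
features the pipeline consumes. It makes no attempt at X-ray physics
(no projections, filtered back projection, beam hardening or scatter).

**Geometry** (defaults, mm): a hollow compact-bone cylinder (outer
radius 0.9, cortical thickness 0.25, length 8) with marrow-filled cavity
(+100 HU) along image axis 0, on an isotropic 0.116 mm grid (default
128³); a posterior longitudinal ridge (radius 0.25) emulating the linea
aspera — without it a plain cylinder leaves the axial rotation
mathematically unidentifiable, which real femoral anatomy does not; a
1.1 mm circular defect through the anterior cortex; water and air tubes
(radius 1.2, wall 0.25 at +1000 HU) parallel to the shaft, 5 mm off-axis.
The tubes are rendered in the static scanner frame: pose jitter (uniform
within configurable bounds, per timepoint, day 0 fixed at identity)
applies to the animal only, as in a real scanner bed.

**Healing model.** Defect voxels are ranked rim-first by distance from
the defect axis (ties broken by a wrapped azimuth key so partial healing
is patchy rather than one polarized arc, then by depth; the order is
total). Voxel i converts — leaves soft density — on the day its rank
quantile crosses the log-logistic filling curve
F(t) = t^k / (t^k + t₅₀^k), so F(0) = 0 (the defect is all soft the day
it is made) and exactly half the defect has converted at t = t₅₀. After
conversion a voxel becomes woven at +`woven_onset` days (default 0) and
compact at +`compact_onset` days (default 24); the stagger produces the
rise-then-fall woven transient. Presets: spontaneous healing t₅₀ = 11 d,
k = 2.9; intramedullary-reamed t₅₀ = 16 d, k = 1.35, compact onset 30 d
(shape exponents chosen so 75% conversion falls near days 16 and 36
respectively). Class HU targets sit mid-band: soft −100, woven +1550,
compact +3000. The per-voxel soft→woven→compact path is a stand-in:
longitudinal CT observes only the aggregate curves, and direct
soft→compact densification would be indistinguishable at that level.

**Acquisition model.** HU → raw via raw = water_raw + HU·(water_raw −
air_raw)/1000 (defaults 2000/1000, i.e. 1 raw unit per HU); additive
Gaussian noise on the raw scale (σ = 0 by default; 200 ≈ 200 HU is the
"moderate" condition used in tests); one seeded generator drives jitter
and noise, making series bit-reproducible. Anatomy voxels are averaged
over a 2×2×2 subvoxel grid (partial-volume rendering, emulating detector
voxel integration); voxels whose centers lie in the defect keep their
pure class HU so that classifying the true defect mask on a rendered,
calibrated volume reproduces the generative class counts exactly — the
closure property the acceptance tests rely on.

**What passing tests do and do not show.** The phantom has exact HU
plateaus, ideal phantom tubes, no beam hardening, rings, scatter, motion
blur or anatomical background (muscle, second bone, growth plate), and
its healing trajectory is spatially deterministic. Closure and recovery
results therefore validate the *software* — calibration algebra,
transform estimation and composition, ROI bookkeeping, classification
and statistics — not biological accuracy on real scans, where partial
volume at band edges, calibration drift and anatomy-dependent
registration error will dominate.

## Problem sizes

Unit tests run on compact grids (80×64×64 with a 5 mm shaft) so the
suite stays fast; the acceptance tests exercise the full default
geometry: a nine-timepoint 128³ closure run, twenty ±8°/±1 mm transform
recoveries at 128³, and healing-half-time recovery at both presets with
and without noise. Statistical oracles use small fixed tables plus a
1000-replicate null simulation.

## Known limitations

* Ingest mode expects axis-aligned NIfTI affines; oblique orientations
  and DICOM are out of scope.
* Registration assumes HU-calibrated, isotropic volumes with overlapping
  anatomy and a roughly axis-0-aligned shaft for the axial sweep
  heuristic; it is rigid only (no growth/deformation).
* The ANOVA requires balanced cells; longitudinal mixed-effects
  modeling is out of scope.
* `suggest_defect_roi` floods any sub-bone density, so without a radius
  clip it will leak through the defect into the medullary cavity; it is
  a starting mask, not a segmentation.
* BMD calibration to mg HA/cm³, trabecular morphometry (BV/TV etc.) and
  contrast-enhanced cartilage quantification are not implemented.
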