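# Methods

This note documents the measurement models implemented in `tsmm`, the
synthetic-data generator that stands in for subject data, the numerical
choices that shape the results, and the limits of what the synthetic
validation can show.

## Muscle volumetry

A label volume is an integer grid with voxel spacing `(dx, dy, dz)` in mm;
the axial axis is the slice direction. The volume of a muscle label is its
voxel count times the voxel volume — no partial-volume weighting — reported
in cm³. This matches the voxel-counting measurement model of manual
segmentation, and it makes volume exactly additive under any re-labelling
of voxels. Derived quantities:

- relative volume: `100 · V_muscle / V_total` (%), scale-invariant by
  construction;
- normalized volume: `V / (height · mass)` in cm³/(kg·m), the allometric
  body-size correction used throughout the cohort statistics.

Voxel ownership is by center: world coordinate = `index × spacing`, a voxel
belongs to a shape iff its center is inside. All four muscle labels (PS, AS,
MG, LG) must be present; a missing label is an error naming the muscle.

## Free-tendon geometry

The free tendon is measured between two landmark slices — the most proximal
slice where the calcaneus is visible and the soleus muscle–tendon junction —
taken either from landmark labels in the volume (synthetic phantoms) or from
explicit slice indices (sidecar metadata for real data); both paths are
identical downstream. Per slice, CSA = in-plane voxel count × in-plane
voxel area, **measured in the axial plane**, not perpendicular to the local
tendon direction; the obliquity correction is deliberately not applied
because the slice-wise protocol it emulates does not apply it either.
Tendon volume is `Σ CSA_k · dz`; tendon length is the summed distance
between centroids of adjacent slices (equal to the straight-line distance
when centroids are collinear). A gap in the tendon label between the
landmarks is an error listing the offending slices.

The representative "Achilles tendon CSA" is taken at mid-length: the first
slice whose cumulative centroid-path length reaches 50% of the total. This
rule is deterministic and robust to curved tendons. The CSA profile is
linearly resampled to 101 points on normalized path length (0% = calcaneus,
100% = MTJ).

Ratios are computed in consistent units: mid CSA is converted to cm² before
dividing by volumes in cm³ (yielding cm⁻¹), and CSA/(height·mass) stays in
mm²/(kg·m). The printed exponents of tendon-CSA/volume ratios in some
published tables are not unit-consistent with the corresponding mean CSA and
volume; this package always reports the unit-consistent value.

## Moment arm

A range-of-motion trial carries marker clusters on shank, foot and
ultrasound probe plus paired superficial/deep tendon edge points in the
probe frame. Frame 0 is the neutral calibration; cluster poses at every
frame are least-squares rigid fits (SVD/Kabsch, reflection excluded) against
the frame-0 marker positions, so the "shank frame" is the laboratory frame
at neutral.

The functional axis summarizes foot-in-shank motion: finite helical axes
are computed between **all pairs of poses at least 5° apart** (smaller
displacements give noise-dominated axes), the axis direction is the
rotation-weighted mean of the (sign-aligned) helical directions, and the
axis point is the least-squares closest point to all helical axes (the
minimum-norm solution resolves the along-axis indeterminacy of a pure
hinge). All-pairs averaging, rather than consecutive pairs only, is what
keeps the direction error sub-degree at realistic marker noise: at 0.5 mm
iid noise on every cluster over a 30° sweep (41 frames), the direction
error is ~0.8° median, ~90% below 1.5°, and the neutral moment arm has
≈ 2 mm SD with negligible bias. Noiseless trials are recovered exactly.

The ankle angle of a frame is defined as the rotation of the foot-in-shank
pose about the functional axis relative to neutral (rotation vector
projected on the axis direction), dorsiflexion positive, with the axis
direction canonically oriented (largest-magnitude component positive). The
protocol never fixes an operational angle definition, so this convention is
the package's own choice, self-consistent with the axis being the only
rotation model available.

Per frame, the tendon line of action is the first principal direction
through the superficial/deep edge midpoints mapped probe → lab → shank, and
the moment arm is the perpendicular (skew-line) distance between that line
and the functional axis, with a point-to-line fallback for the parallel
case. The neutral moment arm is the constant term of an ordinary
least-squares quadratic of moment arm against ankle angle, fitted over the
observed range only (≥ 5 frames, ≥ 3 distinct angles, range bracketing 0°
within 5°).

## Gait kinetics

Gait events are threshold crossings of vertical GRF at 20 N with a 50 ms
debounce; heel strikes rise, toe-offs fall, events strictly alternate. On a
treadmill, stride length = belt speed × stride time, cadence = 120 / stride
time, and step length defaults to half the stride (symmetric gait) unless
contralateral events are given.

The ankle moment is a sagittal-plane Newton–Euler reduction of the foot
segment (x anterior, y up, plantarflexion positive):

```
M_pf = [(P − C) × F]_z + [(A − C) × J]_z − I·α,   J = m(a_C − g) − F
```

with COP `P`, foot COM `C`, ankle center `A`, GRF `F`, foot mass `m` and
moment of inertia `I = m·ρ²`. For a massless foot this reduces to
`[(P − A) × F]_z` (body weight 735.75 N applied 0.12 m anterior to the ankle
gives 88.29 Nm of plantarflexion). A full 3-D inverse-dynamics model is
deliberately replaced by this planar formulation: the outcome of interest
is the sagittal plantarflexion moment, and the planar form is exactly
testable against constructed trials.

Numerical choices: forces are low-pass filtered at 25 Hz and kinematics at
6 Hz (4th-order zero-lag Butterworth) before central-difference
differentiation — conventional gait defaults, declared rather than
recovered from any protocol; the COP is not filtered (it is already a
smooth ratio of force signals, and filtering it across swing-phase
discontinuities rings into stance). Filtered forces are interpolated onto
the kinematic time base (1,900 → 190 Hz). Each cycle (heel strike to
ipsilateral heel strike) is time-normalized to 101 points; the peak is the
waveform maximum per cycle and peaks are averaged across cycles. Missing
foot anthropometrics fall back, with a warning, to mass fraction 0.0145 of
body mass, COM offset (0.06, −0.03) m from the ankle in the foot frame, and
radius of gyration 0.05 m. Peak tendon force is mean peak torque divided by
the moment arm in metres, attributing the whole plantarflexion moment to
the triceps surae.

## Cohort statistics

Mann–Whitney U is computed from midranks. With a tie-free pooled sample of
at most 25 observations the two-sided p is exact: twice the lower-tail
probability of `min(U_ab, U_ba)` under the full enumeration counting
recursion, capped at 1 (doubling the tail rather than summing both tails
beyond the observed value — a documented dialect, since packages differ).
The 25-observation cutoff covers a 14 + 7 design with enumeration cost that
is negligible. With ties or larger samples, a normal approximation with
midrank tie correction and continuity correction is used; a zero variance
(all values identical) yields p = 1.

Holm–Bonferroni is the step-down rule — sort ascending, multiply `p_(i)` by
`m − i + 1`, enforce monotone non-decreasing, return in input order — and is
**uncapped by default**, so adjusted values above 1 are reported as such
(tables in this literature print such values); `cap=True` (CLI `--cap-p`)
restores the conventional `min(1, ·)`. Families are exactly the
four-per-muscle repetitions of a measure; single tests (totals, tendon CSA,
torque) are unadjusted.

Regressions are ordinary least squares via `scipy.stats.linregress` with
R² = 1 − SSE/SST and the two-sided slope p from `t = slope/SE` on n − 2 df.
In the third report table the regressions follow the scaling-table
convention of this literature: body size, tendon CSA, peak torque and
tendon force are each regressed **on** the individual and total muscle
volumes, per group.

## The synthetic-data generator

The generator's defaults are the study conditions under which the analysis
is validated; they are fixed, not tuning knobs.

- **Cohort structure** (young n = 14, older n = 7): heights and masses are
  Gaussian per group (1.78 ± 0.10 m / 74.87 ± 12.11 kg young, 1.76 ± 0.07 m
  / 74.57 ± 15.26 kg older), rejection-sampled at ±4 SD and above physical
  lower bounds. Total muscle volume is `slope · (h·m) + ε`, slope 7.00
  (young) vs 5.95 (older) cm³/(kg·m); the volume scatter SDs (80 / 122 cm³)
  are sized so normalized volume has SD ≈ 0.60 / 0.93 cm³/(kg·m) at the
  group-mean body size. Per-muscle volumes are total × fractions
  (0.4194, 0.0883, 0.3091, 0.1832 for PS/AS/MG/LG), jittered (SD 0.02) and
  renormalized so they always sum exactly to the total.
- **Muscle–tendon coupling**: young mid-tendon CSA =
  `0.05 mm²/cm³ · V_total + 16.56 mm² + N(0, 5.5 mm²)`; older CSA is drawn
  independently of volume as N(65.54, 6.96) mm². This single switch encodes
  the young/older structural difference; no analysis module contains
  group-conditional logic.
- **Other measures**: moment arm N(46.64, 3.87) / N(43.54, 8.13) mm; peak
  torque `0.857 / 0.808 Nm per kg·m × (h·m)` plus N(0, 6.5 / 9.1) Nm; stride
  time N(1.11, 0.07) / N(1.02, 0.08) s at belt speed 1.25 m/s; tendon length
  N(50.95, 17.94) / N(45.26, 20.39) mm bounded below at 20 mm; the CSA
  profile is a quadratic in normalized length through group-specific end
  ratios. The stride-to-stride torque scatter (5% of peak in the noisy
  configuration) is a free parameter of the generator, not a reported value.
- **Randomness** is split with `SeedSequence.spawn`: one child stream per
  subject (and per trial within a subject), so enlarging a cohort never
  perturbs existing subjects, and identical config + seed reproduces
  byte-identical outputs.
- **Phantoms**: muscles are ellipsoids with semi-axes (a, 0.7a, 3a) solved
  from the target volume, rasterized by the voxel-center rule; the tendon is
  a sheared tube whose axial slices are discs of prescribed CSA, so the
  axial-plane CSA equals the prescription by construction and the centroid
  path length is the axial extent divided by cos(incline). The phantom's
  true tendon volume follows the slab model (`Σ CSA_k · dz` over its
  discrete slices), the same quantity the slice-sum measurement estimates.
  The tube center is snapped to a half-voxel x offset and voxel-center y,
  a sampling phase at which disc voxel counts are near-unbiased across
  tendon-like radii (single-slice CSA discretization error can still reach
  ~4% for unlucky radii at the 0.72 mm in-plane spacing; at the radii used
  in validation it is ~1%).
- **ROM trials**: frame 0 is neutral; the foot cluster rotates about the
  specified axis through a dorsi-to-plantarflexion sweep (default ±20°,
  121 frames), the probe drifts mildly to exercise the probe→shank chain,
  and in every frame the tendon edge points are placed so the fitted line's
  distance to the true axis equals the prescribed quadratic in the frame's
  angle, exactly, before iid Gaussian noise.
- **Gait trials**: the per-cycle plantarflexion torque target is
  `peak · sin(π x^q)²` over stance (x = fraction of stance, q ≈ 2.41 placing
  the single peak at 75% of stance ≈ 45% of the cycle). The stance foot
  translates backward at constant belt speed with zero rotation (zero
  inertial terms by construction; swing uses C² quintics), vertical GRF is a
  single arch of 1.05 body weight with a sinusoidal anteroposterior
  component, and the COP is solved per sample so the Newton–Euler moment
  equals the target exactly. Two margin strides surround the requested
  strides so filter edge effects never touch scored cycles. The
  inverse-dynamics round trip recovers the generated peak to <0.1% at zero
  noise and well within 5% at the configured noise.

### What the generator does not emulate

Real muscle shapes (statistical shape variation, inter-muscle boundaries in
contact), MR intensity and segmentation ambiguity, soft-tissue artifact
beyond iid marker noise, ultrasound image formation (edge points are
consumed as coordinates), double-support force-plate cross-talk, and
non-stationary gait. Passing the synthetic battery therefore demonstrates
correctness of the measurement and statistical machinery under the stated
geometric and statistical structure — not robustness to segmentation error
or soft-tissue artifact in real data.

## Problem sizes used in validation

The test suite and the acceptance script use: two 4-muscle phantom sets (8
ellipsoids) and three tube phantoms at 0.72 × 0.72 × 2 mm; one noiseless
121-frame ROM trial plus 30–100 noisy 41-frame trials for Monte-Carlo
characterization; 10 + 10 gait trials of 10 strides (1,900 / 190 Hz); exact
Mann–Whitney against full enumeration for all group sizes 2–8; 1,000 Holm
families and 100 OLS datasets against hand oracles; and 200 seeded
study-scale cohorts for the structural young/older reproduction. The
end-to-end pipeline demo runs 6 subjects at a coarser 1.5 × 1.5 × 3 mm
spacing, a deliberate down-scaling for a quick, self-contained demonstration.

## Known limitations

- CSA is an axial-plane measure; for strongly inclined tendons it
  overestimates the perpendicular CSA by ≈ 1/cos(incline).
- The mid-length slice rule picks a single slice; with steep local CSA
  gradients the representative CSA inherits single-slice discretization
  noise.
- The planar inverse dynamics omits frontal/transverse moments and assumes
  a single-segment foot.
- The exact rank-sum enumeration applies only to tie-free pooled samples;
  tied cohorts fall back to the tie-corrected normal approximation even at
  small n.
- Empirical power of the normalized-volume group comparison under the
  default cohort (reported by the acceptance script) is ≈ 70–75%, so any
  single cohort realization may fail to detect the group difference.
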