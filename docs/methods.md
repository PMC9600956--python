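# Methods

## The planning problem

Medial open-wedge high tibial osteotomy (mOWHTO) treats medial
unicompartmental knee osteoarthritis in varus limbs by opening a
medially based bone wedge in the proximal tibia, tilting the distal
limb into slight valgus.  Digital planning follows the Miniaci idea:
choose a target point on the tibial plateau for the post-operative
weight-bearing line (WBL, the hip-centre-to-ankle-centre Mikulicz
line), rotate the distal limb about the intended lateral hinge until
the WBL passes through the target, and read off the opening angle and
the medial gap ("wedge width") that realise the correction.

This package simulates that procedure for synthetic cohorts and asks
how the wedge width depends on two free surgical choices: the height
of the medial saw entry below the plateau (30 vs 40 mm) and the
position of the lateral hinge (5, 10, 15 mm medial to the lateral
cortical wall, labelled A, B, C).

## Limb model

The limb is a 2D frontal-plane landmark set: hip, knee and ankle
centres plus the medial and lateral plateau edge points (millimetres).
Modelling decisions:

* **Deformity apex at the knee.** The whole varus deformity is placed
  in the proximal tibia: the femoral mechanical axis is vertical and
  the ankle is rotated medially from the vertical by the mechanical
  femorotibial angle (mFTA).  This is the deformity a tibial osteotomy
  corrects; femoral bowing and joint-line convergence are not
  modelled.
* **Horizontal joint line** perpendicular to the femoral axis, with
  the knee centre at the plateau midpoint; joint-line obliquity is not
  modelled.
* The WBL fraction is the intersection parameter of the Mikulicz line
  with the infinite joint line, 0 at the medial and 1 at the lateral
  plateau edge.  A neutral limb reads 0.50; the default correction
  target is 0.55 (slight lateral overcorrection, the tip of the
  lateral intercondylar spine).
* All measures are computed from the labelled landmarks, so they are
  invariant under rigid motion and left/right mirroring (property
  tested).

## Planner

* **Entry point**: on the modelled medial cortex — vertical through
  the medial plateau edge by default; an optional flare angle tilts it
  (`cortex_flare_deg`, default 0°).
* **Hinge point**: `dist_from_lateral` medial to the lateral plateau
  edge, at `hinge_depth_mm` below the joint line.  The default depth
  of 15 mm stands in for the tip of the fibular head / proximal
  tibiofibular joint level; results are first-order insensitive to it
  (it enters the osteotomy length at < 2%).
* **Correction solve**: the distal fragment (the ankle centre — the
  only distal landmark that affects alignment) is rigidly rotated
  about the hinge; the correction angle α is found by Brent
  bracketing/bisection on the post-rotation WBL fraction
  (tolerance 1e-13 rad on α; every plan is re-verified to hit the
  target fraction within 1e-8).  Rotation about the hinge, not the
  knee centre, matches opening-wedge mechanics.
* **Wedge width**: the chord swept by the entry point,
  `w = 2 L sin(α/2)` with `L = |entry − hinge|`.  The alternative
  (perpendicular gap) differs by O(α²) at these angles and is not
  offered.  A saw-kerf allowance can be added (`saw_kerf_mm`,
  default 0).
* `apply_wedge` inverts the chord identity to simulate *executing* a
  given wedge at a different hinge than planned and reports the
  achieved WBL fraction and mFTA.

### What the geometry implies

Because the ankle sits ~360 mm from the hinge, a 10 mm hinge shift
changes the required α by well under 0.1°; the wedge difference
between hinge positions is therefore driven almost entirely by the cut
length, `Δw ≈ 2 sin(α/2) ΔL ≈ 1.2 mm per 10 mm` at a typical α ≈ 7°.
Two consequences, both asserted in the test suite:

* at a fixed height, the wedge *decreases* as the hinge moves medially
  (hinge A > B > C), because the cut shortens while α stays put;
* executing a wedge planned for a medial hinge (C) at a more lateral
  hinge (A) under-corrects: the same gap over a longer cut opens a
  smaller angle.

Changing the entry height 30 → 40 mm changes the cut length by ~3%
and the wedge by ~0.3 mm: the medial saw point is nearly free, the
hinge is not.

## Synthetic cohort

The generator reproduces a 55-knee varus cohort characterised by
printed summary statistics:

| quantity | distribution | default |
|---|---|---|
| varus angle | fixed integer-degree frequency table | 3°×15, 4°×10, 5°×4, 6°×8, 7°×2, 8°×5, 9°×6, 12°×3, 13°×1, 17°×1 (mean 327/55 = 5.945°) |
| plateau width | truncated normal (±3 sd) | 79.5 ± 6.9 mm |
| femoral length | truncated normal (±3 sd) | 475.0 ± 34.5 mm |
| tibial length | truncated normal (±3 sd) | 372.6 ± 30.2 mm |
| side | Bernoulli | right 31/55 |

Choices: varus angles are *assigned* from the table (default "exact"
mode), not resampled, which pins the cohort mean exactly and removes a
variance source; "sample" mode draws from the same table for
arbitrary n.  The continuous variables are drawn independently — no
joint covariance is available — and truncated at ±3 sd to exclude
non-physical limbs (this shrinks the realised plateau-width sd by
~1.3%, still within the tested 2% convergence band).  Integer varus
values are treated as exact, not as bin centres.  Side and age-like
metadata have no geometric effect beyond mirroring.

What the generator does **not** emulate: femoral deformity,
joint-line obliquity, osteophytes, varus–geometry correlations, and
measurement error of the underlying landmarks.  Passing cohort-level
tests therefore show that the *planning geometry* behaves as derived,
not that real radiographic cohorts would produce identical tables.

The observer-noise overlay (`simulate_raters`) models
`observed = true + rater_bias + noise` with a once-per-rater bias
(default sd 0.15 mm) and i.i.d. cell noise (default sd 0.3 mm,
sub-millimetre digital-caliper precision; 0.15° for angles).  With
between-knee wedge sd ≈ 4 mm this yields ICC(A,k) ≈ 0.99, i.e. the
"(almost) perfect" regime expected of software-assisted measurement.

## Experiment and statistics

`run_conditions` plans all 6 conditions × n knees (330 plans by
default; solver failures are recorded per row, never aborting a run).
Summaries: per-condition mean/sd; all 15 pairwise mean differences
with the share of knees whose per-knee |Δw| reaches the 2 mm
clinical-relevance threshold; Pearson correlations of wedge width
with femoral/tibial length (expected weak: wedge width is driven by
varus angle and plateau width).

The statistics battery mirrors standard practice for such studies:

* one-way ANOVA across the six condition groups (deliberately
  unpaired, although the knees are paired, to mirror the study design
  being emulated; the pairwise ≥2 mm rate does use pairing);
* Tukey HSD on the same groups (studentized range, df = N − k,
  simultaneous 95% CIs), via scipy;
* ICC, two-way model, absolute agreement, average of k = 2 ratings —
  McGraw–Wong ICC(A,k) = (MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n) —
  implemented from the mean squares, with the F-based confidence
  interval of the same convention (single-rating bounds stepped up by
  Spearman–Brown).  Intra-rater tables use sessions as k; inter-rater
  tables use session means per rater.  Estimates are clamped to
  [−1, 1]; zero between-subject variance raises.
* Landis–Koch grading with half-up rounding to two decimals before
  binning, so the printed bin edges (0.20 vs 0.21) tile the range.

## Numerical choices and degenerate inputs

* Degrees at every interface, radians internally.
* Already-corrected limbs (WBL at/lateral to target): α = 0 with a
  warning, or an error in strict mode.
* No root in [0°, 45°]: explicit no-solution error.
* Identical-data ANOVA/Tukey return F = 0 / p = 1 instead of NaN.
* Outputs are serialised at fixed 4-decimal precision so a (config,
  seed) pair reproduces byte-identical CSV/JSON.

## Problem sizes

The default experiment is 55 knees × 6 conditions; replication layers
(acceptance script, multi-seed tests) use 20–25 independently seeded
cohorts, enough to make the across-seed standard error of every
reported mean < 0.05 mm.  A full 25-seed replication takes well under
a minute on one core.

## Known limitations

* 2D only: no tibial slope, no biplanar cut geometry, no hinge
  fracture mechanics, no implant.
* The wedge is the chord at the entry point; real gap measurement on
  radiographs may follow the cortex instead (sub-0.1 mm difference at
  these angles).
* The hinge-depth stand-in (15 mm) is a convention, not a per-patient
  measurement.
* Reliability tables are synthetic by construction; they validate the
  ICC machinery and the noise model, not human observer behaviour.
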