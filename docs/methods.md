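# Methods

## Enhancement maps

The three-timepoint series is summarized voxelwise as early/late percent
enhancement and their ratio (SER).  Maps are stored in percent so that
thresholds carry their conventional units.  Two numerical decisions are not
determined by the defining formulas:

- **Baseline validity floor.**  Fat-suppressed voxels have near-zero
  baseline signal and the PE quotient there is noise.  Voxels with
  `S0 ≤ floor` are marked invalid and excluded from every downstream mask.
  The default floor is 5 % of the volume's 98th intensity percentile: it
  rescales with arbitrary scanner units, sits clearly above the suppressed-
  fat noise floor, and clearly below enhancing-tissue baselines.  It is
  configurable as an absolute intensity.
- **Non-positive late enhancement.**  `SER = PE_early/PE_late` is undefined
  when the late signal returns to or below baseline.  Such complete-washout
  voxels are the extreme of the behavior SER is designed to flag, so the
  default policy assigns them an infinite sentinel: they pass every finite
  SER threshold.  An alternative `exclude` policy marks them invalid
  instead.  Non-enhancing voxels (`PE_early ≤ 0`) get SER = 0 and never
  pass a positive SER threshold.

## Volume of interest

The VOI is the intersection of two rectangular ROIs back-projected from
maximum-intensity-projection images along two different axes, minus
declarative exclusion regions (axis-aligned boxes, or 2D polygons rasterized
in a projection plane and extruded along its axis).  Exclusions are applied
after the intersection.  Coordinates are 0-based half-open `[lo, hi)` voxel
indices in array order; rectangles are clipped to the volume and rejected if
empty after clipping.  Any two distinct axes are accepted; nothing in the
construction privileges a particular anatomical plane.

## Functional tumor volume

FTV at `(PE_t, SER_t)` applies, strictly in order: the PE threshold
(closed, `≥`), a connected-component filter, and the SER threshold
(closed, so `SER_t = 0` gates out nothing with non-negative SER).  Choices:

- **Connectivity.**  26-neighborhood in 3D by default (the most permissive
  standard choice); 6 and 18 are configurable.  The filter runs in 3D.
- **Minimum cluster size.**  Speckle removal needs a size; the default of
  8 voxels corresponds to ≈ 0.01 cc at the 0.7 × 0.94 × 2.0 mm voxel size
  used throughout, and is configurable.
- **Percent change.**  `(later − baseline)/baseline × 100`, negative =
  shrinkage.  Cells with zero baseline FTV yield missing percent-change
  predictors at that cell only; a missing early-treatment visit yields an
  all-missing ΔFTV₂.

FTV surfaces are non-increasing along both threshold axes by construction
(raising a threshold can only remove voxels; splitting a component can only
shrink or delete it) — this is asserted as a test invariant, not enforced.

## Survival model

Each grid cell is tested with a univariate Cox proportional-hazards model,
maximized by Newton's method with step-halving on the Efron-corrected
partial likelihood (the tie correction used by default in the standard R
survival tooling).  Reported per cell: β and the hazard ratio `exp(β)` per
*scale* units of the predictor, Wald 95 % CI `exp(β ± 1.96·se)`, and the
likelihood-ratio p against β = 0 (χ², 1 df).

- **Predictor scaling.**  "Per unit change" is ambiguous for percent-change
  predictors whose natural spread is tens of points.  Defaults: 10
  percentage points per unit for ΔFTV₂/ΔFTV_f, 1 cc per unit for FTV_f;
  always configurable and always recorded alongside results.
- **Degeneracy guard.**  Small subsets produce monotone likelihoods
  (β̂ → ±∞, explosive CIs).  Cells with |β| > 15 on the scaled covariate or
  se > 10 are flagged, excluded from optimum selection, but kept in the
  matrices (and hatched in heat maps).  The bound is applied to the scaled
  coefficient because that is the quantity whose divergence the guard
  detects; at these magnitudes the distinction from any other scaling
  convention is immaterial.
- **Optimum selection.**  Lowest LR p among converged, non-degenerate
  cells; exact ties broken by higher HR, then lower PE_t, then lower SER_t.
- **Multiple testing.**  No correction across the 198 cells, matching
  standard practice for this exploratory sweep; the number of fits and the
  naive count of p < 0.05 cells are always reported together.
- **Numerics.**  The covariate is mean-centered before fitting (β is
  invariant); Newton runs to a 1e-12 step tolerance with step-halving, and
  runaway iterations stop early and flag the cell.  Non-convergence is
  reported on the result, never raised.

## Heat maps

PE_t on the y axis, SER_t on the x axis.  Hazard ratios clamp to
[0.9, 1.2] on a blue→red scale; p-values clamp to [0.001, 0.1] on a
red→blue scale with log10 color spacing (a linear map would spend almost
the whole range on p > 0.01; the choice is recorded in each figure's JSON
sidecar).  Per-cell rasters are the default for test determinism.  The
renderer returns the exact clamped matrices plotted, so tests assert on
numbers rather than pixels.

## Synthetic cohorts

The generator emulates the structure of a neoadjuvant DCE-MRI study:
64 patients by default with subtype probabilities 21/15/11/17 (of 64) for
HR+/HER2−, HER2+, TN and unknown; visits at baseline, early treatment
(missing completely at random for 20 % of patients) and pre-surgery; voxel
size 0.7 × 0.94 × 2.0 mm.  Volumes are 32 × 32 × 16 voxels — several
hundred tumor voxels at study voxel size, small enough that replicated
cohort-scale experiments stay cheap.

Each patient has an ellipsoidal tumor (base radius 7–11 mm, mild
anisotropy) inside a fixed parenchyma ellipsoid on a fat background.
Voxelwise kinetics by tissue class: fat enhances negligibly; parenchyma
enhances moderately (PE ≈ 35 %) and persists (SER ≈ 0.7); tumor voxels are
a per-patient mixture of a *background* enhancing component (high PE, SER
centered at 0.65) and a *washout* component (PE centered at 118 %, SER at
1.35 — both above the default true thresholds), with the washout fraction
uniform on [0.05, 0.95].  Patient-level kinetic means vary substantially
(e.g. washout PE sd 25 between patients vs 10 within); this heterogeneity
is what makes neighboring threshold cells imperfect surrogates for the
true cell, so that threshold recovery is falsifiable rather than trivial.
Post-contrast volumes invert the map definitions
(`s_early = s0(1+PE/100)`, `s_late = s0(1+(PE/SER)/100)`), giving exact
round trips when noise is off.  Tumors shrink across visits by per-patient
residual volume fractions (radii scale with the cube root).

**Survival ground truth.**  Event times are exponential with hazard
`h0·exp(β·z/scale)` where `z` is the active predictor — final FTV by
default — computed *through the actual pipeline* at the true threshold
pair (100 %, 1.0).  Because the hazard uses the pipeline's own value of
`z`, re-running the pipeline reproduces the generating covariate exactly
at the true cell, and every other cell sees an error-prone version of it.
Final FTV is the default active predictor because, with visit-invariant
kinetics, a percent-change predictor is nearly threshold-invariant (the
threshold survivor fraction cancels in the ratio), which would make
recovery structurally impossible.  Defaults `β = 0.5` per 0.25 cc,
`h0 = 0.004`/month, a 96-month administrative horizon and exponential
dropout at 0.003/month give roughly 40–55 % of the cohort an event — an
association strength representative of the significant threshold regions
this method is meant to detect.  Censored patients carry the time to their
last follow-up.

**What the generator does not emulate:** MR physics (coil inhomogeneity,
k-space artifacts, motion between timepoints), irregular tumor shapes and
infiltrative margins, spatially correlated kinetic noise, informative
censoring, and treatment-regimen effects.  Passing recovery tests
therefore shows the *pipeline* is correct and the *design* identifiable
under clean conditions; it does not certify performance on clinical data.

## Validation experiments

- **Oracle equivalence:** FTV agrees exactly (integer voxel counts) with a
  plain triple-loop + flood-fill oracle on random instances up to 16³.
- **Null calibration:** with survival independent of imaging (β = 0), the
  cell-averaged rejection rate at p < 0.05 over 100 replicates at n = 200
  sits near 0.05, and default-cell p-values are KS-uniform.
- **Coefficient recovery:** the mean Cox estimate at the true cell over
  100 replicates is within ±0.1 of the generating slope.
- **Threshold recovery:** the sweep's min-p cell lands within one grid
  step of the true pair in well over 70 % of replicates at n = 200.
  Recovery replicates simulate baseline and final visits only, since the
  early-treatment visit does not enter the final-FTV predictor.

## Known limitations

- The Cox stage is univariate by design; no multivariable adjustment,
  time-varying covariates or competing risks.
- The VOI stage replaces interactive ROI drawing with declarative
  specifications; there is no automatic lesion detection.
- No motion correction or co-registration between timepoints is performed;
  inputs are assumed aligned (affines are checked, voxels are not warped).
- Monotone-likelihood flagging uses fixed bounds rather than a formal test
  (e.g. Firth correction is not implemented); flagged cells are reported,
  not repaired.
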