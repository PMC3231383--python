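# Methods

## The measurement being emulated

A vehicle drives at constant speed past a row of garden trees. Two
sensors share a clock: a multi-layer automotive laser scanner (0.25°
angular resolution) that accumulates a side-view point cloud, and a
vertical line spectrometer with a 44.4° opening angle, 659 pixels, and
123 spectral channels spanning 397–1,086 nm. The 10 outermost pixels view
a Spectralon™ white panel mounted on the vehicle, so every exposure
carries its own illumination reference. Trees are classified per
specimen: first coniferous vs deciduous (the *separation* task, all
specimens), then by species (specimens of identified species with at
least five representatives).

## Synthetic scene model

The generator produces the statistical structure this analysis depends
on, not photorealism.

**Crown geometry.** Conifers are uniform-density cones (apex up). The
height pdf of a uniform cone is 3(1−h)², so the mean normalized height is
1/4 and P(h_N > 0.5) = 0.125 — returns concentrate low. Deciduous trees
are a thin trunk cylinder plus a uniform ellipsoid crown centred at
normalized height 0.70 with vertical semi-axis 0.25: P(h_N > 0.5) ≈ 0.97
for the crown. These are the simplest shapes that reproduce the habits'
separability by height-ratio features. Tree height is uniform on a
species range (roughly 1.5–11 m across the default garden); the point
count is point density (default 60 pts/m³) times crown volume, minimum
20.

**Spectra.** Each species has a deterministic leaf-like reflectance curve
(green bump near 550 nm, red edge near 700 nm, NIR plateau) with
deciduous canopies brighter in the NIR than conifers, plus a smooth
species-specific ripple. Channel centers are linearly spaced over
397–1,086 nm (~5.65 nm); named wavelengths resolve to the nearest
center.

**Illumination.** All noise is multiplicative lognormal:

| parameter | default | role |
|---|---|---|
| `frame_sd` | 0.5 | per-frame factor on *all* pixels; cancels under panel normalization |
| `directional_sd` | 0.35 | per-(frame, tree) factor on targets only; survives normalization |
| `spectral_sd` | 0.15 | per-pixel, per-channel measurement noise on targets |
| `shaded_reference_prob` | 0.03 | frames whose targets are darkened by `shade_factor` = 0.12 while the panel stays lit |

With these defaults the single-pixel reflectance of one tree varies by
well over a factor of two across draws, matching the severity of
directional-lighting variation in side-view surveys. The shaded-reference
events reproduce the occasional near-black normalized spectra seen when
the panel is sunlit but the crown shaded.

**Geometry and coverage.** The trajectory is a straight line at 4 m/s,
trees at 8 m stand-off, frames at 2 Hz, sensor at 2 m height, pixel
elevations spanning −5° to +39.4°. Tall near trees exceed the top of the
opening, so their upper points never receive spectra — the spectral
coverage truncation present in real data. Pixels between laser returns of
the same crown are treated as seeing the crown too (3-pixel dilation),
since a crown is a continuous surface; where two trees compete for a
pixel the nearer one wins.

**Effect knobs.** `shape_effect` mixes each species' crown profile with a
common neutral profile (full-height ellipsoid centred at 0.5);
`spectral_effect` shrinks every reflectance curve toward the
specimen-weighted grand mean. At 0 the corresponding class signal
vanishes, enabling null experiments. The analytic habit gap in
P(h_N > 0.5) is exposed as `GardenConfig.shape_margin()` and validated
against a configured minimum (default 0.3).

**What the generator does not emulate** — and hence what passing tests do
not show about field data: leaf/branch geometry and BRDF (noise is purely
multiplicative), multi-echo returns, occlusion between neighbouring
crowns (only pixel ownership is contested), georeferencing error, and
phenology. Synthetic class differences are cleaner than real ones, so
absolute accuracies on synthetic scenes overstate field performance; the
pipeline's comparative statements (fusion vs single sensor) are what the
simulations are for.

## Fusion

Overlap is tested first along the driving direction — a time window on
the shared clock, default half the frame interval (0.25 s ≈ ±1 m at
4 m/s) — then vertically: the point's elevation angle from the frame pose
must fall in the pixel's angular interval widened by half the matching
footprint (default 0.25°, the scanner's angular resolution; the beam
divergence is an alternative and both are configuration). Matched pixels
are normalized by the channel-wise **mean** of the 10 reference pixels
(mean rather than median, for linearity) and averaged per laser point,
across frames. Frames whose reference signal is non-positive in any
channel raise an error naming the channel and are skipped during bulk
fusion. Specimens with zero fused spectra stay in structural-only
analyses and are dropped, with a logged warning, from analyses that need
spectra.

## Features

34 structural features of the per-specimen height distribution, in
registry order: PR(h_N<0.33), PR(0.33<h_N<0.67), PR(h_N>0.67); eight
decile bands PR(0.1<h_N<0.2) … PR(0.8<h_N<0.9); nine thresholds
PR(h_N>0.1) … PR(h_N>0.9); skewness and kurtosis; hq10…hq90; Max, Mean,
CV. Plus 123 spectral features: per-channel means over the specimen's
fused points.

Numerical conventions (each validated against an independent brute-force
oracle):

- h_N = (z − z_min)/(z_max − z_min) with the specimen's own extremes;
  degenerate (flat or single-point) specimens are an error.
- One-sided ratios are strict, bands half-open [lo, hi); with continuous
  heights ties have probability zero, so the choice matters only for
  constructed inputs. The middle third is computed as the complement so
  the three coarse ratios partition to 1 within float addition.
- Moments are population moments; kurtosis is the raw fourth
  standardized moment (normal ≈ 3); excess kurtosis is kurtosis − 3 if
  needed.
- Quantiles interpolate linearly between order statistics.
- hq, Max, Mean and CV use heights above the base (z − z_min); this
  keeps every feature invariant under vertical translation, and under
  scaling of heights-above-base only hq/Max/Mean scale.

## Classification protocol

Features are scaled to [−1, 1] by per-feature min/max (constant features
map to 0). The default is **global** scaling — scale once, then
cross-validate, the classical SVM recipe — with a leakage-safe
**per-fold** mode available that refits min/max on each training fold.

The classifier is an RBF-kernel SVM with one-vs-one multiclass voting and
no class weighting (unweighted training reproduces the bias toward
well-represented species that the protocol is known for). For each
feature subset, (C, γ) are tuned by 5-fold seeded stratified inner CV
over a coarse grid, C ∈ {2⁰, 2⁵, 2¹⁰} × γ ∈ {2⁻⁷, 2⁻³, 2¹}, spanning the
orders of magnitude of the full LibSVM-guide grid (available via
`ClassifierSpec.full_grid()`); whether tuning is per subset or fixed
(`tune="none"`, C = 2⁵, γ = 2⁻³, the grid center) is configuration —
per-subset is the default, fixed parameters are used in the large
simulation sweeps for tractability. Ties break toward the smallest C,
then the smallest γ. An LDA reference runs the identical evaluation
without tuning.

Evaluation is leave-one-out cross-validation: n models, each trained on
n−1 specimens; the confusion matrix (rows predicted, columns reference)
accumulates the held-out predictions. Overall accuracy is
100·trace/total; user accuracy is the diagonal over the row sum,
producer accuracy over the column sum; undefined (zero-sum) entries are
NaN. Display rounding is one decimal, half-up; internal values stay full
precision.

Searches: exhaustive over all singles and unordered pairs of a pool; the
best-performing fraction (default 10%, nominal cutoff ⌈fN⌉ with all ties
at the cutoff included, so the realised fraction can exceed the nominal
one); quadruples as the Cartesian product of the selected structural and
spectral pairs; greedy forward selection over four iterations, locking
the best extension each round (taken even when it does not improve —
a fixed number of rounds is run). Ranked results order ties
lexicographically by feature names and tied winners are reported as a
set, never as one arbitrary choice.

**LOOCV null behaviour.** On class-uninformative features with balanced
classes, LOOCV accuracy sits *below* 1/k: the held-out specimen's class
is always the training minority, so any majority-defaulting fit is wrong
on every such fold. This pessimistic bias is a property of the protocol,
not a defect; the null tests therefore assert the one-sided no-skill
property (mean accuracy not exceeding chance beyond Monte-Carlo error)
rather than equality with 1/k.

## Problem sizes used in the tests and the acceptance script

Unit and property tests run on small generated scenes (4–6 species, 12–42
specimens). The combinatorial identities use the real pools (34 features
→ 561 pairs, 123 channels → 7,503 pairs; 73×754 = 55,042 and 62×786 =
48,732 quadruples; realised selections 13.0%, 11.1%, 10.0%, 10.5%). The
fusion-recovery experiment runs 10 scenes of a 6-species × 7-specimen
garden with thinned pools (20 structural features, 30 channels),
fixed-parameter SVMs, and 40 subsampled quadruples per scene — sizes
chosen so the whole suite completes in minutes on one CPU while leaving
the compared quantities (mean selected-pair vs mean quadruple accuracy)
stable across seeds. The null experiment uses 200 seeded replicates of a
balanced two-class, 40-specimen, single-noise-feature design.

## Known limitations

- The exact spectrometer frame rate and overlap footprint of the original
  instrument are unknown; both are configuration with documented
  defaults.
- Per-subset tuning on the full table (tune, then LOOCV) mirrors the
  classical protocol but lets the inner CV see the held-out specimen;
  the per-fold scaling mode mitigates the analogous leakage for scaling,
  and a fully nested tuning mode would be the next step.
- Quadruple means in the large sweeps are estimated from a seeded
  subsample when the product set is large.
- The synthetic garden's species differences are parametric and cleaner
  than nature's; absolute synthetic accuracies are not field estimates.
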