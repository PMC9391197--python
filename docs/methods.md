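# Methods

This note documents the statistical machinery, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Digitization template

The packaged scheme (`toemorph/data/default_scheme.yaml`) fixes 19
anatomical landmarks and 13 curves. Landmarks 1–2 mark the toe base, 3–4
the proximal pad boundary, 5–6 the widest pad points, 7–8 the distal pad
boundary, 9 the claw base; 10–19 mark the left/right edges of five focal
lamellae in distal-to-proximal pairs. Eight curves outline the toe
(anchored on consecutive outline landmarks 1-3-5-7-9-8-6-4-2) and five
trace lamella free edges. Curves are digitized with 10 points whose
endpoints duplicate their anchors; stripping those leaves 8 semilandmarks
per curve and 19 + 104 = 123 points. The outline-curve anchoring order is
isolated in the scheme file so an alternative template can be supplied
without code changes. Landmark indices are 1-based at every interface,
matching anatomical usage.

`SCALE=` in TPS files is read as **mm per pixel** (pixels × scale = mm).
Dialects differ on this; the convention is stated in `tps_io` and applied
uniformly. Records with neither a scale nor a fallback dpi are dropped
(with a logged reason) rather than kept unitless, because the linear
measurements require millimetres. Coordinates are stored exactly as read
(tpsDig's bottom-left origin); no y-flip is applied, and all downstream
mathematics is orientation-agnostic.

## Alignment

GPA centers each configuration, scales it to unit centroid size, and
rotates it to the evolving consensus with the closed-form 2-D proper
rotation; the consensus is re-estimated and re-scaled each round until the
mean consensus displacement falls below `tol` (default 1e-6, dimensionless
Procrustes units; default `max_iter` 100). Reflections are never fitted:
chirality is handled by explicit anatomical mirroring of right-side toes
about the configuration centroid's vertical axis, which keeps landmark
numbering anatomically meaningful.

Sliding runs after initial convergence, up to 5 passes (one joint linear
solve per specimen per pass). The tangent at each semilandmark is the chord
between its curve neighbors (anchors included at curve ends); coincident
neighbors freeze that point for the pass. The sliding target is the
evolving consensus, re-estimated after each pass, and the bending-energy
matrix is rebuilt from it. The solve minimizes a convex quadratic whose
value at zero displacement equals the current energy, so energy cannot
increase within a pass (a numerical-safety check reverts the update in the
rare event rounding violates this). After sliding, specimens are
re-centered, re-scaled and re-rotated, restoring unit centroid size to
1e-8. Scaling to unit centroid size (rather than tangent-space projection,
which is not applied) keeps "shape only" literal; at the shape variances
involved here the difference is negligible.

The final sample is rotated to a canonical frame (consensus major
principal axis vertical, sign fixed by a shape-intrinsic rule), making the
result independent of input ordering up to `tol`.

## Inference

**Procrustes ANOVA.** Flattened aligned coordinates (n × 246) are
regressed on the design with treatment-coded factors. Type-II SS per term:
each main effect is adjusted for the other main effect, the interaction
for both mains; the F denominator is the full-model residual mean square.
Type-II SS do not partition the total SS in unbalanced designs — the
per-term R² values are reported against the total SS but only sum to one
in balanced/orthogonal designs. Significance by RRPP with 999 permutations
by default (residuals of the term's reduced model permuted; the same
permutation set serves all terms; p = (count + 1)/(n_perm + 1)). The Z
effect size is the observed F standardized against the permutation F
distribution. Seeds are recorded in every results object.

**Disparity** is Procrustes variance Σ‖rᵢ − r̄_g‖²/n_g of the residuals of
a shape ~ municipality model, compared between habitats by permuting
habitat labels. This realizes "disparity adjusted for region" concretely;
other covariate-adjustment conventions exist and would shift values
slightly.

**CVA** first reduces to PC scores (retained dimensions: enough axes for
95% variance, capped at n − g − 1; both exposed as parameters), then
solves eigh(B, W) for between- and pooled-within covariances in score
space. Axes are scaled to unit pooled within-group variance, so group
separations are in within-group standard deviations (Mahalanobis-like).
"Percent variation captured" by a CV axis is the variance share of the
data projected on the unit-norm axis mapped back to shape space. The
100-draw label-randomization null (group sizes preserved) is the only
meaningful yardstick for CVA separation; the observed-vs-null-max verdict
is reported alongside null mean and sd. Note the separation magnitude
depends directly on the retention rule: retaining more dimensions inflates
both observed and null separations together.

**Allometry** regresses shape on log size (centroid size, measured area,
or body length) through the same RRPP machinery and reports Pearson
correlations of PC1–PC3 with log size.

**Linear statistics.** Welch (unequal-variance) t-tests throughout, with
ln transforms for lengths/areas/ratios and √ for lamella counts;
back-transformed CIs are the inverse-transformed interval bounds. The GLM
ANOVAs are Gaussian linear models with type-II tests (via statsmodels).
The ICC is the one-way random-effects decomposition with the
unbalanced-design coefficient; ICC = among/(among + within).

The landmark-polygon area closes the toe outline distal of LM3/LM4 through
the claw base (shoelace formula, absolute value, with a simplicity check).
It deliberately differs from a digitized toepad area, which extends
proximally to the nearest phalangeal joint; the two live in separate
columns and are never conflated.

## Synthetic-data model

The generator draws from the study design: urban/forest × five
municipalities, 13–20 specimens per cell by default (or an explicit
total spread evenly). Habitat-level template means are the published group
means — pad width 1.86/1.69 mm, pad length 3.61/3.20 mm, proximal segment
7.01/6.63 mm, lamella spacing 0.17/0.15 mm, lamella count 22.44/21.87
(urban/forest). The distal segment (2.1/2.0 mm) is not pinned by any
published number and is exposed in the parameters.

Lengths are lognormal: a shared per-specimen log-size factor
(σ = 0.125) plus per-trait residuals, moment-matched so raw-scale means
equal the cell means and raw-scale sds match the published ones (width
sd ≈ 0.28, length ≈ 0.45; lamella-height residual σ = 0.156, back-computed
from its published confidence interval). The shared factor induces the
width–length correlation (~0.85) implied by the published ratio CIs —
without it, ratio tests would be far noisier than the study's. Proximal
and distal sds are not published; the pad-length coefficient of variation
is assumed. Lamella counts are rounded normals whose mean shifts with the
drawn pad length (1.4 lamellae/mm), so count differences ride mostly on
pad length, matching the reported GLM pattern (length significant, habitat
marginal). Municipality offsets are fixed ±3% multiplicative factors on
all lengths — purely isometric, so they structure the linear measurements
but vanish under Procrustes alignment. The "measured" pad area is
1.026 × width × length with lognormal noise; the single factor reproduces
both published habitat area means.

Each toe is built as a deterministic template (vertical midline, bulged
outline curves, evenly spaced lamella rows), bent by a constant-curvature
map (cross-sections rotated by curvature × arc position; midline arc
length preserved exactly) with tip-deflection sd 0.12 rad by default —
the specimen-preparation nuisance that dominates PC1 — and perturbed by
0.02 mm iid Gaussian digitization noise per coordinate; curve endpoints
stay snapped to their noised anchors, as a digitizer snaps them. Sides are
assigned at random and right-side toes stored pre-reflected so ingestion's
mirroring is genuinely exercised. Everything is reproducible from one
seed, including byte-identical TPS export.

What the generator does **not** emulate: real outline curvature detail
(bulges are smooth and symmetric), between-habitat differences in variance
(disparity), non-uniform digitization error, damaged or partially
flattened toes, and municipality-specific shape (not just size) structure.
Tests passing on this generator therefore demonstrate the statistical
machinery — calibration of permutation tests, sign recovery of calibrated
effects, artifact reproduction — not fidelity to every feature of real
toe images.

## Problem sizes and numerical choices

- Calibration suites run 200 replicate datasets of n = 150 (type-I error
  of the ANOVA habitat term and GLM interaction term) and 200 replicates
  of n = 246 (sign recovery of the five group contrasts); the calibration
  ANOVA uses 119 permutations per term, which makes the 5% level exactly
  attainable ((c+1)/120), and skips sliding, which cannot affect a null
  rejection rate.
- Anchor-coincidence tolerance for stripping is 1e-6 mm (synthetic data
  snap exactly); for hand-digitized data pass a looser tolerance
  (~0.02 mm) — endpoints farther than the tolerance warn but still strip.
- Degenerate sliding tangents freeze the point for that pass; the
  restricted solve uses a least-squares (min-norm) solution, so rank
  deficiencies cannot crash a pass.
- TPS bending-energy kernel is U(r) = r² log r² on the consensus; duplicate
  reference points and collinear references raise errors naming the
  offenders.
- Permutation p-values use the (+1)/(n+1) convention and never equal zero.
- Rounding in reports follows field practice (2 decimals mm, 3 decimals
  ratios); stored tables keep full precision.

## Known limitations

- 2-D landmarks only; no missing-landmark estimation, no 3-D sliding.
- The disparity estimator (residual Procrustes variance) is one of several
  conventions for covariate-adjusted disparity.
- CVA separation magnitudes are convention-dependent (retention rule and
  within-group scaling); only comparisons against the built-in
  randomization null are interpretable.
- The GLM battery assumes Gaussian errors on the transformed scales;
  lamella counts are treated as continuous after the √ transform.
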