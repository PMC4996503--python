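# Methods

`onhmorph` implements BMO-referenced morphometry of the optic nerve head
(ONH) and an objective classification of glaucomatous discs into
Nicolela's four phenotypes — focal ischemic (FI), myopic (MY), senile
sclerotic (SS) and generalized enlargement (GE). This note records the
model, the numerical choices, what the synthetic data emulate, and the
known limitations.

## Geometry

**Inputs.** One eye is described by (a) up to 24 marked Bruch's membrane
opening (BMO) edge points from 12 radial B-scans — two per scan — and (b)
a segmented inner limiting membrane (ILM) height grid, by default 512×256
samples over a 6×6 mm en-face area. Heights are in µm, increasing toward
the vitreous. Left eyes are mirrored about the vertical axis into
right-eye orientation on ingest (an exact involution), so "temporal"
is always +x.

**Base and reference planes.** The base plane is the total-least-squares
plane through the BMO points (perpendicular residuals, SVD of the centred
cloud; z is converted to mm so residuals are isotropic). The choice of
perpendicular rather than z-only residuals matters only at large tilts and
is the natural convention for a plane "drawn through" 3-D marks. The
reference plane (RP) is parallel to the base plane, a configurable height
(60–180 µm, default 120 µm) anterior to it. All depth-like quantities are
measured perpendicular to the base plane, not along the scanner axis.

**Disc boundary.** The BMO marks are projected onto the base plane,
expressed in an in-plane frame (e₁ = horizontal, e₂ = vertical, CCW from
anterior), sorted by angle about their centroid, and densified by linear
interpolation of the polar radius r(θ) to 1° steps (360 vertices). Radius
interpolation — rather than straight chords between marks — reconstructs a
circular opening sampled at 24 marks to within 0.01% area, where an
inscribed 24-gon would be 1.1% low; for openings with corners it rounds
them, which is the right bias for anatomical openings. Two marks at the
same angle, or a self-intersecting ordering, raise an error advising
re-marking.

**Cup boundary.** The signed field d(x, y) = perpendicular distance from
the ILM point above (x, y) to the RP is evaluated at every grid node;
marching squares with linear interpolation extracts its zero level set.
Among closed contours enclosing an ILM-below-RP region whose interior
meets the disc polygon, the largest by area is the cup, clipped to the
disc polygon (the rim cannot be negative). No below-RP node inside the
disc ⇒ empty cup; a below-RP region inside the disc that touches the grid
edge ⇒ "cup truncated by scan area" error.

**The 20 parameters.** Disc/cup/rim areas (shoelace; rim = disc − cup);
vertical/horizontal disc diameters (full extents through the disc centroid
along the frame axes); linear and area C/D ratios (clamped to [0, 1]) and
R/D area ratio = 1 − C/D; maximum and area-weighted mean cup depth (grid
nodes inside the cup, measured from the **reference plane**, which
guarantees non-negative depths; the datum is configurable in principle but
this one makes "cup" and "depth" refer to the same surface); six sector
R/D averages on the HRT sectors (T 315–45°, TS 45–90°, NS 90–135°,
N 135–225°, NI 225–270°, TI 270–315°), computed per 1° ray as
(disc radius − cup radius)/disc radius with the cup radius clamped to
[0, disc radius]; the rim decentering ratio
(rim area TS − rim area TI)/(rim area TS + rim area TI) with sector rim
areas from the same 1° ray decomposition (½Σ(d² − c²)Δθ), so all sector
quantities are mutually consistent; the horizontal disc angle
atan(|Δz|/‖Δxy‖) of the temporal–nasal BMO chord (the horizontal-scan
pair when present, else the extreme-x marks); and the disc height
difference |temporal − nasal| of the perpendicular BMO→ILM distances
(root-solved along the plane normal).

Degenerate cases: an empty cup reports zero depths and C/D ratios, unit
R/D everywhere, and an `empty_cup` flag; a cup covering the whole disc
reports zero rim, R/D = 0 and decentering 0 with a `degenerate_rim` flag.

**Resolution.** The 1° ray step and the marching-squares linear
interpolation are matched to the 512-pixel raster; both are configurable.
On smooth phantoms, parameters computed on 256×512 and 512×1024 grids
differ by < 0.5%.

## Synthetic phantoms

The generator exists to provide analytic ground truth, so fidelity to
closed forms was preferred over anatomical realism. A phantom is an
elliptical BMO ring (24 points at the 12 radial-scan angles) on a base
plane sheared by tan(tilt) about the vertical axis, plus an ILM consisting
of a flat rim shelf (default 250 µm above the plane) and a paraboloid cup
of given depth and radius fraction, optionally decentred vertically and
carved by a Gaussian angular notch (σ = 25°) that can extend the cup to
the disc edge. i.i.d. Gaussian height noise (seeded) is added last. For
this family every one of the 20 parameters has a closed form (the cup
level set is an ellipse; the paraboloid's area-weighted mean depth is
exactly half its maximum for any angular gain), so noise-free
quantification can be required to agree with truth within 1% — and does.

The four phenotype presets solve the paraboloid equations so that the
noise-free phantom lands on the published per-type means at the 120 µm RP:
average cup depth 330/309/257/437 µm and disc angle 3.30/6.99/2.95/2.77°
for FI/MY/SS/GE, with C/D area ratios 0.63/0.66/0.71/0.75. FI carries an
inferotemporal notch, MY the strong tilt and vertical-oval disc, SS the
shallow saucer, GE the large deep round cup.

What the phantoms do **not** emulate: OCT speckle, vessel shadows,
peripapillary atrophy, undermined (overhanging) cup walls, or segmentation
failures. Passing tests on phantoms therefore validate the geometry and
statistics pipeline, not robustness to real segmentation artefacts.

## Reference-plane selection

For each candidate height the pipeline computes the Pearson correlation of
rim area with cpRNFLT (and MD) overall and per type, and an OLS of
rim area on cpRNFLT plus the disc-type factor (FI reference level, tested
as a single 3-df block with a type-II partial F). The selected height
maximises the overall correlation among heights where the type block is
non-significant (α = 0.05); ties go to the smallest height, and if no
height qualifies the global argmax is returned with a warning. The "CV"
column reported alongside the regression is the residual coefficient of
variation, 100·RMSE/mean rim area (declared in output headers since the
quantity is otherwise ambiguous). p-values are two-sided; no multiplicity
correction is applied across the five heights.

The synthetic sweep cohort makes the optimum identifiable by
construction: cpRNFLT = 40 + 55·rim(120 µm) + ε, ε ~ N(0, 3 µm), and
MD = −14 + 9·rim(120 µm) + N(0, 2.5 dB), with rim taken from the analytic
truth. Because the paraboloid's rim-area slope with respect to RP height
is proportional to f²ab/depth, log-normal per-eye dispersion of cup depth
(σ = 0.40) and cup radius fraction (σ = 0.08) decorrelates rim areas
measured at other heights from the 120 µm rim area, and the type-mean
depth differences make the type block significant away from 120 µm — the
same two signatures the selection rule looks for. At 18 eyes/type these
choices give the correct height in ≈95% of cohorts; they are the
generator's definition of the study conditions, set by a grid-free design
analysis and not adjusted afterwards.

## Classification

**Stepwise selection** is the classic Wilks'-lambda stepwise discriminant
procedure: at each step every excluded candidate's partial F
(Λ-ratio transform, df (g−1, n−g−p)) is computed given the entered set;
the largest-F candidate enters if p < α_enter (default 0.05); then any
entered feature whose removal partial F has p > α_remove (default 0.10)
is removed; iterate to a fixed point. The procedure is deterministic given
the column order (exact ties go to the earlier column); candidates exactly
collinear with the entered set (R/D area = 1 − C/D area is such a pair)
are skipped by a zero-tolerance rule; constant features are excluded with
a warning. The published analysis calls this a "stepwise regression"; with
a categorical outcome it is implemented as stepwise discriminant analysis,
and since the original entry/removal thresholds were not reported, both
are exposed as options.

**LDA.** Class means with a pooled within-class covariance (divisor
n − g), ridge-stabilised before inversion by inflating each diagonal
element by a relative 1e-8 (the features span µm² and pure-ratio scales,
so an absolute trace-based ridge would perturb the small-variance
coordinates by percents — enough to move posteriors visibly).
Posterior probability of each type is the normalised Gaussian likelihood ×
prior; priors default to equal across the four types, matching the
balanced 18/type training design (empirical priors are an option). The
highest posterior decides the type; exact ties are broken FI < GE < MY <
SS and flagged. Validation reports the confusion matrix, per-type and
overall identification rates, one-vs-rest sensitivity/specificity,
rank-statistic (Mann–Whitney, ties ½) AUC per type from the posteriors,
and unweighted Cohen's kappa.

**Feature-level cohort generator.** Classifier experiments need labelled
DiscParameters vectors at realistic per-type distributions. Independent
sampling of the 20 printed marginals is impossible (it violates
rim = disc − cup, R/D = 1 − C/D, max ≥ avg) and, as measured, caps
achievable accuracy near 72% — inconsistent with the published 80%
identification rate, 0.73 kappa and 0.84–0.93 AUCs. The printed marginals
underdetermine the joint distribution; the missing degree of freedom is
the within-type covariance. The sampler therefore uses a latent-variable
design: a per-eye *cupping severity* factor loads on the C/D ratios
(0.95/0.88) and average cup depth (0.94) and negatively (−0.60) on the six
sector R/D averages, which also share a per-eye rim factor (0.75); the
maximum cup depth is the average times a type-typical shape ratio
(1.70/1.82/1.86/1.54 ± 0.095, from the printed max/avg means); the disc
angle is log-normal with the printed moments; decentering is coupled to
the TS−TI sector contrast; disc area, diameters and height difference are
independent. Loadings keep every marginal mean/SD at its printed value
(up to clipping) and were calibrated once so that the full pipeline —
stepwise + LDA trained on 18/type — reproduces the published validation
performance (design-time check: median identification 78%, median kappa
0.71, near-Bayes rate 89% with unlimited training data); they were frozen
before any acceptance measurement. This is a deliberate modelling
judgement: within-type correlation of this strength is also the only way
the published partial F-to-enter values (6.5–24) can exceed the marginal
four-group ANOVA F of the same parameters (≈0.3–7).

**Stepwise validation experiment.** A separate controlled problem draws
six informative features carrying orthogonal-contrast class-mean patterns
with noncentralities in the published strong partial-F range (6.5–24) plus
14 i.i.d. standard-normal noise features. Note a structural property of
stepwise selection at α_enter = 0.05: each null candidate's partial F is
exactly F-distributed, so the chance that at most one of 14 noise features
ever clears the threshold is 0.95¹⁴ + 14·0.05·0.95¹³ ≈ 0.85, independent
of implementation — about one cohort in six admits two or more noise
features. Expectations on "no noise enters" rates should be set
accordingly.

## Reproducibility

Agreement between paired quantifications of the same eyes is summarised by
ANOVA-based single-measure ICCs: ICC(2,1) — two-way random effects,
absolute agreement — for two raters, and ICC(3,1) — two-way mixed,
consistency — for two sessions of one rater. Forms are explicit parameters
because the two conventions differ precisely in whether a systematic
between-rater offset counts against agreement (ICC(2,1): yes). Variance
components (subject, rater, error) are reported unclipped; a table with no
between-subject variance raises rather than returning a meaningless value.
Single-measure rather than average-measure forms are used because a
clinical reading is a single measurement. Simulated reproducibility
experiments jitter the BMO marks (σ ≈ 20 µm) and redraw ILM noise, which
mimics re-marking variability but not between-visit acquisition
differences. One phantom-specific artefact to expect: the phantoms have no
true between-eye variance in the disc height difference (its generative
value is zero for every eye), so its simulated ICC hovers near zero — a
property of the phantom, not of the estimator, and the reason the ICC
guarantee in the tests is asserted for areas and depths.

## Problem sizes and tolerances

Defaults used by the test and acceptance workloads, chosen as the
package's own simulation design: full-raster phantoms (256×512) where
closed-form agreement is asserted; 128×128 grids for cohort simulations
(convergence to the full raster is < 0.5% on smooth phantoms); 18
eyes/type for training-style cohorts and 15/type for validation, matching
the balanced published design; 100 seeds for distribution-level claims.
Numerical tolerances: 1% against analytic truth (grid discretisation),
1e-10 against algebraic oracles, 1e-12 for serialization round-trips.

## Limitations

* The cup datum and the diameter convention follow the declared choices
  above; other software may use the base plane as depth datum or maximal
  rather than centroid extents, so absolute values are comparable only
  under matching conventions.
* Sector quantities assume the disc contour is star-shaped about its
  centroid and the cup reachable by rays from it; grossly decentred cups
  fall back to furthest-crossing radii.
* The synthetic cohorts reproduce published summary statistics, not
  patient data; correlations printed in the original study (e.g. r = 0.625
  at 120 µm) are properties of that cohort and are not reproduced
  numerically here.
* Eyes whose BMO cannot be marked (large peripapillary atrophy, ~10% of
  discs in practice) are out of scope: the package starts from given
  segmentations.
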