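# Methods

This note documents the models, estimators and numerical choices behind
`neurocurve`, and what the synthetic-cohort tests do and do not
establish about real traced data.

## Curvature estimation

A neurite trace is an ordered 3D polyline with per-node radii, in μm.
Curvature — the reciprocal of the local radius of the curve, in μm⁻¹ —
is estimated discretely by the Menger construction: the curvature of
the unique circle through three consecutive points,

    κ(p₁, p₂, p₃) = 4 · Area(p₁p₂p₃) / (|p₁p₂| · |p₂p₃| · |p₃p₁|).

This is the direct discrete realization of "reciprocal of the curve
radius": exactly zero for collinear points, exactly 1/R for any three
points on a circle of radius R, and convergent to the smooth curvature
as sampling densifies. The cross-product form is numerically benign;
agreement with an independent least-squares circumcenter solve is at
the 1e-13 level over random triplets (the test suite enforces 1e-8).

**Resampling.** Manual tracing places nodes irregularly, and triplet
curvature estimates are sensitive to the sampling interval. Each trace
is therefore resampled to uniform arc-length spacing before evaluation.
The default step is **1.0 μm**, configurable: large enough to smooth
node-placement jitter at sub-μm voxel pitches, small enough to resolve
curvature on the 0–2 μm⁻¹ scale where neurite tortuosity lives. Exact
interior points are obtained by linear interpolation along the
piecewise-linear path; the original endpoints are always preserved, so
the final spacing may be shorter than the step. Radii are linearly
interpolated in arc length. Halving the step moves smooth-fixture
summaries (circle, helix) by under 1%, which is the package's working
definition of step-converged.

**Per-neurite summaries.** Curvature is evaluated at every interior
resampled node (no one-sided endpoint estimates). The per-neurite
summary curvature is the arc-length-weighted **mean** of the point
curvatures — one value per neurite, the natural length-normalized
choice when each neurite contributes one observation to the case
distribution. Median and maximum are selectable alternatives
(`summary="median"|"max"`), since the distribution tail is of interest
in its own right. The per-neurite radius is the arc-length-weighted
mean of the interpolated node radii. A trace shorter than one
resampling step cannot yield an interior triplet; it is flagged
excluded and counted, never silently dropped.

## Unit of analysis and cohort statistics

All group inference operates on **one value per case**. Per-neurite
summaries are pooled over every dataset belonging to a case (pooling is
associative, so dataset boundaries are irrelevant), then reduced to the
case mean, sample SD (n−1), median, max, mean radius and total length.
Group differences (mean curvature, curvature SD, mean radius) use the
two-sided Welch *t*-test with Welch–Satterthwaite degrees of freedom on
the case-level values — 8 vs 8 at the default cohort shape — not on
pooled neurites, whose thousands of pseudo-replicates would fabricate
precision. A guard test verifies that inflating one case's neurite
count a hundredfold leaves the *t* statistic unchanged.

Group mean curvature is reported under two conventions: the unweighted
mean of per-case means (primary, consistent with the case-level unit of
analysis) and the neurite-pooled mean (cross-check; weights cases by
neurite count). With balanced neurite counts the two coincide.

When both groups have zero variance on a parameter, the Welch statistic
is undefined; the package raises a `DegenerateVarianceError` rather
than returning ±∞, because in practice this signals a misconfigured
synthetic cohort. Shapiro–Wilk (scipy's implementation) checks the
normality of case-level curvature SDs. Regressions are Pearson *r*
with two-sided *t*-distribution p-values (n−2 df) plus an OLS line:

* curvature SD vs age, fitted on **controls only** by default — the
  aging trend is defined by the non-disease population, and disease
  cases are then read against it (an all-cases fit is a flag away);
* case mean curvature vs hallucination score, fitted on **all cases**
  by default (controls sit at score 0 by construction; excluding them
  is a flag away);
* case mean curvature vs chlorpromazine-equivalent dose, reported
  descriptively over the medicated cases as a specificity check.

No multiple-testing correction is applied; the report records the
number of tests performed so a reader can apply their own.

Per-case histograms use right-open bins [k·w, (k+1)·w) from zero,
default width 0.1 μm⁻¹, as relative frequencies over included
neurites; the mass at or beyond 0.8 μm⁻¹ is reported separately
because the high-curvature tail is where group differences
concentrate.

## Skeleton file formats

The PDB-dialect mapping is: one chain per trace; nodes as consecutive
ATOM records with residue sequence number = node order; x/y/z columns
read directly as μm (no ångström conversion); node radius in the
occupancy column (2 decimals); constituent kind in the residue name
(NEU/SOM/OTH); traces delimited by TER records (chain ids cycle and are
cosmetic); dataset label on a TITLE record. Tracing tools differ in
which spare column carries the radius, so `PdbDialect` exposes the
radius column and a coordinate unit scale. Values unrepresentable in
the fixed columns (coordinates beyond ±999.999/9999.999, radii that
would round to 0.00) raise at write time instead of truncating.
Round-trips are exact at column precision (0.0005 μm coordinates,
0.005 μm radii) and idempotent byte-for-byte.

SWC files are read as parent-pointer forests and split into unbranched
traces at branch points and at structure-type changes; the junction
node is duplicated into each child trace so that every trace is an
independent open curve (curvature is a per-unbranched-segment
quantity). Cycles and orphan parents are errors. Node ids are
renumbered on reading, so identity is positional, not nominal.

## Synthetic cohorts

The generator exists because per-neurite trace data of this kind are
rarely shareable; it produces cohorts with the statistical structure the
analysis is designed to detect, with every generating parameter
recorded in a per-case `truth` object.

**Neurite model.** A discrete worm-like chain with node spacing h
(default 1 μm): after each step the tangent is rotated about a random
perpendicular axis. The rotation is parametrized through the *chord*
variable θ′ ~ Rayleigh(σ), turning by θ = 2·arcsin(θ′/2), which makes
the realized Menger point curvature exactly θ′/h — i.e. Rayleigh with
mean √(π/(2·h·Lp)) for persistence length Lp = h/σ². This keeps the
tangent autocorrelation at the worm-like-chain law E[cos θ] = 1 − h/Lp
≈ exp(−h/Lp) while making the expected measured curvature available in
closed form and unbiased at any curvature magnitude (a naive
vector-perturbation scheme under-shoots by 5–15% at high curvature,
which matters when group ratios are the quantity under test). Each
neurite draws a target curvature κ from its case's distribution and is
grown with Lp = π/(2hκ²).

**Cohort structure (defaults).** 8 cases per group, 200 neurites per
case, trace lengths uniform on 20–60 μm. Controls: case mean curvature
~ Normal(0.36, 0.03) μm⁻¹; across-neurite SD declining linearly with
age, 0.25 − 0.002·age μm⁻¹ (ages uniform on 25–75, lognormal
case-level jitter ×e^{N(0,0.1)}, floor 0.02). Disease cases multiply
the mean by **1.6** and the SD by 1.6, thin radii by ×0.85 (control
node radii lognormal, mean 0.6 μm, CV 0.25), and mix in a minority
tail component: 15% of neurites drawn from Normal(1.0, 0.15) μm⁻¹,
with the bulk component's mean solved so the case target mean is
preserved. The tail reproduces long-tailed disease histograms without
moving the bulk mode. Per-neurite targets are Gamma-distributed within
each component. Hallucination scores are affine in the case target
mean curvature (slope 12 per μm⁻¹ about 0.33 μm⁻¹) plus Normal(0, 2)
noise, truncated at zero; controls are exactly zero. The noise SD is
calibrated so the emergent case-level curvature–score correlation is
r ≈ 0.8, the strength of link the generator is meant to emulate.
Antipsychotic dose is lognormal and independent of structure, so the
dose regression is null by construction. A single global seed expands
into per-case substreams via `SeedSequence` spawn keys: cohorts are
bit-reproducible and adding cases leaves existing cases untouched.

**What the generator does not emulate.** Tracing noise and node
misplacement, branch topology (every synthetic trace is unbranched),
somata, spatial correlations between neighbouring neurites, absolute
neurite counts of any real study, and any image-level artifact. Tests
passing on synthetic cohorts establish that the estimator and the
statistics recover known generating structure at realistic sample
sizes — not that any particular biological claim holds in real tissue.

## Verification strategy and problem sizes

* Geometry: 1000 random triplets against the independent circumcenter
  oracle (1e-8 relative); circle (R = 5 μm → 0.2 μm⁻¹) and helix
  (a = b = 1 μm → a/(a²+b²) = 0.5 μm⁻¹) closed forms within 1%; exact
  zero on collinear input; scale covariance (κ → κ/s, length → s·L)
  and rigid-motion invariance as property tests.
* Statistics: Welch results agree with a hand-coded
  Welch–Satterthwaite formula to 1e-10 on 100 random small samples;
  textbook fixture {1,2,3} vs {2,3,4} gives t = −1.2247, df = 4;
  Pearson ±1 on exact linear data; null p-values uniform by KS test.
* Calibration/power simulations run at reduced sizes chosen for test
  runtime while keeping the checked property well-powered: null
  calibration over 500 zero-effect cohorts (8+8 cases, 20
  neurites/case — p-value uniformity is size-free); ratio recovery
  over 100 cohorts (60 neurites/case; the 1.6× multiplier must land in
  [1.4, 1.8] in ≥ 95); age-slope sign recovery in ≥ 95% of 200
  replicates at n = 8 controls (30 neurites/case).
* End-to-end: simulate → write → read → measure → analyze is
  deterministic under a fixed seed (summary JSON serialized at 10
  significant digits to be platform-stable), and the measure stage
  never touches clinical metadata.

## Known limitations

* Menger curvature at a fixed 1 μm step is a banded estimator: genuine
  sub-μm wiggles are smoothed away, and curvature approaching 2/step
  (the equal-chord geometric ceiling) saturates. For data with
  qualitatively different tortuosity scales the step should be
  revisited alongside the histogram range.
* Per-neurite radii enter only as arc-weighted means; no taper or
  varicosity analysis.
* The supplementary-workbook reader accepts the two layouts described
  in its docstring (long format, or sheet-per-case with the first
  numeric column); curvature-only workbooks yield NaN radius/length
  summaries, and group tests on those fields will refuse to run.
* Welch tests at n = 8 + 8 have limited power for small effects; the
  package reports effect sizes (group means, both conventions)
  alongside p-values for that reason.
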