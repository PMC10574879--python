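# Methods

## Profile model and curvature

A tubercle profile is an ordered planar polyline in microns, apex up, whose
first and last points are the base points; the baseline is the chord through
them. The profile is modelled as a polynomial Bézier curve
C(t) = Σⱼ Bⱼ,ₙ(t) Pⱼ, fitted by linear least squares in the Bernstein basis
with both endpoints interpolated. Data points are initially parameterised by
normalised chord length; the parameterisation is then improved by up to ten
foot-point sweeps (one Newton step per point toward its orthogonal
projection on the current curve, followed by a re-fit). With refinement the
fit reproduces exactly representable curves to machine precision, and a
degree-5 fit of a noise-free 120° circular arc recovers the arc's curvature
to 0.01%.

Signed curvature is evaluated analytically on the hodographs,
κ = (x′y″ − y′x″)/(x′²+y′²)^{3/2}, and reported as |κ|·10³ with κ in µm⁻¹:
a value of 20 corresponds to an osculating circle of radius 50 µm, 100 to a
radius of 10 µm. A curvature profile samples |κ| at n uniform parameter
values (default n = 200, minimum 50). The summary statistics are the
maximum, the arithmetic mean over uniform-t samples, and their ratio. The
uniform-t mean matches the abscissa of the usual published curvature plots;
an arc-length-weighted mean is available behind a flag so the averaging
convention is auditable. For near-circular profiles the two agree to ~2%.

Numerical safeguards:

- **Cusps.** Where the first derivative's magnitude falls below 10⁻⁹ of the
  chord length the sample is flagged NaN with a warning and excluded from
  the max/mean statistics — never silently zeroed.
- **Degenerate fits.** A curve of too low a degree can only follow a very
  sharp apex by collapsing its parameterisation into a near-cusp, which
  sends the fitted curvature to meaningless values (10⁵ and beyond) even
  though the positional residual is small. The diagnostic is the minimum
  parametric speed divided by arc length: clean fits score ≳0.3, degenerate
  ones ≲0.1. `analyze_tubercle` therefore escalates the degree (default 5,
  up to 10) until this ratio exceeds 0.15; `fit_bezier` keeps plain
  fixed-degree behaviour for callers who want it.
- **Endpoint bias.** With only positional clamping, the curvature of a
  least-squares fit is weakly constrained at the extreme ends of the
  parameter range; for flat-ended profiles a degree-5 fit can overshoot the
  true end curvature substantially (the profile maximum then sits near the
  base rather than the apex, as is also seen in some real flat tubercles).
  Raising the degree reduces the bias; it is documented rather than hidden
  because the max-curvature statistic of wide, low profiles inherits it.

Default degree 5 balances noise smoothing against shape fidelity for
single-bump profiles; `degree="auto"` raises the degree from 2 until the
residual RMS falls below 0.5 µm (or degree 10), which is useful for
compound bumps with secondary excrescences.

## Measurements

W is the distance between the base points, H the maximum perpendicular
distance from the base chord (identical to the vertical for upright
profiles; the printed precision of reference tables cannot discriminate the
two conventions). The steepness index is S = 200·H/W — the typography of
the defining equation is ambiguous in print, but only this reading
reproduces every published slope value (e.g. 200·15/87 = 34.5). Reported
values follow the reference-table conventions: W, H as measured, S and the
curvature statistics to one decimal.

## Image extraction

The extractor emulates the classic manual protocol: convert to 8-bit
grayscale, threshold (fixed value or Otsu; scikit-image), trace component
boundaries (largest first), and read a single-valued profile y(x) — for
every integer pixel column the topmost boundary point, so overhangs are
flattened with a log message. Only contour points on horizontal pixel edges
(integer x) are used per column; vertical-edge points would leak the
neighbouring column's top onto steep flanks and cost ~2 px of accuracy
there. The scale comes from a user-measured ruler of known physical length
(µm per pixel = physical/pixels); automatic scale-bar detection is out of
scope. Optional 3-px moving-average smoothing damps the pixel staircase
before fitting. Round-trip accuracy on noise-free renderings is ≤0.5 px.

`segment_tubercle` crops a tubercle between two base x-positions and applies
the rigid motion that maps the base chord onto the x axis, preserving all
distances and curvatures.

## Synthetic data generator

The generator emulates the two tubercle morphologies of tuberculate seed
coats and is the test bed for every downstream stage. Shapes (baseline on
the x axis, span W, peak H):

- **rounded** (rugose class): raised cosine y = H·(1+cos 2πx/W)/2.
- **acute** (echinate class): raised cosine sharpened by an exponent,
  y = H·((1+cos 2πx/W)/2)^q with q = 10W/(π²H), which pins the apex
  osculating radius at W/20 while keeping the flanks curved. (A literal
  smoothed triangle was rejected: its straight flanks have zero curvature,
  which would push the acute class's *mean* curvature below the rounded
  class's — the opposite of what is observed on real echinate seeds.)
- **compound**: rounded bump plus an off-centre secondary bump (default
  amplitude 0.35·H, quarter-width), emulating secondary excrescences.
- **arc**: circular arc of given radius and span (default 120°), the
  calibration target for the curvature unit convention.

Additive Gaussian y-noise (default sd 0.5 µm, roughly sub-pixel at typical
image scales) is applied with a per-profile seed.

Species-level datasets draw per-tubercle (W, S) as independent log-normals
and derive H = S·W/200. This parameterisation was chosen because width and
height co-vary on real seeds: independent (W, H) draws at the published
class CVs would inflate the slope CV to ~44–57% against the observed
25.8/52.2. Class defaults are the published pooled group conditions —
rugose W 83.3 µm (CV 24.8%), S 49.8 (CV 25.8%); echinate W 72.0 µm
(CV 23.1%), S 124.3 (CV 52.2%) — giving implied mean heights of 20.7 and
44.7 µm. All draws descend deterministically from a single dataset seed.

What the generator does and does not emulate: population means of W, H and
S match the published group conditions by construction, and the rugose vs
echinate contrasts of all six variables reproduce the published sign
pattern with comfortable significance at n = 50/group. The *curvature
magnitudes*, however, are dictated by the idealised shapes (a raised cosine
at rugose dimensions has apex curvature ≈59·10⁻³ µm⁻¹ where real rugose
tubercles average ≈41), so passing tests demonstrate correct pipeline
behaviour and correct orderings, not that real tubercles are raised
cosines. Likewise, at the full published class dispersions the S > 100
rule classifies only ~80% of draws correctly (three published echinate
species themselves have mean S below 100); the ≥95% separability quoted for
the render→extract→measure fixture holds at that fixture's 10% CVs.

## Statistics

Per-species summaries report N, mean, CV% and min/max per variable. The CV
uses the sample (n−1) standard deviation — the convention that reproduces
the published summary rows (population SD does not). One-way fixed-effects
ANOVA is computed from explicit sums of squares; two all-identical groups
return F = 0, p = 1 by convention, and a Welch variant is available behind
a flag (off by default, matching common statistical-package defaults).
Tukey HSD uses the studentized-range distribution with the Tukey–Kramer
standard error for unbalanced designs; both routes are cross-checked
against independent implementations in the tests. The compact letter
display uses insertion–absorption: two groups share a letter iff they are
not significantly different; letters are assigned in ascending order of
group mean ("a" = smallest), ties broken alphabetically.

Pooled group statistics (seed type, subgenus) weight per-species means by
tubercle count, which equals pooling the raw records exactly.

## Clustering

Species are clustered on their trait-mean vectors (default: all six
variables; a maximum-curvature-only variant is supported) with Euclidean
distances and Ward's minimum-variance linkage, heights on the distance
scale (the Ward.D2 convention). No standardisation by default — none is
used in the published analysis this mirrors — but a z-score flag exists
because the six variables have heterogeneous scales and the slope variable
otherwise dominates. The dendrogram is deterministic given the matrix;
export is Newick with branch lengths equal to merge-height differences, and
plots colour leaf labels by subgenus (Behenantha red, Silene blue).

On the packaged 31-species means, the two-cluster cut isolates a pure
high-curvature group of five Behenantha species; most other Behenantha
species sit interleaved with subgenus Silene at that cut depth, so subgenus
enrichment on the high-curvature side is qualitative, not a clean
two-cluster split.

## Known limitations

- Overhanging tubercles lose their overhang in the single-valued profile.
- Endpoint curvature of low-degree fits is biased for flat-ended profiles
  (see above); comparisons across datasets should hold the degree fixed.
- The generator's shapes are idealised; curvature magnitudes transfer to
  real data only approximately.
- Several cells of the packaged reference tables are internally
  inconsistent in the original source (a printed ratio that does not follow
  from its printed numerator and denominator, per-tubercle values outside
  their species-level ranges, pooled rows that no weighting of the
  per-species rows reproduces). They are packaged verbatim; tests that
  touch them report the discrepancies explicitly.

## Problem sizes used in the tests

Simulation-based tests use 50 tubercles per class for the group-contrast
recovery, 1000 replicates for the type-I error calibration, 20 rendered
bumps for the extraction round trip, and ≤8-point matrices for the
exhaustive Ward oracle; these sizes give stable verdicts for the properties
they check while keeping the default suite fast.
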