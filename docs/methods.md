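# Methods

## Data model

A geometry table holds one row per substructure hit, identified by a
refcode-like structure id and a 1-based fragment index (a structure can
contain several hits), and one typed column per descriptor. Descriptor
kinds drive the statistics: `linear` (distances in Å, non-periodic angles
in degrees), `circular` (torsions, period 360° by default), `integer`
(grouping labels), `categorical` (free text). Missing data is an empty
cell on disk and NaN in memory; no statistic ever treats a missing cell as
zero. Rows can be hidden: hidden rows stay in the table but are excluded
from selections, grouping, pooling and every downstream statistic.

On disk a table is CSV (RFC-4180 via the standard `csv` module) or TSV
with a mandatory header; `_id`, `_frag` and `_hidden` are reserved column
names, and descriptor kinds travel in a `<name>.kinds.json` sidecar.
Floats are serialised with Python's shortest-repr and re-parsed with
`float()`, so write→read round-trips are bit-identical (pandas' fast CSV
float parser is deliberately bypassed on read for this reason).

Filtering is expression-driven (`"D <= 2.5 and HAL == 1"`), a conjunction
of per-descriptor cut-offs; the range comparator is inclusive on both
ends, and rows missing a tested descriptor are excluded. Grouping
partitions the visible rows by an integer descriptor. Pooling of
topologically equivalent columns concatenates them column-major (so
per-value provenance is deterministic; order is irrelevant to every
downstream statistic), dropping missing cells and hidden rows.

## Circular statistics

For angles θᵢ in degrees: C = (1/n)Σcos θᵢ, S = (1/n)Σsin θᵢ,
R = √(C²+S²), μ = atan2(S, C). Circular variance V = 1−R, circular
standard deviation σ = deg(√(−2 ln R)). Skewness b = (1/n)Σ sin 2(θᵢ−μ)
and kurtosis k = (1/n)Σ cos 2(θᵢ−μ) are the uncorrected second
trigonometric moments about μ; the bias-corrected variants
b₀ = ρ₂ sin(μ₂−2μ)/(1−R)^{3/2} and k₀ = (ρ₂ cos(μ₂−2μ) − R⁴)/(1−R)²
(ρ₂, μ₂ from the doubled angles) are exposed under distinct field names so
the two conventions are never confused. The circular median is the data
point minimising mean shortest-arc deviation, computed exactly in
O(n log n) with sorted prefix sums; ties break to the smallest angle.

Conventions fixed here: all interfaces take and return degrees (radians
are internal only); mean directions are reported on [−180°, 180°) with
−180° canonical for the seam, so wrapping is unambiguous; R < 10⁻¹² marks
the mean direction undefined (antipodal data) rather than returning a
noise-driven angle.

## Histograms and the cone-angle correction

Bins are half-open [eᵢ, eᵢ₊₁) with the final bin closed; out-of-range
values are excluded and counted, never clipped. Polar histograms bin
wrapped angles uniformly over [−180°, 180°).

Two correction methods are provided for D—H⋯A angle histograms on
[0°, 180°]. `midpoint-sine` divides each bin count by sin of the bin
midpoint — the textbook rule, kept as the literal default for fidelity —
and refuses bins whose midpoint sits at 0° or 180° where it is singular.
`solid-angle` divides by the exact cone measure cos θ_lo − cos θ_hi, is
finite up to the boundary, and is what the Monte-Carlo acceptance check
uses. Both rescale the corrected weights to preserve the total count, so
raw and corrected histograms share a y-scale (a pure-shape normalisation;
the choice is cosmetic and does not affect mode positions or ratios).

## PCA

Eigendecomposition (`numpy.linalg.eigh`) of the covariance matrix of the
centred columns; correlation mode additionally divides by column standard
deviations and refuses zero-variance columns by name. Default mode is
covariance when all chosen columns share units (the equal-unit torsion
case), correlation otherwise. Circular columns default to `unwrap`:
each value is re-expressed within ±period/2 of its column's circular mean
before centring, since raw torsions straddling ±180° inject spurious
variance into a linear analysis; `raw` mode is available to mirror direct
use of −180…180 values. Rows with any missing value are dropped listwise
and counted, never imputed. Eigenvalues are clipped at zero and sorted
non-increasing; the sign of each loading column is fixed by making its
largest-magnitude entry positive, so output is deterministic across
platforms. n ≤ p is recorded as a rank-deficiency warning on the result.

Outlier flagging measures Euclidean distance in the first k components
from the nearest user-declared cluster centre (from the origin when none
are declared); automatic cluster detection is deliberately out of scope.

## Inference

Association matrices are computed on pairwise complete cases (not
listwise) with the per-pair n reported, so imbalance between pairs is
visible. Spearman is Pearson on mid-ranks with average-rank ties. A
zero-variance column has undefined (NaN) correlation entries and zero
covariance entries.

The hypothesis test is the pooled-variance two-sample Student t-test
(not Welch — the equal-variance form is the classic spreadsheet test this
engine re-creates): t = (μ₁−μ₂)/(s_p√(1/n₁+1/n₂)) with
s_p² = ((n₁−1)s₁²+(n₂−1)s₂²)/(n₁+n₂−2), two-sided p from the t
distribution on n₁+n₂−2 df, reject ⇔ p < α. Degenerate zero-pooled-variance
input yields t = 0, p = 1 when the means agree (not an error). When many
descriptors are tested the p values are reported raw, with no
multiple-testing correction — the user is expected to weigh them.

## Synthetic generators

The generators define the study conditions for every end-to-end check;
they emulate the *structure* of real geometry tables, not database error
processes (no disorder, no R-factor filtering, no space-group effects).

* **Furanoside rings**: τⱼ = τₘ·cos(P + 144°·j), j = 0..4, with τₘ = 39°
  (typical furanose amplitude) and P either a two-cluster wrapped-normal
  mixture — defaults P = 162° (C2′-endo) and P = 18° (C3′-endo), sd 8°,
  equal weights, illustrative of the two dominant pucker populations — or
  uniform on [0, 360) to sweep the whole pseudorotation pathway.
  Independent wrapped-normal noise (default sd 2°) is added per torsion;
  wrapped-normal was chosen over von Mises for simplicity, the difference
  being negligible at these widths. The phase-index convention (j from the
  glycosidic-adjacent torsion) is arbitrary: any fixed convention gives
  the same rank-2 geometry.
* **Hydrogen bonds**: deviation from linearity ψ = 180°−θ drawn from
  density ∝ sin ψ·e^{κ cos ψ} by rejection from the sin ψ proposal
  (cos ψ uniform on [−1, 1], acceptance probability e^{κ(cos ψ−1)}; mean
  acceptance rate exactly (1−e^{−2κ})/(2κ), e.g. ≈ 0.025 at κ = 20).
  κ = 0 is the pure cone-of-approach bias (uniform directions on a
  sphere); κ = 5 is the default moderately linear donor; κ = 20 a strongly
  linear one. Distance DIST = 1.9 Å + 0.004 Å/°·ψ + N(0, 0.08 Å), a
  typical H⋯A distance with the short-bond/linear-donor coupling built in.
  θ is a *linear* descriptor on [0°, 180°]: bond angles are not periodic
  over 360°, and circular machinery is reserved for torsions.
* **Symmetric fragments**: per row an offset ~ N(0, sd_between²) shared by
  k bonds, each bond ~ N(mean+offset, sd_within²); defaults k = 6,
  mean 1.90 Å, sd_within 0.015 Å, sd_between 0.010 Å (bond-length scales
  typical of M—C distances). The pooled variance is sd_within²+sd_between²
  by the law of total variance, which the acceptance suite checks to 5%.
* **Halide groups**: normal angles per integer-coded acceptor group,
  common sd 10°; the CLI default shifts group 2 by −5°, a difference the
  pooled t-test detects with power > 0.9 at α = 0.01 and n = 200/group
  (verified by Monte-Carlo in the test suite).

All generators draw from a single `numpy.random.default_rng(seed)` stream
in a documented order, so tables are bit-reproducible under a seed.

## Problem sizes and tolerances

Monte-Carlo checks use 10⁵ draws (sphere-uniform cone-angle check,
wrapped-normal σ recovery at 2% relative), 10⁴ replicates for t-test
type-I calibration (band 0.05 ± 3√(0.05·0.95/10⁴) ≈ ±0.0065), 100 random
data sets against brute-force circular oracles at 10⁻¹⁰…10⁻¹², and 50
random matrices for the PCA invariants at 10⁻⁸ (relative to λ₁ where a
scale is needed). Exact-model pseudorotation data must put ≥ 99.99% of
variance in two components; with the default 2° noise the observed figure
is ≈ 99.7%, the gap being exactly the injected noise.

## What passing tests do and do not show

The generators produce clean, well-specified distributions; passing tests
demonstrate that the statistical machinery is correct on data whose ground
truth is known by construction. They do not certify behaviour on real
database exports, which add disorder, correlated errors between
chemically related structures, multimodality beyond two clusters, and
selection effects from search filters. The engine's contracts (missing
data handling, hidden-row exclusion, pooling provenance) are designed so
those complications degrade gracefully rather than silently.

## Known limitations

* No circular confidence intervals or uniformity (Rayleigh-type) tests.
* No ANOVA, nonparametric location tests, or circular hypothesis tests.
* No kernel density estimation; no 2D cone correction.
* PCA offers no factor rotation or probabilistic variants; cluster
  centres for outlier flagging are user-declared, never detected.
* Plot determinism is guaranteed for SVG only; PNG rasterisation may
  differ across platforms.
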