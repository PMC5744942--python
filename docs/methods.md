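# Methods

This note records the models behind `torusrange`, the defaults that matter,
the choices made where the design was genuinely open, and what the test
suite does and does not establish.

## Coordinate frame and rasters

All coordinates are planar metres in an arbitrary local frame (field GPS
fixes are assumed already projected; every computation is Euclidean, so the
zone is irrelevant). Rasters are cell-centred, row-major, origin at the
lower-left plot corner; cells are half-open boxes so every point maps to
exactly one cell. The default resolution is 5 m — one shared grid for UDs,
kriged maps and the torus test keeps every overlay an integer-index
operation. Areas are reported in hectares at 2 decimals in output tables
and kept at full precision internally.

## Home ranges

**Inclusion rules.** Individuals with fewer than 25 relocations are
dropped: MCP area-accumulation curves (100% MCP of the first k points, with
the asymptote rule "five further points add at most 1% area") generally do
not stabilise below that. Individuals with more than 32 relocations are
subsampled to exactly 32 — LSCV degenerates when many near-coincident
points accumulate — by seeded uniform sampling without replacement,
preserving the original order of kept points. Random (rather than
chronological) subsampling avoids seasonal bias and is reproducible from
the run seed.

**Kernel UD.** One isotropic Gaussian kernel per relocation, averaged, then
renormalized to unit mass on the grid. A single isotropic bandwidth keeps
the LSCV score one-dimensional and is the common fixed-kernel default. The
LSCV score is evaluated in closed form (Gaussian convolution identities),
scanned on a 64-point geometric grid over `[0.05·h_ref, 2·h_ref]`
(`h_ref = σ·n^(−1/6)`, the bivariate-normal reference) and refined by
bounded golden-section search. A minimum on the interval boundary means the
score is monotone — the classic failure with heavily duplicated points —
and raises a convergence error; the pipeline then falls back to `h_ref`
with a logged warning, because every retained bird must contribute a UD to
the pooled overlay. The UD grid is the plot grid expanded (lattice-aligned)
to cover all points plus a 3-bandwidth margin, so less than ~1e-3 of kernel
mass is lost off-grid before renormalization.

**Isopleths.** The 95% region is assembled greedily: cells in decreasing
density order (row-major on ties) until 95% of mass is covered. This is
grid-exact and trivially testable; against a contoured region the area
difference vanishes as the grid refines (the closed-form check for a single
kernel, area ≈ π·χ²₂(0.95)·h², holds to 5% at 0.25 m cells).

**MCP.** `floor((1−percent)·n)` points farthest (Euclidean) from the
arithmetic mean centre are peeled — ties peel the later-listed point — and
the convex hull of the rest is the range. An epsilon in the floor guards
binary-float artifacts such as `(1−0.8)·5 = 0.9999…`.

**Overlap.** Directional: `|A∩B| / |A|` over kernel-region cells on the
shared grid. The overlap index in the source literature for this kind of
table is rarely stated; the output labels the metric explicitly rather than
claiming comparability with any published percentage.

**Summaries.** Mean, SD with n−1 denominator, quartiles by linear
interpolation of order statistics (type 7, the numpy/R default).

## Kriging

Empirical semivariogram: pair distances binned into 5 equal-width lags on
`(0, max_distance/2]` (half-max cutoff is standard practice; when a
degenerate layout leaves no pair under the cutoff, e.g. exactly two
samples, the cutoff falls back to the maximum distance), semivariance per
bin `mean(0.5·Δz²)`, empty bins dropped with a warning. The spherical model
is fitted by pair-count-weighted least squares with 5 multi-starts
(L-BFGS-B, bounds nugget ≥ 0, partial sill ≥ 0, range ≤ 2·max lag); among
near-tied optima the smallest range wins. Prediction is ordinary kriging
with a global neighbourhood — plots hold at most a few hundred quadrats, so
the (n+1) system is factorized once and solved for all cell centres; with
γ(0) = 0 the predictor interpolates exactly at sample locations. Negative
weights are logged, not forbidden. Negative predictions can be clipped at
zero for physically nonnegative variables (heights, densities, covers);
the CLI does this by default, the library function does not. Sites split by
unsampled gaps (e.g. a lake) are kriged as separate rectangular plots via
configuration, never jointly.

## The torus-shift association test

**Profile.** Over the N unmasked cells with habitat values `xᵢ` and pooled
UD mass `wᵢ` (Σw = 1): `p(x) = (1/N)Σ K_b(x−xᵢ)` and
`p(E|x) = Σ wᵢK_b(x−xᵢ) / p(x)` (Nadaraya–Watson), evaluated at 100 evenly
spaced points spanning the observed value range, with Silverman's
rule-of-thumb bandwidth on the cell values. Gradient points where `p(x)`
falls below 1% of its maximum are unsupported and excluded — the ratio is
unstable where almost no habitat exists. All three knobs (grid size,
bandwidth rule, support threshold) are arguments.

**Statistic.** The adjusted SD is the `p(E|x)`-weighted standard deviation
of `x` over supported points. `p(E|x)` is use per unit availability, so
weighting by it (rather than by raw use `p(x)·p(E|x)`) is what "adjusts"
for habitat abundance: a variable the birds track shows a single peak of
conditional use on a narrow band of values, hence a small SD, regardless
of whether that band is common or rare on the plot. Avoidance of a clumped
invader is the mirror image — conditional use concentrates at the low end
of the invader gradient — and also yields a small SD with a negative sign.
An earlier candidate statistic (the availability-weighted SD of the
`p(E|x)` values themselves) was rejected during validation: genuine
association makes that statistic systematically *larger* than its torus
null, so a lower-tail rule built on it has essentially no power.

**Null.** Exhaustive enumeration: 4 base maps (identity, 180° rotation,
mirror about the horizontal axis, both) × all `nx·ny` cyclic translations
in cell-size steps, the identity variant included exactly once — hence
fully deterministic, no random sampling anywhere. The smoothing bandwidth
and gradient grid are held at their observed-map values across variants:
without a mask the cell-value multiset is conserved, so recomputing them
per variant would be a no-op; with a mask, holding them fixed keeps the
statistic comparable across variants. The exclusion mask lives in plot
coordinates and is applied after shifting — exclusions are a property of
the plot (no field data there), not of the habitat pattern. Variants whose
profile is undefined (fewer than 3 supported points) are dropped from the
denominator and logged.

The production path computes all variants at once: for each base map and
gradient point, the Nadaraya–Watson numerator over all shifts is a circular
cross-correlation on the grid, done by FFT; the denominator is the same
correlation with the unmasked-cell indicator. A direct per-variant loop is
kept as the reference implementation and the two are asserted equal to
1e-8 in the tests. The observed statistic, the quantile
`#{null ≤ observed}/n_valid`, the lower-tail decision at level 0.05, and
the sign (use-weighted mean habitat value above/below the unweighted plot
mean; exact ties refuse to sign) complete the result. One test per variable
per plot, uncorrected — mirroring how such per-variable tables are
reported.

## Synthetic marshes

The generator states a small explicit world:

* **Habitat**: a stationary Gaussian random field on the cell centres with
  the covariance implied by a spherical variogram
  (`C(h) = psill·(1 − sph(h/a))` for h > 0, `C(0) = psill + nugget`),
  simulated exactly by Cholesky factorization with escalating diagonal
  jitter (1e-10 … 1e-6) — exactness over speed at desk scale (≤ ~10⁴
  cells); the factor is cached per geometry/model so repeated seeds cost
  one matrix–vector product. Default variogram: nugget 0.05, partial sill
  1.0, range 60 m — autocorrelation at the scale of a territory diameter,
  resolvable by the 35 m quadrat grid; an optional clip-at-zero transform
  mimics nonnegative variables. Chosen once, not tuned.
* **Birds**: territory centres by sequential inhibition (minimum spacing
  2×dispersion, default dispersion 15 m), two birds per territory sharing a
  centre (the monogamous pair), default 4 pairs × 30 relocations,
  bivariate-normal scatter truncated to the open plot rectangle.
* **Planted association**: candidates — both territory-centre proposals and
  relocation draws — are accepted with probability proportional to
  `exp(β·z)`, `z` the standardized habitat value. β = 0 is an exact null
  (the thinning branch is never entered). Thinning the centres as well as
  the points matters: habitat selection in territorial birds acts chiefly
  at territory establishment, and a within-territory tilt alone shifts the
  realized habitat use by an order of magnitude less than the
  between-territory placement noise, leaving nothing for any test to
  detect.

What the generator does **not** emulate: temporal autocorrelation of
movement (no step-selection or Ornstein–Uhlenbeck dynamics), detection
error, observer bias along transects, zero-inflated or skewed habitat
variables beyond the clip transform, and — importantly — torus-periodic
habitat. A green calibration test therefore validates the test machinery
under this world, not under every field situation.

## Known limitations

* **Torus translation is mildly liberal on non-periodic habitat.** The
  exhaustive shift group only guarantees exact exchangeability when the
  habitat field's distribution is invariant on the torus. Fields simulated
  (or measured) on the plane acquire a wrap-around seam under translation,
  which inflates null statistics slightly; measured here as a ~0.08–0.10
  rejection rate at nominal 0.05 over 200 null plots. A control experiment
  with an exactly torus-stationary field (covariance on wrapped distances)
  restores rejection 0.050 and near-perfect quantile uniformity — the
  machinery is exact; the approximation is inherent to applying torus
  translation to real maps. Users should treat p-values near the threshold
  accordingly.
* LSCV bandwidths at n ≈ 30 are variable; the 95% kernel area recovers the
  true 95% disk of a Gaussian territory only to ~20% median relative error
  at 32 points.
* The kriging neighbourhood is global; beyond ~2,000 samples per plot the
  dense solve would need a local-neighbourhood variant.
* Quadrat grids much coarser than the habitat correlation range (e.g. 35 m
  spacing on a 150 m plot) can collapse the variogram fit to pure nugget,
  yielding a constant kriged map on which the association test is — by
  design — undefined.
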