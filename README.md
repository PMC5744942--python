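# torusrange

Home-range estimation and habitat-association testing for territorial birds
on rectangular study plots.

`torusrange` is a small spatial-ecology pipeline built for studies of
marsh-dwelling, socially monogamous passerines monitored by repeated
sightings of banded individuals — the setting where a handful of birds hold
small contiguous territories inside a wetland plot, vegetation is measured
in 1 m² quadrats on a coarse grid, and the question is whether the birds'
space use tracks (or avoids) a continuous habitat variable such as cattail
height, water depth, or the stand density of an invasive plant.

## What it computes

**Home ranges.** For each individual with enough relocations (default: at
least 25, subsampled to at most 32), two standard estimators:

* the fixed-kernel utilization distribution (UD)
  `f̂(s) = (1/n) Σᵢ K_h(s − sᵢ)` with an isotropic Gaussian kernel and the
  bandwidth `h` chosen by least-squares cross-validation (LSCV); the home
  range is the smallest region holding 95% of UD mass, and pairwise overlap
  is reported as the proportion of the focal range intersected;
* the 95% minimum convex polygon (MCP): the convex hull after peeling the
  5% of points farthest from the arithmetic mean centre, with
  area-accumulation curves and the "five more points add ≤ 1% area"
  asymptote rule to judge sample-size adequacy.

**Habitat maps.** Quadrat measurements are interpolated to a continuous
raster by ordinary kriging: an empirical semivariogram with 5 equal-width
lags, a weighted least-squares fit of the spherical model
`γ(h) = c₀ + c·(1.5 h/a − 0.5 (h/a)³)` for `h < a`, and the exact
(n+1)-equation kriging solve at every cell centre. Cells inside exclusion
polygons (e.g. a dirt road crossing the plot) are masked throughout.

**Association test.** Along each habitat gradient `x` the pipeline
estimates, by Gaussian-kernel smoothing over raster cells, the habitat
availability `p(x)` and the conditional use `p(E|x)` (probability of bird
presence per unit of availability; Nadaraya–Watson with the pooled UD of
all retained birds as weights). The test statistic is the **adjusted SD**:
the `p(E|x)`-weighted standard deviation of `x` — small when conditional
use peaks on a narrow band of habitat values, i.e. when the birds are
specialists along that gradient. The null distribution is built by
**torus translation**: every cyclic shift of the habitat map in cell-size
steps, times 4 base maps (original, 180°-rotated, mirrored,
mirrored-and-rotated), `4·nx·ny` variants in all — exhaustive, hence fully
deterministic. The association is significant when the observed SD falls in
the lower 5% of the null; its sign is positive (preference) when the
use-weighted mean habitat value exceeds the plot mean, negative
(avoidance) otherwise.

**Synthetic marshes.** A first-class generator produces the same world the
pipeline consumes: Gaussian-random-field habitat surfaces with a spherical
variogram (exact Cholesky simulation), quadrat samples on a 35 m grid,
territorial pairs placed by sequential inhibition with bivariate-normal
relocation scatter, and an optional planted preference/avoidance
(acceptance-thinning by `exp(β·z)`). Calibration and power of the torus
test are validated against this generator in the test suite.

## Worked example

```python
import torusrange as tr

geometry = tr.PlotGeometry(length_x=250, length_y=250, cell_size=5)
config   = tr.RunConfig(seed=1)

habitat = tr.simulate_habitat(
    geometry,
    tr.HabitatFieldSpec(variable_name="invader_density", mean=5.0,
                        transform="clip"),
    seed=42,
)
birds = tr.simulate_relocations(
    geometry, tr.TerritorySpec(preference_beta=-2.0), habitat, seed=43
)

rows, regions, uds = tr.homerange_table(birds, config, geometry)
overlay = tr.overlay_from_relocations(birds, geometry, config)
result  = tr.torus_test(overlay, habitat, config)
print(result.observed_sd, result.quantile, result.significant, result.sign)
```

Running the packaged end-to-end driver prints, for seed 1:

```
$ python scripts/acceptance.py --seed 1 --out results/acceptance.json
8 individuals retained; 95% kernel UD mean 0.20 ha (SD 0.10), MCP mean 0.09 ha
kriged invader_density: spherical fit nugget 0.000, partial sill 1.087, range 89.0 m
torus test on the generating surface: observed SD 0.670, quantile 0.0001 of 10000 variants, significant=True, sign=negative
```

Reading: all 8 simulated birds clear the 25-location rule; their kernel
ranges average 0.20 ha. The spherical variogram refitted from the 64
quadrats recovers the field's autocorrelation scale. The planted avoidance
(β = −2) is detected — the observed adjusted SD is smaller than all but the
identity variant of the 10,000-member torus null (quantile 10⁻⁴ ≤ 0.05) and
the sign is negative, i.e. the birds sit on below-average values of the
"invader" surface.

The same stages are exposed as CLI subcommands
(`torusrange simulate | homerange | krige | torus-test`), reading a YAML
config and writing CSV tables and ESRI-ASCII rasters; see `--help`.

## scripts/acceptance.py

`python scripts/acceptance.py --seed <int> --out <path>` re-runs the whole
pipeline from scratch on a freshly simulated marsh — home-range table,
variogram fit + kriged map, and the torus association test — prints the
headline numbers, and writes the JSON result file to `--out`.
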