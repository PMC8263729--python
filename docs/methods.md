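# Methods

## Degradation and quality model

Habitat quality is scored in the InVEST-style two-step form. Each of the six
threat classes has a maximum effect distance `d_rmax` (km), a weight `w_r`
and a decay law (shipped defaults in `src/habscape/data/threats.csv`):
cropland 5 km / 0.5 / exponential, city–town 9 km / 1.0 / exponential, rural
settlements 6 km / 0.6 / exponential, other construction 2 km / 1.0 /
exponential, unused land 1 km / 0.4 / linear, sea reclamation 2 km / 0.3 /
linear. Eleven habitat classes carry suitability `H` and per-threat
sensitivity `S` (`data/sensitivity.csv`); construction classes default to
`H = S = 0`. The exponential decay uses the constant 2.99 exactly.

**Density normalization.** The raw decayed sum over threat cells is
unbounded (it grows with kernel size), which is incompatible with a
degradation degree defined on [0, 1]. We therefore divide the decayed sum
over source cells by the decayed sum over *every in-bounds cell* of the
kernel, giving a density of exactly 1 when everything within reach is a
source and 0 when nothing is; this is the only reading under which the
weighted aggregate `D` is guaranteed to stay in [0, 1]. The normalizer uses
only in-bounds cells (no padding), so the all-source density is 1 at edges
too. Raw sums are available via `normalize=False`.

Other numerical choices:

* distances are Euclidean centre-to-centre in projected metres, truncated at
  `d_rmax` exactly (contributions beyond it are identically zero, not merely
  small);
* a cell that is both habitat and threat source (e.g. cropland) receives
  degradation from its own class's kernel like any other cell; self-distance
  0 contributes decay 1;
* the kernel convolutions run through FFT; equivalence with a dense
  pairwise-distance evaluation is enforced to 1e-10 in the tests, and a
  literal four-nested-loop evaluation anchors the dense oracle on tiny
  grids;
* accessibility `β` defaults to 1 everywhere; an optional raster scales
  exposure multiplicatively;
* the half-saturation constant `k` defaults to 0.5 (the conventional choice
  for this model family; the parameter is exposed everywhere it is used).
  `Q = H` at `D = 0`, `H/2` at `D = k`;
* grades use half-open bands `[0,.2) … [.8,1]` mapped to I–V, so `Q = 0.2`
  is grade II and `Q = 1.0` grade V; invalid cells grade 0 (nodata).

## Transition statistics

`HQCI` is the mean per-cell quality change `Σ(Q_t2 − Q_t1)/n` over the cells
undergoing a given class transition and `CI = HQCI × S` with `S` the
converted area in km². The formula pair in the source literature is
ambiguous (the "total" index is printed as a mean); this reading is the one
consistent with the published six-row impact table, where `CI / S` rounds to
the printed `HQCI` at two decimals in every row — an identity the package
checks mechanically (`reference_values.check_impact_consistency`). ΔQ is
oriented `t2 − t1` (negative = loss). Cells entering or leaving the nodata
mask between epochs are excluded from all transition statistics. Transitions
with `n = 0` report NaN, not 0. Reports round HQCI/S/CI to two decimals;
the identity `CI = HQCI × S` is exact only before rounding.

## Synthetic landscapes

The generator emulates the statistical structure of a 30 m categorical
land-cover product over an urbanizing delta, not any particular map:

* **class mix** is hit exactly up to integer rounding (largest-remainder
  allocation); non-urban classes are laid out by slicing the rank order of a
  Gaussian-smoothed noise field into quantile bands, giving spatially
  clustered classes. The smoothing radius (default σ = 4 cells) is a free
  parameter — nothing is inferred about real covariance structure;
* **urban seeds** grow as mutually disjoint 4-connected clusters (an
  8-neighbour buffer keeps them separate), so the seed count is the cluster
  count by construction;
* **urban growth** converts exactly `round(rate × n_non_urban)` cells per
  period in one weighted draw with `P ∝ exp(compactness × urban fraction of
  the 3×3 neighbourhood)`; compact accretion for positive compactness,
  spatially random infill at zero. The default per-period schedule
  (0.08, 0.14, 0.03) makes the middle period fastest, the qualitative
  pattern of delta urbanization across 1990–2018-style epochs;
* **covariates** (NTL, POP) are affine transforms of the Gaussian-smoothed
  construction indicator plus noise whose sd is a fraction (default 0.05)
  of each layer's urban–background contrast, clipped at zero — positively
  correlated with built-up density by construction;
* **basins** are a seeded discrete Voronoi tessellation with smallest-first
  merging into the neighbour sharing the longest border until every basin
  reaches the minimum area (default 5 km², the conventional merge rule for
  small-watershed partitions); a post-pass reattaches any disconnected
  fragment. True DEM flow-accumulation delineation is out of scope.

Every generator is a pure function of an explicit integer seed.

What the synthetic data does **not** emulate: real class adjacency
constraints (rivers, coastlines), the mixed 30 m / 500 m / 1 km resolutions
of real covariate stacks (covariates are generated at the land-use grid
resolution), sensor artefacts in nighttime lights, and demographic dynamics.
Passing tests therefore demonstrate correctness of the *computations* under
controlled conditions, not calibration against any real landscape; headline
values from real-data studies (e.g. basin-wide mean quality levels) are not
reproduced here, and the published tables shipped in `reference_values` are
used purely as arithmetic inputs to consistency checks.

## Basin indicators and regression

NTL and POP enter as basin **means** (scale-free with respect to basin
area; sums would confound indicator level with basin size). LUR is the
construction-land cell share. Standardization is min–max by default because
the zone-ordering statistic SUM (sum of four standardized indicators) is
most interpretable on a common [0, 1] scale; z-score is available.

OLS and GWR are solved from scratch via the normal equations. GWR fits a
weighted least-squares problem at every basin centroid with a Gaussian
kernel by default (adaptive bisquare on k-nearest neighbours as an option);
at infinite bandwidth the Gaussian weights are exactly 1 and GWR reproduces
OLS to machine precision. Model comparison uses the hat-trace AICc

    AICc = 2n ln(σ̂_ml) + n ln(2π) + n (n + tr S) / (n − 2 − tr S)

for both models (tr S = p for OLS) and the residual standard error
σ = √(RSS / (n − tr S)). GWR is "preferred" only when both AICc and σ are
lower; a split is flagged ambiguous rather than resolved. Bandwidth is
chosen by deterministic golden-section search on AICc over a span from a
tenth of the median pairwise distance to twice the maximum distance.
Regressions default to one indicator at a time (three univariate local
fits, each yielding its own coefficient surface); a joint fit is supported
but not the default.

## SOM zoning

A 2×2 Kohonen map is the default so that neurons *are* the four zones.
Weights initialize from random data samples (seeded). Training is classic
online: per sample, the best-matching unit by Euclidean distance; Gaussian
neighbourhood on the neuron grid; 500 epochs with learning rate decaying
exponentially 0.5 → 0.01 and radius 1 → 0.1. Zones are lettered A–D by
descending mean member SUM, making the labelling invariant to neuron index
permutation; fewer than four non-empty neurons flags the assignment as
degenerate rather than failing. Zoning operates on per-basin indicator
means across epochs.

## Problem sizes and tolerances

The default end-to-end run uses a 160×160 grid at 250 m cells (1600 km²),
four epochs and ~374 requested basins merging to roughly 170–180 of ≥ 5 km²
— a size at which the full chain (including AICc bandwidth search and SOM
training) completes in seconds while every stage still has a few hundred
analysis units. The 30 m generator default matches the emulated product; at
30 m a 5 km² basin floor needs multi-thousand-pixel grids, hence the coarser
pipeline default. Oracle equivalences are asserted at 1e-10, closed forms at
1e-12, conservation identities at 1e-9 relative.

## Known limitations

* The degradation bound relies on the kernel normalization described above;
  with `normalize=False` the raw sums are not bounded and no [0, 1] grade
  semantics apply.
* The discrete Voronoi basins are convex-ish polygons, not hydrological
  catchments; indicators that depend on drainage topology would need real
  delineation.
* GWR standard errors / significance tests are not implemented (local
  coefficients and R² only), and no spatial autocorrelation diagnostics are
  provided.
* With strongly overlapping clusters the 2×2 SOM can collapse two clusters
  onto one neuron; the degenerate flag reports this but no automatic
  re-initialization is attempted.
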