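# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Phytoindication

A plot's community score on an ordinal indicator scale is the arithmetic
mean of the scores of the species recorded in it (default), or the
cover-weighted mean Σcᵢsᵢ/Σcᵢ when `weighting="cover"`. The unweighted mean
is the classical phytoindication convention and the default because the
weighting used in practice varies between workers; both paths share the
same machinery and are exchanged by one argument. A plot score is only
reported when at least `min_species` (default 3) scored species are
present — a one- or two-species "community" mean is not an indication, and
silently reporting it would poison downstream ordinations. Plots failing
the guard get a missing score and a logged warning.

The twelve score→physical-unit conversions are implemented exactly as
printed in the source scale system, with no rescaling:

| scale | relation | output |
|---|---|---|
| Hd (23 grades) | W = 18.65·e^(0.15·Hd) | productive moisture, mm/1 m layer |
| fH (12) | ω = 0.042·fH − 0.032 | moisture irregularity, 0–0.5 |
| Ae (15) | P = (100 − Ae⁴)/(100·(Ae⁴ + 1700)) | aeration (see caveat) |
| Rc (15) | pH = 2.26·ln(Rc) + 1.88 | soil pH |
| Sl (19) | S = 2^(0.6·Sl + 1) | salts, µg/l |
| Ca (13) | CaO+MgO = 14·Ca⁴·⁵/(Ca⁴·⁵ + 45000) | carbonates, % |
| Nt (11) | N = 5·Nt³·⁷/(Nt³·⁷ + 345) | nitrogen, g/kg |
| Tm (17) | RB = 0.21·Tm | radiation balance, gJ·m⁻²·yr⁻¹ |
| Om (23) | Hum = 0.54·Om − 7 | precipitation − evaporation, mm/day |
| Kn (17) | SKn = 10·Kn + 41 | Ivanov continentality |
| Cr (15) | Temp = 3.83·Cr − 38.17 | coldest-month mean, °C |
| Lc / Ellenberg L | log L = 0.22·score | log₁₀ relative light |

Caveats and conventions:

* The aeration relation's magnitude (~6·10⁻⁴ at Ae = 1) is implausible as a
  literal percentage. It is implemented verbatim and reported as
  printed-formula output rather than "corrected"; a silent correction would
  make results irreproducible against the published relation.
* ω is not clipped to [0, 0.5]; at the scale maximum fH = 12 the relation
  yields 0.472, inside the nominal range anyway.
* The light relation is stated for the Ellenberg L-value; the Didukh light
  factor Lc is routed through the same relation behind a flag
  (`convert_regimes(..., light_from=...)`), and both columns are emitted
  when both scores exist. Other Ellenberg scales are reported on their
  native ordinal scale — no physical conversion is printed for them.
* Conversions are defined for any positive score; out-of-ordinal-range
  inputs convert with a warning (soft check), except Rc ≤ 0 which is a hard
  domain error (logarithm).
* Moisture supply classes use lower-inclusive half-open bins
  [0,60) / [60,90) / [90,130) / [130,160) / [160,∞) mm: the verbal
  thresholds overlap at the boundaries, so a deterministic closure had to
  be chosen; boundaries belong to the upper class.

## Hemeroby and naturalness

Per-species hemeroby grades use the 7-step ordinal convention of the
hemeroby literature (1 ahemerobic … 7 metahemerobic). The plot hemeroby
index is the community-(cover-)weighted mean grade — the standard
operationalisation. Naturalness is the share of the plot's species count
(presence mode) or scored cover (cover mode) contributed by grades ≤
`natural_threshold` (default 3, i.e. up to mesohemerobic; configurable
1–6). Defining naturalness as a cover share rather than `8 − hemeroby`
keeps the two indices informationally distinct, which is what lets them
load with different magnitudes in ordinations of disturbed vegetation;
both definitions are exposed in config. Outputs are bounded by
construction: hemeroby in [1, 7] (convex combination of grades),
naturalness in [0, 1].

## TWINSPAN classification

Covers are expanded into nested binary pseudospecies at cut levels
0/2/5/10/20 % (a species at cover c is present in every pseudospecies with
cut ≤ c; the 0 % pseudospecies is plain presence). Each division:

1. computes the first correspondence-analysis axis of the group's binary
   submatrix by reciprocal averaging — power iteration on the row-score
   transition operator with the trivial constant axis deflated, tolerance
   1e-10, ≤ 10⁴ iterations. The start vector and the orientation rule
   (species score of largest magnitude made positive, ties by column name)
   are functions of the data only, so the result is invariant to plot
   order;
2. splits the plots at the weighted centroid of the axis (score ≤ 0 goes
   to the negative side; a plot exactly at the centroid is negative — a
   fixed tie rule for determinism);
3. selects up to five indicator pseudospecies maximising the between-side
   relative-frequency difference (minimum difference 0.2) and lets them
   reassign only *borderline* plots — those within 5 % of the maximum
   |score| around the centroid. Full misclassification handling of the
   historical desktop programs is undocumented; restricting indicator
   reassignment to the centroid band keeps the partition reproducible
   while preserving the spirit of indicator refinement.

A group is divided only while (a) depth < `max_levels` (6), (b) both sides
would keep ≥ `min_group` plots (5), and (c) the division's CA eigenvalue
reaches `min_eigenvalue` (0.45). The eigenvalue floor is this
implementation's own stopping criterion: divisions inside a compositionally
homogeneous group have markedly lower axis-1 eigenvalues than divisions
between real community types, and cutting noise produces spurious terminal
groups. All three are configurable; with the defaults, 12 terminal groups
are reachable from 135 plots. Eigenvalues lie in (0, 1); exactly 1 occurs
only for fully disjoint blocks and is accepted as a (perfect) division.

## Fidelity and the synoptic table

φ = (N·n_p − n·N_p)/√(n·N_p·(N−n)·(N−N_p)) from the 2×2 occurrence table
(N plots, N_p in the group, n species occurrences, n_p of them in the
group). With `equalize=True` (default) the counts are rescaled to a virtual
design in which the target group holds `target_fraction` (default 1/2) of
all plots before applying the formula, removing the group-size dependence;
a perfect indicator then reaches φ = 1 regardless of group size. A species
present in every plot has a vanishing numerator with a vanishing
denominator and is assigned φ = 0 (no association); other degenerate
margins leave φ undefined. Significance uses the two-sided Fisher exact
test on the raw (unequalised) table — the standard companion of φ in
synoptic-table practice. A species is flagged diagnostic for its best group
when both p < α (0.05) and φ ≥ `phi_threshold` (0.25) hold.

## Ordination

Correlation-matrix PCA (not covariance): the variable block mixes ordinal
scores, indices in [0, 1] and physical units, and correlation loadings are
bounded like correlation coefficients. Rows with missing cells and
zero-variance variables are dropped with warnings. Components are retained
by the Kaiser criterion (λ > 1); signs are fixed so the largest-|loading|
variable of each component loads positive. Loadings are masked by the
two-sided t-test of the variable–score correlation,
t = r·√((n−2)/(1−r²)); the test is a documented choice (the masking
convention in published ordination tables usually states only the α). PCA
runs on plots, with association labels available as an overlay via
`summarize_by_group`.

## Morphometry

Water is the set of DEM cells with elevation strictly below the water
surface (cells exactly at the level are dry — deterministic boundary);
bodies are 8-connected so diagonal channels connect; nodata cells are never
water and do generate shoreline. Area is cell count × cell², volume is the
per-cell depth sum × cell², shoreline is the count of water-cell edges
facing dry/nodata/border cells × cell size. Cell-edge shorelines are biased
upward relative to vector shorelines digitised from imagery (a grid
staircase measures longer than a smooth curve); within-method percent
changes between scenarios, the quantities of interest for drawdown
analysis, cancel that bias to first order. Percent decreases are
(from − to)/from × 100 rounded half-up to one decimal; a zero baseline
leaves the delta undefined. The DEM interchange format is the ESRI ASCII
grid, read and written directly (it is a six-line-header plain-text
format).

## Synthetic data

The generator emulates a drawdown-affected floodplain survey:

* 12 associations with evenly spaced optima on a dominant moisture
  gradient and random trophy/light optima; 11 exclusive species per
  association (niche breadth 0.05) plus 14 broad generalists (breadth
  0.20) = 146 species; 135 plots.
* plots sample their richness (normal, mean 12.1, SD 4.6, resampled into
  [5, 28]) species without replacement with probability ∝ Gaussian niche
  overlap (gradient weights 1.0/0.6/0.4); covers are lognormal
  (meanlog 0.9, sdlog 1.0) truncated to (0, 100], not renormalised, so
  summed plot cover averages ≈ 50 % and can exceed 100 % as layered
  vegetation does.
* indicator scores are linear functions of the species' latent position
  plus noise, truncated to each scale's range, with signs arranged so that
  dry-end species also score high on moisture variability, aeration,
  thermal and continentality scales and low on ombroregime — the
  correlation structure that makes one dominant moisture axis emerge.
* hemeroby grades couple to dryness (coupling 0.8 by default): dry open
  substrates carry the disturbance-tolerant flora. This is what gives
  hemeroby/naturalness recovery tests their signal.
* terrain grids are a flat 20 m base plus non-overlapping paraboloid
  depressions whose below-rim volume πr²d/2 is kept as analytic ground
  truth.

What the generator does **not** emulate: spatial autocorrelation between
plots, species' cover-abundance correlation structure beyond the lognormal
draw, succession (time), observer error in cover estimation, and the long
tail of rare species in real surveys. Tests passing on synthetic data
therefore demonstrate that the algorithms recover structure that is present
at realistic signal-to-noise, not that any particular field data set will
show that structure.

All randomness flows from a single `numpy.random.default_rng` seed;
identical seeds give byte-identical outputs.

## Pipeline

Stages run strictly in order (ingest → phytoindication → hemeroby →
classification → fidelity/synoptic → ordination → morphometry), each
writing plain CSV/JSON artifacts; a manifest records a hash of the
analysis-relevant config (the output directory is excluded — where
artifacts land does not change them), the package version, the seed and
per-stage row counts. Single-group classifications skip the fidelity stage
with a warning instead of failing. Validation errors exit with code 2,
runtime errors with 3.

## Problem sizes

The default test and acceptance runs use the survey-scale synthetic
fixture (135 plots × 146 species, ~530 pseudospecies), 50–80² terrain
grids, and 10 generator seeds for the across-seed contracts; these sizes
exercise every code path at the scale the methods are designed for while
keeping a full run in the tens of seconds.

## Known limitations

* TWINSPAN here targets partition-level agreement with the classical
  procedure, not label-level replication of any historical binary; the
  indicator-refinement band and the eigenvalue floor are this package's
  documented choices.
* Absolute shoreline lengths are grid-resolution dependent (edge counting);
  compare shorelines only within one grid and resolution.
* The phi significance test treats plots as independent samples; spatially
  clustered relevés inflate significance, as in all synoptic-table
  practice.
* No syntaxonomic naming: terminal groups are numbered, and attaching
  association names is expert work outside the package's scope.
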