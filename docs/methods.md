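# Methods

This note documents the models, the synthetic study system, the numerical
choices, and the limitations of the `paleorefugia` pipeline. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Grid model and coordinate conventions

All layers in a run share one `Grid`: cell (0, 0) is the upper-left corner,
cell centers at `origin + (index + 0.5)·cell_size` with y decreasing down
rows. Synthetic mode uses a Cartesian grid in kilometres (`crs_tag
"synthetic-cartesian"`), so every distance is exact; real-mode inputs must be
pre-gridded on a projected metric CRS, and distance operations refuse
geographic degrees, because the cell size (4.5 km) and buffer (100 km) are
metric quantities. Rasterization of polygons uses the center-point rule (a
cell is inside iff its center is covered by a polygon): deterministic and
area-unbiased at the working resolution. Nodata is NaN in memory and a
sentinel value in files.

## Suitability models

Maximum-entropy presence-background models are mathematically equivalent to a
logistic regression of presences against background in the
infinitely-weighted-points limit, so the package fits a transparent surrogate:
a ridge-penalized logistic regression (penalty λ = 1.0 on the standardized
scale, default 10,000 uniform background points) on linear and quadratic
features of the climate variables.

Two normalization details matter:

* **Quadratic features are built on centered variables**, `(v − v̄)²` with v̄
  the mean over the fitting design and frozen into the model. Raw `v` and
  `v²` are nearly collinear across a smooth climate gradient, so expressing a
  Gaussian niche requires two huge opposing coefficients that a ridge penalty
  crushes toward a flat response; centering makes the linear and quadratic
  terms nearly orthogonal and leaves the penalty acting on coefficients of
  moderate size. This changes the parameterization, not the model class.
* **Standardization constants are frozen at fitting time** and reused for
  every hindcast slice; slices are never re-standardized, so all projections
  share the contemporary suitability scale.

Screening follows the workflow's rules: species with ≤ 10 unique records are
not modeled; models with AUC ≤ 0.70 are excluded. AUC is the Mann–Whitney
probability that a presence outscores a background point (ties half), computed
single-pass on the full presence/background sets — no cross-validation folds,
since the fitted model is deterministic given the seed and the gate is a
discrimination screen, not a model-selection device.

The binarization threshold is the **nearest-rank 5th percentile** of model
scores at the occurrence points (sort ascending, take rank ⌈0.05·n⌉): it is
convention-free, deterministic, and guarantees ≥ 95% of occurrences classify
as suitable, with ties at the threshold counting as suitable (≥). Occurrences
exist only in the present, so the threshold is computed once from the
contemporary projection and applied unchanged to every paleo slice — the only
coherent reading of applying a minimum-occurrence threshold "at each time
interval". Projections are restricted to a 100 km buffer around the species'
range mask before thresholding (center-to-center distances via an exact
Euclidean distance transform).

## Stability, refugia, distance

The persistence table counts, per cell and species, the slices (of T) in
which the thresholded hindcast is suitable; summing over species gives the
stability surface, normalized by S·T to [0, 1].

The refugium rule is read **per-species-then-count**: a cell belongs to the
fraction-p refugium when at least ⌈p·S⌉ species each persisted ≥ τ slices
there. The ceiling is the strict reading of "p% of species present" for
fractional counts (p = 0.75, S = 10 → 8 species). The alternative reading
(≥ τ slices in which ≥ p·S species co-occur) was rejected as inconsistent
with per-species persistence phrasing. One τ applies to all four fractions;
τ defaults to `round(230/257 · T)` — the study's 230-of-257 cutoff (≈ 90% of
slices) rescaled to the stack length — and is a config key.

Climate stability (model-independent, per variable): for each consecutive
slice pair, deviation = SD of the two values (|Δ|/2) divided by the elapsed
time; per-cell deviation is the mean over the T−1 pairs; stability is
1/deviation rescaled by its finite maximum, with zero-deviation cells mapped
to exactly 1 rather than infinity. The statistic is invariant to adding a
constant to all slices and to rescaling all values or all time gaps by a
constant (tested). The window is the consecutive pair; a wider window is a
parameter, not a default.

Distance-to-refugium is the center-to-center Euclidean distance to the
nearest refugium **cell**, approximating edge distance at sub-cell precision;
exact polygon-edge distance is out of scope at a 4.5 km resolution.

## Diversity metrics

Computed on an assemblage matrix (cells × species) built from stacked
presence masks, with an optional reporting extent smaller than the PE extent.

* SR: presence count.
* PD: root-inclusive Faith PD — the summed length of every branch whose
  descendant tips intersect the cell's species set, so a single species
  scores its full root-to-tip path. Implemented as a branch × species
  incidence matrix; verified exactly (1e-12) against an independent
  brute-force path-enumeration oracle.
* RPD: PD divided by PD on a comparison tree of identical topology whose
  every branch equals `total_length / n_branches`. Preserving total length
  anchors the full assemblage at RPD = 1 exactly; the unit-branch alternative
  differs only by a global constant but loses that anchor.
* PE: Σ_b L_b / range_b over branches present in the cell, with range_b the
  number of cells over the PE extent occupied by ≥ 1 descendant tip. Summed
  over the PE extent, PE equals the occurring subtree's total branch length
  (conservation, tested on random fixtures to 1e-9). Range sizes always use
  the full PE extent even when reporting is clipped.
* Normalization: each metric is also reported divided by its observed maximum
  (the 0–1 presentation specifies no method; raw layers are always kept).

Species without tree tips stay in SR and are excluded from PD/RPD/PE with a
logged manifest. Taxa lacking sequence data can be grafted onto a sister tip
or clade at a calibrated attachment age; the graft preserves ultrametricity
(new pendant branch length = attachment age).

## Spatial regressions

Response and predictors are z-scored (population SD) before fitting, so
reported coefficients are standardized and univariate OLS R² equals the
squared Pearson correlation (an identity the tests check to 1e-10). Spatial
weights default to queen contiguity on the analysis grid, row-standardized —
the weight construction is a config key (`queen`, `rook`, `knn:k`) and is
echoed in output provenance. SLX regresses the response on each predictor
plus its spatially lagged copy; zero-variance lag columns are dropped, so a
degenerate all-zero W reduces SLX exactly to OLS. Reported are the
coefficients on X and the adjusted R².

Stepwise selection is forward from the empty model, adding the candidate with
the largest AIC decrease and stopping when none decreases AIC; ties break by
candidate order; the intercept is always kept. AIC uses the Gaussian
log-likelihood with estimated variance. With a single pure-noise candidate
the expected empty-model rate is P(χ²₁ < 2) ≈ 84%, which the tests probe at
n = 10,000.

All effects are reported with p-values and a significance flag; filtering to
significant effects is left to presentation. Cells are the sampling units
with no thinning; rows are complete-case (occupied cells with all predictors
finite).

## Conservation

Overlap and richness statistics are raster-based (cell counts on the shared
grid), consistent with cell-based richness averaging. The scenario experiment
samples, per replicate, 1000 cells without replacement from the scenario pool
and averages richness; 100 replicates. The "PA + random area" pool adds a
fresh uniform draw of unprotected cells (not contiguous blobs), matching the
refugium's cell count, redrawn every replicate; contiguity and redraw policy
are deliberate design choices exposed as parameters.

## The synthetic study system

The generator's defaults are the desk-scale study conditions: a 100 × 100
grid of 4.5 km cells; T = 60 paleo slices (610 → 20 kyr BP at 10 kyr steps,
the study's step and endpoint at a desk-scale depth); 10 stability-indicator
plus 40 focal species; a 30 × 30-cell core at the grid center.

* **Climate.** BIO1 rises 18→30 °C across columns, BIO12 1200→3000 mm across
  rows; the precipitation-to-temperature unit scale is 150 mm/°C, and anomaly
  SDs and niche breadths stated in °C apply to BIO12 times that scale. Each
  slice adds an independent zero-mean anomaly with per-cell SD 0.2 °C inside
  the core and 2.0 °C outside — this variance asymmetry **is** the planted
  stability signal, and the generator refuses configurations without it. The
  contemporary climate is one more anomaly draw. Anomalies are temporally
  independent (no autocorrelation): the stability statistics depend only on
  variance structure, and independence keeps analytic expectations available.
* **Species.** Gaussian niche kernels with breadth 1.2 °C — chosen so a
  core-matched species' equilibrium range (suitability ≥ 0.5 under the
  gradient climate, a disk of radius ≈ 12 cells) sits inside the 15-cell
  half-width core. Indicator species draw optima from the climate of the
  core's central third; half of the focal species (the core-affinity
  fraction) draw optima from anywhere in the core, the rest from the whole
  grid — the richness gradient is induced mechanically rather than by
  simulating diversification. The "true range" is the equilibrium range under
  the gradient climate: the single contemporary anomaly draw is year-scale
  weather noise, not range. Occurrences (200 per species) are cell centers
  sampled without replacement proportional to contemporary (noisy)
  suitability, via Gumbel-key weighted sampling. A skewed-kernel option
  exists to probe niche misspecification.
* **Phylogeny.** A pure-birth (Yule) tree over the focal species, made
  exactly ultrametric by extending pendant branches to just before the next
  speciation event. Core-affine species are assigned the least-nested tips
  (fewest root-path branches): such tips have the highest single-species
  relative PD, which carries the planted core signal into the RPD surface the
  same way the optimum assignment carries it into richness.
* **Tree density.** 800 stems/km² × mean indicator suitability under the
  gradient climate, plus independent N(0, 80) measurement noise (≈ 10% of the
  range), clipped at zero — tree stands integrate decades of climate, so the
  layer reflects the long-term gradient rather than one anomaly draw.
* **Protected areas.** Non-overlapping random rectangles accumulated until
  coverage is within ±2% of the target fraction; default 0.15, in line with
  typical terrestrial protected-area coverage, which also keeps the smallest
  scenario pool above the 1000 sampled cells.

What the generator does **not** emulate: temporal autocorrelation and trends
in climate; dispersal limitation and biotic interactions (suitability is
occupancy); speciation/extinction dynamics tied to refugia; rivers, oceans,
topography; spatially structured occurrence sampling bias; vector range maps
(truth ranges are rasters). Passing tests therefore show the pipeline
recovers a planted variance-asymmetry signal under a correctly specified
niche model — not that the empirical effect sizes of any real system are
reproduced.

## Seeds and determinism

One master seed deterministically derives independent per-stage streams
(climate, phylogeny, species, occurrences, protected areas, tree density,
model fitting, scenarios) via a seed sequence, so stages are individually
rerunnable and a full rerun is byte-for-byte identical; the run manifest
records SHA-256 digests of every artifact.

## Problem sizes

Default analyses run on the 100 × 100 grid with 60 slices and 50 species;
property tests use trees ≤ 8 tips and grids ≤ 5 × 5 where an exact
brute-force oracle is feasible; regression null checks use n = 10,000 rows.

## Known limitations

* The stability surface inherits any niche-model misspecification; only the
  quadratic (Gaussian) response is built in.
* AUC without cross-validation is optimistic for flexible models; with two
  climate variables and quadratic features the optimism is small, but the
  0.70 gate should be read as a coarse screen.
* SLX absorbs covariate autocorrelation only; residual autocorrelation in
  the response (spatial error or lag-y processes) is out of scope, as are
  corrections for the modifiable areal unit problem.
* Refugium "edge" distance is cell-based, biased low by up to half a cell
  diagonal relative to polygon edges.
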