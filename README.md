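# paleorefugia

Quantitative estimation of Pleistocene habitat stability from hindcast
ecological niche models, spatial phylogenetic diversity on a shared
sampling-unit grid, and refugia-aware conservation prioritization.

The package is aimed at biogeographers and conservation scientists who want to
test whether **past habitat stability** or **contemporary climate** better
explains present-day diversity in a region, and to turn the answer into a
protected-area gap analysis. It implements the full workflow end to end:

1. **Stability surface.** Fit a suitability model per forest-obligate
   indicator species (a ridge-penalized logistic regression of presences
   against uniform background on standardized, centered linear + quadratic
   climate features), screen models by unique-record count (> 10) and AUC
   (> 0.70), binarize with the 95% minimum-occurrence threshold (the
   nearest-rank 5th percentile of suitability at the occurrence points), and
   project each model onto every slice of a paleoclimate stack. Summing the
   thresholded hindcasts over species and slices gives a 0–1 spatio-temporal
   stability surface *f(cell) = #(species, slice) suitable / (S·T)*.
2. **Refugia.** Nested binary refugia at species fractions
   p ∈ {0.50, 0.75, 0.90, 0.95}: a cell qualifies when at least ⌈p·S⌉ species
   were each suitable there in ≥ τ of the T slices (τ defaults to the
   230-of-257 cutoff, rescaled to the stack length). A Euclidean
   distance-to-refugium surface is derived from the strictest mask.
3. **Diversity metrics.** Per 4.5 × 4.5 km sampling unit, from stacked species
   distribution maps and a rooted ultrametric phylogeny: species richness SR,
   Faith's PD = Σ L_b over branches spanning the cell's species
   (root-inclusive), relative PD = PD / PD on an equal-branch-length
   comparison tree of the same topology (total length preserved), and
   phylogenetic endemism PE = Σ_b L_b / range_b with branch ranges counted
   over a configurable PE extent. Unsequenced taxa can be grafted onto the
   tree at a calibrated attachment age.
4. **Spatial regressions.** Standardized univariate and multivariate OLS, the
   spatial lag of X model (SLX: OLS on [X, WX] with row-standardized queen
   weights), a Pearson collinearity screen, forward stepwise-AIC subset
   selection, and distance-decay regressions of each metric on distance from
   the refugium edge.
5. **Conservation.** Refugia × protected-area overlap, mean richness per
   refugia category, and a resampling experiment comparing mean richness of
   1000 sampled cells across protection scenarios (PA, PA + refugia,
   PA + equal-area random), 100 replicates each.

Because the real occurrence/paleoclimate/protected-area data are not shipped,
the package includes a first-class **synthetic-data generator** that plants a
known stable core: climate gradients with temporal anomaly variance that is
small inside a core rectangle and large outside, niche-structured species
whose suitability tracks that core, occurrence records sampled proportional to
contemporary suitability, a Yule phylogeny, and random rectangular protected
areas. Every downstream stage can therefore be validated against ground truth.

## Worked example

```python
from paleorefugia.synthetic import SimulationConfig, simulate_world
from paleorefugia.pipeline import AnalysisParams, analyze_world, best_univariate

world = simulate_world(SimulationConfig(seed=42))
result = analyze_world(world, AnalysisParams())

refugium = result.refugia.strictest().bool_array
core = world.core_mask.bool_array
print(f"refugia (95% species, tau={result.refugia.tau}) vs planted core: "
      f"Jaccard = {(refugium & core).sum() / (refugium | core).sum():.3f}")
for metric in ("SR", "PD", "RPD", "PE"):
    best, r2 = best_univariate(result.regressions, metric)
    slope = result.regressions["distance_decay"][metric]["OLS"]["coef"]["distance_to_refugium"]
    print(f"{metric}: best univariate predictor = {best} (R2 = {r2:.2f}), "
          f"distance-decay slope = {slope:+.2f}")
sc = result.conservation["scenarios"]
print("mean sampled richness: PA {:.1f}, PA+refugia {:.1f}, PA+random {:.1f}".format(
    sc["PA"]["grand_mean"], sc["PA_plus_refugia"]["grand_mean"],
    sc["PA_plus_random"]["grand_mean"]))
```

prints

```
refugia (95% species, tau=54) vs planted core: Jaccard = 0.828
SR: best univariate predictor = forest_stability (R2 = 0.69), distance-decay slope = -0.72
PD: best univariate predictor = forest_stability (R2 = 0.63), distance-decay slope = -0.73
RPD: best univariate predictor = forest_stability (R2 = 0.30), distance-decay slope = -0.57
PE: best univariate predictor = forest_stability (R2 = 0.61), distance-decay slope = -0.66
mean sampled richness: PA 8.2, PA+refugia 12.0, PA+random 7.1
```

Reading this: the refugia delineated purely from hindcast niche models
recover the planted stable core almost exactly (Jaccard 0.83); past forest
stability is the strongest univariate predictor of every diversity metric;
all four metrics decline significantly with distance from the refugium edge;
and a protection network extended to cover the refugia samples markedly
higher richness than one extended by an equal random area.

## Command line

```bash
paleorefugia all --config config.yaml --out-dir run/   # whole pipeline
paleorefugia summarize --out-dir run/                  # regenerate the report
```

`simulate`, `enm`, `stability`, `diversity`, `regress` and `conserve` rerun
individual stages from the artifacts stored in the run directory, so deleting
downstream outputs and rerunning only downstream stages reproduces them
byte-for-byte. Rasters are written both as single-band float32 GeoTIFF and as
a plain-text grid dialect (`.asc`); all thresholds (records > 10, AUC 0.70,
5th percentile, τ, fractions, 100 km buffer, 4.5 km cells) live in the YAML
config with the study defaults.

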