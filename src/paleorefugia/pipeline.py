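"""End-to-end orchestration: simulate → enm → stability → diversity → regress → conserve.

Each analysis stage exists as an in-memory function over the package's domain
types, plus a file-based wrapper that reads its inputs from a run directory
and writes its outputs back, so stages are individually rerunnable from
stored artifacts. ``run_all`` executes everything from one YAML config and
writes a manifest with per-file digests; one master seed deterministically
derives every stage seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import conservation as cons
from . import enm, io, spatial, stability
from . import phylodiversity as phylo
from .grid import Grid, MaskLayer, OccurrenceSet, RasterLayer, TimeSliceStack
from .synthetic import SimulationConfig, World, simulate_world
from .trees import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisParams",
    "PipelineResult",
    "default_tau",
    "fit_all_models",
    "stability_stage",
    "diversity_stage",
    "build_cell_table",
    "regression_stage",
    "conservation_stage",
    "analyze_world",
    "run_all",
    "summarize",
    "load_config",
]

PREDICTORS = [
    "temperature",
    "precipitation",
    "current_forest",
    "temperature_stability",
    "precipitation_stability",
    "forest_stability",
]
CONTEMPORARY_PREDICTORS = PREDICTORS[:3]
PAST_PREDICTORS = PREDICTORS[3:]
METRICS = ["SR", "PD", "RPD", "PE"]

#: the study's slice cutoff as a fraction of its slice count (230 of 257)
TAU_REFERENCE = 230 / 257


def default_tau(n_slices: int) -> int:
    """Scale the 230-of-257 slice cutoff to a stack of ``n_slices``."""
    return max(1, int(round(TAU_REFERENCE * n_slices)))


@dataclass(frozen=True)
class AnalysisParams:
    """Stage parameters, defaulting to the study's values."""

    tau: int | None = None            # None → default_tau(T)
    fractions: tuple[float, ...] = stability.REFUGIA_FRACTIONS
    buffer_km: float = 100.0
    percentile: float = 5.0
    n_background: int = 10_000
    reg: float = 1.0
    auc_cutoff: float = 0.70
    weights_scheme: str = "queen"
    n_cells: int = 1000
    n_reps: int = 100

    def resolved_tau(self, n_slices: int) -> int:
        tau = self.tau if self.tau is not None else default_tau(n_slices)
        if not 1 <= tau <= n_slices:
            raise ValueError(f"stability stage: τ={tau} outside [1, T={n_slices}]")
        return tau


@dataclass
class PipelineResult:
    """Everything an in-memory run produces."""

    world: World
    params: AnalysisParams
    models: dict[str, enm.SuitabilityModel]
    persistence: stability.PersistenceTable
    stability_map: stability.StabilityMap
    refugia: stability.RefugiaSet
    distance: RasterLayer
    climate_stability: dict[str, stability.ClimateStabilitySurface]
    diversity: dict[str, RasterLayer]
    cell_table: pd.DataFrame
    regressions: dict
    conservation: dict


# ---------------------------------------------------------------------------
# in-memory stages
# ---------------------------------------------------------------------------

def fit_all_models(
    occurrences: list[OccurrenceSet],
    contemporary: dict[str, RasterLayer],
    params: AnalysisParams,
    seed: int,
) -> dict[str, enm.SuitabilityModel]:
    """Fit, screen and threshold one suitability model per species."""
    climate = {v: contemporary[v] for v in ("BIO1", "BIO12")}
    models = {}
    for i, occ in enumerate(occurrences):
        models[occ.species] = enm.fit_enm(
            occ, climate,
            n_background=params.n_background,
            reg=params.reg,
            seed=(seed + i) % 2**31,
            percentile=params.percentile,
            auc_cutoff=params.auc_cutoff,
        )
    n_ok = sum(m.accepted for m in models.values())
    logger.info("enm stage: %d/%d models accepted", n_ok, len(models))
    return models


def _species_binary_hindcasts(
    model: enm.SuitabilityModel,
    stack: TimeSliceStack,
    range_mask: MaskLayer,
    buffer_km: float,
) -> list[MaskLayer]:
    """Thresholded, buffer-restricted projection of one model per slice."""
    out = []
    for i in range(stack.n_slices):
        suit = enm.project(model, stack.slice_climate(i))
        suit = enm.buffer_restrict(suit, range_mask, buffer_km)
        out.append(enm.binarize(suit, model.threshold))
    return out


def stability_stage(
    models: dict[str, enm.SuitabilityModel],
    stack: TimeSliceStack,
    range_masks: dict[str, MaskLayer],
    params: AnalysisParams,
) -> dict:
    """Stack indicator hindcasts into stability, refugia and distance surfaces."""
    accepted = {s: m for s, m in models.items() if m.accepted}
    if not accepted:
        raise ValueError("stability stage: no accepted indicator models")
    tau = params.resolved_tau(stack.n_slices)
    binary = {
        s: _species_binary_hindcasts(m, stack, range_masks[s], params.buffer_km)
        for s, m in accepted.items()
    }
    table = stability.build_persistence(binary)
    stab = stability.stack_stability(table)
    refugia = stability.refugia_set(table, params.fractions, tau)
    strictest = refugia.strictest()
    if not strictest.bool_array.any():
        raise ValueError("stability stage: the strictest refugium is empty")
    distance = stability.distance_to_refugia(strictest)
    climstab = {v: stability.climate_stability(stack, v) for v in stack.variables}
    return {
        "persistence": table,
        "stability_map": stab,
        "refugia": refugia,
        "distance": distance,
        "climate_stability": climstab,
        "tau": tau,
    }


def diversity_stage(
    models: dict[str, enm.SuitabilityModel],
    contemporary: dict[str, RasterLayer],
    range_masks: dict[str, MaskLayer],
    tree: Phylogeny,
    params: AnalysisParams,
) -> dict:
    """Focal species distribution maps → assemblages → SR/PD/RPD/PE.

    Accepted models contribute their thresholded, buffer-restricted
    contemporary projection; rejected species fall back to their range mask
    (the analog of using published range maps for unmodelable species).
    """
    climate = {v: contemporary[v] for v in ("BIO1", "BIO12")}
    species_masks: dict[str, MaskLayer] = {}
    for sp, model in models.items():
        if model.accepted:
            suit = enm.project(model, climate)
            suit = enm.buffer_restrict(suit, range_masks[sp], params.buffer_km)
            species_masks[sp] = enm.binarize(suit, model.threshold)
        else:
            species_masks[sp] = range_masks[sp]
    asm = phylo.build_assemblages(species_masks)
    maps = phylo.diversity_maps(tree, asm)
    return {"assemblage": asm, "maps": maps, "species_masks": species_masks}


def build_cell_table(
    diversity: dict[str, RasterLayer],
    contemporary: dict[str, RasterLayer],
    climstab: dict[str, stability.ClimateStabilitySurface],
    stability_map: stability.StabilityMap,
    distance: RasterLayer,
) -> pd.DataFrame:
    """One row per occupied cell: diversity metrics, predictors, distance."""
    layers = {
        "SR": diversity["SR"].values,
        "PD": diversity["PD"].values,
        "RPD": diversity["RPD"].values,
        "PE": diversity["PE"].values,
        "temperature": contemporary["BIO1"].values,
        "precipitation": contemporary["BIO12"].values,
        "current_forest": contemporary["tree_density"].values,
        "temperature_stability": climstab["BIO1"].stability,
        "precipitation_stability": climstab["BIO12"].stability,
        "forest_stability": stability_map.normalized,
        "distance_to_refugium": distance.values,
    }
    grid = distance.grid
    rows, cols = np.mgrid[0:grid.n_rows, 0:grid.n_cols]
    table = pd.DataFrame({"row": rows.ravel(), "col": cols.ravel()})
    for name, vals in layers.items():
        table[name] = np.asarray(vals, dtype=float).ravel()
    occupied = table["SR"] > 0
    table = table.loc[occupied].dropna().reset_index(drop=True)
    return table


def regression_stage(table: pd.DataFrame, params: AnalysisParams) -> dict:
    """The full model battery of the spatial analysis.

    Univariate OLS+SLX per metric × predictor, multivariate contemporary vs
    past models, forward-AIC subset selection, Pearson collinearity screen,
    and distance-decay regressions.
    """
    W = spatial.build_weights(table[["row", "col"]].to_numpy(), params.weights_scheme)
    corr, flagged = spatial.pearson_screen(table, PREDICTORS)
    as_dict = lambda r: r.to_dict()
    out = {
        "pearson": {"matrix": corr.to_dict(), "flagged": flagged},
        "univariate": {},
        "multivariate": {},
        "stepwise": {},
        "distance_decay": {},
    }
    for metric in METRICS:
        out["univariate"][metric] = {}
        for pred in PREDICTORS:
            out["univariate"][metric][pred] = {
                "OLS": as_dict(spatial.fit_ols(table, metric, [pred])),
                "SLX": as_dict(spatial.fit_slx(table, metric, [pred], W)),
            }
        out["multivariate"][metric] = {
            "contemporary": {
                "OLS": as_dict(spatial.fit_ols(table, metric, CONTEMPORARY_PREDICTORS)),
                "SLX": as_dict(spatial.fit_slx(table, metric, CONTEMPORARY_PREDICTORS, W)),
            },
            "past": {
                "OLS": as_dict(spatial.fit_ols(table, metric, PAST_PREDICTORS)),
                "SLX": as_dict(spatial.fit_slx(table, metric, PAST_PREDICTORS, W)),
            },
        }
        selected, fit = spatial.stepwise_aic(table, metric, PREDICTORS)
        out["stepwise"][metric] = as_dict(fit)
        out["distance_decay"][metric] = {
            kind: as_dict(r)
            for kind, r in spatial.distance_decay(
                table, metric, "distance_to_refugium", W).items()
        }
    return out


def conservation_stage(
    richness: RasterLayer,
    pa_mask: MaskLayer,
    refugia: stability.RefugiaSet,
    params: AnalysisParams,
    seed: int,
) -> dict:
    """Refugia protection gap, per-category richness, and scenario resampling."""
    overlap = {
        p: cons.overlap_fraction(mask, pa_mask)
        for p, mask in refugia.masks.items()
        if mask.bool_array.any()
    }
    categories = {f"refugia_{p:.2f}": mask for p, mask in refugia.masks.items()}
    categories["protected_areas"] = pa_mask
    mean_richness = cons.mean_richness_by_category(richness, categories)
    scenarios = cons.protection_scenarios(
        richness, pa_mask, refugia.strictest(),
        n_cells=params.n_cells, n_reps=params.n_reps, seed=seed)
    return {
        "overlap_fraction": {f"{p:.2f}": v for p, v in overlap.items()},
        "mean_richness": mean_richness,
        "scenarios": {s.scenario: s.to_dict() for s in scenarios},
    }


def analyze_world(world: World, params: AnalysisParams | None = None) -> PipelineResult:
    """Run every analysis stage in memory on a simulated world."""
    params = params or AnalysisParams()
    seeds = world.config._seeds()
    enm_seed = (seeds["species"] * 31 + 7) % 2**31
    cons_seed = (seeds["pa"] * 31 + 7) % 2**31

    models = fit_all_models(world.occurrences, world.contemporary, params, enm_seed)
    range_masks = {t.species: t.true_range for t in world.truths}

    ind_models = {t.species: models[t.species] for t in world.indicator_truths}
    stab = stability_stage(ind_models, world.stack, range_masks, params)

    focal_models = {t.species: models[t.species] for t in world.focal_truths}
    div = diversity_stage(focal_models, world.contemporary, range_masks, world.tree, params)

    table = build_cell_table(
        div["maps"], world.contemporary, stab["climate_stability"],
        stab["stability_map"], stab["distance"])
    regressions = regression_stage(table, params)
    conservation = conservation_stage(
        div["maps"]["SR"], world.pa_mask, stab["refugia"], params, cons_seed)

    return PipelineResult(
        world=world,
        params=params,
        models=models,
        persistence=stab["persistence"],
        stability_map=stab["stability_map"],
        refugia=stab["refugia"],
        distance=stab["distance"],
        climate_stability=stab["climate_stability"],
        diversity=div["maps"],
        cell_table=table,
        regressions=regressions,
        conservation=conservation,
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(source) -> tuple[SimulationConfig, AnalysisParams]:
    """Build config objects from a YAML path or a plain dict."""
    cfg = dict(io.read_config(source)) if not isinstance(source, dict) else dict(source)
    sim_kwargs = dict(cfg.get("simulation", {}))
    seed = int(cfg.get("seed", sim_kwargs.pop("seed", 0)))
    sim_kwargs.pop("seed", None)
    for key in ("core_region", "bio1_range", "bio12_range"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    sim = SimulationConfig(seed=seed, **sim_kwargs)
    ana_kwargs = dict(cfg.get("analysis", {}))
    if "fractions" in ana_kwargs:
        ana_kwargs["fractions"] = tuple(float(f) for f in ana_kwargs["fractions"])
    params = AnalysisParams(**ana_kwargs)
    return sim, params


def _config_echo(sim: SimulationConfig, params: AnalysisParams) -> dict:
    return {
        "seed": sim.seed,
        "simulation": dataclasses.asdict(sim),
        "analysis": dataclasses.asdict(params),
    }


# ---------------------------------------------------------------------------
# file-based stages
# ---------------------------------------------------------------------------

def _age_tag(age: float) -> str:
    return f"{int(round(age)):06d}"


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, spatial.RegressionResult):
        return obj.to_dict()
    if isinstance(obj, cons.ScenarioResult):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def stage_simulate(sim: SimulationConfig, out: Path) -> World:
    """Generate the world and write all its artifacts under ``out``."""
    world = simulate_world(sim)
    climate_dir = out / "climate"
    climate_dir.mkdir(parents=True, exist_ok=True)
    for var, layers in world.stack.layers.items():
        for age, layer in zip(world.stack.ages, layers):
            io.write_raster(layer, climate_dir / f"paleo_{var}_{_age_tag(age)}.asc")
    for var, layer in world.contemporary.items():
        io.write_raster(layer, climate_dir / f"contemporary_{var}.asc")
    io.write_occurrences(world.occurrences, out / "occurrences.csv")
    io.write_tree(world.tree, out / "tree.nwk")
    io.write_geojson(world.pa_polygons, out / "protected_areas.geojson")
    io.write_raster(world.pa_mask.as_raster("protected_area"), out / "pa_mask.asc")
    io.write_raster(world.core_mask.as_raster("planted_core"), out / "core_mask.asc")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for t in world.truths:
        io.write_raster(t.true_range.as_raster("range"),
                        truth_dir / f"range_{t.species}.asc")
    _write_json(
        [
            {
                "species": t.species,
                "niche_optimum": list(t.niche_optimum),
                "niche_breadth": list(t.niche_breadth),
                "is_indicator": t.is_indicator,
                "is_core": t.is_core,
                "truth_threshold": t.truth_threshold,
            }
            for t in world.truths
        ],
        truth_dir / "species.json",
    )
    return world


def _load_simulated(out: Path, sim: SimulationConfig):
    """Reload the artifacts stage_simulate wrote."""
    climate_dir = out / "climate"
    grid = None
    layers: dict[str, list[RasterLayer]] = {"BIO1": [], "BIO12": []}
    for var in layers:
        for age in sim.ages:
            layer = io.read_raster(climate_dir / f"paleo_{var}_{_age_tag(age)}.asc", grid)
            grid = grid or layer.grid
            layers[var].append(layer)
    stack = TimeSliceStack(grid, sim.ages, layers)
    contemporary = {
        var: io.read_raster(climate_dir / f"contemporary_{var}.asc", grid)
        for var in ("BIO1", "BIO12", "tree_density")
    }
    occurrences = io.read_occurrences(out / "occurrences.csv")
    tree = io.read_tree(out / "tree.nwk")
    pa_raster = io.read_raster(out / "pa_mask.asc", grid)
    pa_mask = MaskLayer(grid, pa_raster.values, "protected_area")
    with open(out / "truth" / "species.json") as fh:
        meta = json.load(fh)
    range_masks = {}
    for m in meta:
        r = io.read_raster(out / "truth" / f"range_{m['species']}.asc", grid)
        range_masks[m["species"]] = MaskLayer(grid, r.values, "range")
    return stack, contemporary, occurrences, tree, pa_mask, meta, range_masks


def write_models(models: dict[str, enm.SuitabilityModel], out: Path) -> None:
    models_dir = out / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    for sp, model in models.items():
        _write_json(model.to_dict(), models_dir / f"{sp}.json")


def load_models(out: Path) -> dict[str, enm.SuitabilityModel]:
    models = {}
    for path in sorted((out / "models").glob("*.json")):
        with open(path) as fh:
            m = enm.SuitabilityModel.from_dict(json.load(fh))
        models[m.species] = m
    if not models:
        raise FileNotFoundError(f"no fitted models under {out / 'models'}")
    return models


def write_stability_outputs(stab: dict, out: Path) -> None:
    stab_dir = out / "stability"
    stab_dir.mkdir(parents=True, exist_ok=True)
    io.write_raster(stab["stability_map"].as_raster(), stab_dir / "forest_stability.asc")
    for p, mask in stab["refugia"].masks.items():
        io.write_raster(mask.as_raster("refugium"), stab_dir / f"refugia_p{int(p * 100)}.asc")
    io.write_raster(stab["distance"], stab_dir / "distance_to_refugium.asc")
    for var, surf in stab["climate_stability"].items():
        io.write_raster(surf.as_raster(), stab_dir / f"climate_stability_{var}.asc")
    _write_json(
        {
            "S": stab["persistence"].n_species,
            "T": stab["persistence"].n_slices,
            "tau": stab["refugia"].tau,
            "fractions": sorted(stab["refugia"].masks),
        },
        stab_dir / "provenance.json",
    )


def write_diversity_outputs(maps: dict[str, RasterLayer], out: Path) -> None:
    div_dir = out / "diversity"
    div_dir.mkdir(parents=True, exist_ok=True)
    for name, layer in maps.items():
        io.write_raster(layer, div_dir / f"{name}.asc")


def write_regression_outputs(table: pd.DataFrame, regressions: dict, out: Path) -> None:
    reg_dir = out / "regress"
    reg_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(reg_dir / "cell_table.csv", index=False)
    _write_json(regressions, reg_dir / "regressions.json")


def run_all(config, out_dir) -> dict:
    """Execute the full pipeline from a config, halting on the first error.

    Returns the run manifest (also written to ``out/manifest.json``).
    """
    sim, params = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()

    world = stage_simulate(sim, out)
    params.resolved_tau(world.stack.n_slices)  # fail fast on bad τ
    result = analyze_world(world, params)

    write_models(result.models, out)
    write_stability_outputs(
        {
            "persistence": result.persistence,
            "stability_map": result.stability_map,
            "refugia": result.refugia,
            "distance": result.distance,
            "climate_stability": result.climate_stability,
        },
        out,
    )
    write_diversity_outputs(result.diversity, out)
    write_regression_outputs(result.cell_table, result.regressions, out)
    _write_json(result.conservation, out / "conservation.json")

    io.write_config(_config_echo(sim, params), out / "config.yaml")
    report = summarize(result)
    (out / "report.txt").write_text(report)

    files = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": sim.seed,
        "config": _config_echo(sim, params),
        "tau": result.refugia.tau,
        "digests": {str(p.relative_to(out)): _digest(p) for p in files},
        "elapsed_s": round(time.time() - started, 3),
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def best_univariate(regressions: dict, metric: str) -> tuple[str, float]:
    """Predictor with the highest univariate OLS R² for a metric."""
    uni = regressions["univariate"][metric]
    best = max(uni, key=lambda p: uni[p]["OLS"]["r2"])
    return best, uni[best]["OLS"]["r2"]


def format_report(regressions: dict, conservation: dict) -> str:
    """Human-readable run report mirroring the analysis tables."""
    lines = []
    reg = regressions
    lines.append("UNIVARIATE REGRESSIONS (standardized coefficient, OLS R2, "
                 "SLX coefficient, SLX adjusted R2)")
    for metric in METRICS:
        lines.append(f"  {metric}:")
        for pred in PREDICTORS:
            o = reg["univariate"][metric][pred]["OLS"]
            s = reg["univariate"][metric][pred]["SLX"]
            lines.append(
                f"    {pred:<24s} {o['coef'][pred]:+7.3f}  {o['r2']:6.3f}  "
                f"{s['coef'][pred]:+7.3f}  {s['adj_r2']:6.3f}"
            )
        best, r2 = best_univariate(reg, metric)
        lines.append(f"    best predictor: {best} (R2={r2:.3f})")
    lines.append("")
    lines.append("MULTIVARIATE (contemporary vs past, OLS R2 / SLX adjusted R2)")
    for metric in METRICS:
        m = reg["multivariate"][metric]
        lines.append(
            f"  {metric}: contemporary {m['contemporary']['OLS']['r2']:.3f} / "
            f"{m['contemporary']['SLX']['adj_r2']:.3f}   past {m['past']['OLS']['r2']:.3f} / "
            f"{m['past']['SLX']['adj_r2']:.3f}"
        )
    lines.append("")
    lines.append("STEPWISE AIC SELECTION")
    for metric in METRICS:
        fit = reg["stepwise"][metric]
        lines.append(f"  {metric}: {fit['selected']} (R2={fit['r2']:.3f}, AIC={fit['aic']:.1f})")
    lines.append("")
    lines.append("DISTANCE DECAY (standardized slope on distance, p-value)")
    for metric in METRICS:
        o = reg["distance_decay"][metric]["OLS"]
        slope = o["coef"]["distance_to_refugium"]
        p = o["pvalues"]["distance_to_refugium"]
        lines.append(f"  {metric}: slope {slope:+.3f} (p={p:.2e})")
    lines.append("")
    lines.append("CONSERVATION")
    for p, frac in sorted(conservation["overlap_fraction"].items()):
        lines.append(f"  refugia p={p}: {frac * 100:.1f}% protected")
    for name, mean in conservation["mean_richness"].items():
        lines.append(f"  mean richness {name}: {mean:.2f}")
    for name, sc in conservation["scenarios"].items():
        lines.append(f"  scenario {name}: {sc['grand_mean']:.2f} ± {sc['sd']:.2f}")
    return "\n".join(lines) + "\n"


def summarize(result: PipelineResult) -> str:
    return format_report(result.regressions, result.conservation)
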