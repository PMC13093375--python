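"""Synthetic study system with a planted stable forest core.

The generator emulates the statistical structure the analysis assumes, with a
known ground truth:

* a Cartesian km grid carrying smooth climate gradients — annual mean
  temperature (BIO1) increases west→east across columns, annual precipitation
  (BIO12) north→south across rows;
* a paleoclimate history of T slices: the fixed gradient plus independent
  zero-mean temporal anomalies whose per-cell SD is small inside a rectangular
  "core" and large outside — this variance asymmetry IS the planted stability
  signal, and the contemporary climate is one more anomaly draw;
* forest-obligate species with Gaussian niche kernels: stability *indicator*
  species have optima matching the core's climate; half of the *focal*-clade
  species do too (creating the richness gradient mechanically), the rest sit
  anywhere in climate space;
* occurrence records sampled without replacement proportional to contemporary
  suitability; a Yule phylogeny over the focal species, with core-affine
  species assigned the least-nested tips (which carries the planted gradient
  into relative PD);
* a tree-density layer derived from long-term (gradient) indicator
  suitability plus independent measurement noise, and random non-overlapping
  rectangular protected areas.

Everything is reproducible from a single master seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from dendropy.simulate import treesim
from shapely.geometry import box

from .grid import Grid, MaskLayer, OccurrenceSet, RasterLayer, TimeSliceStack
from .trees import Phylogeny

__all__ = [
    "SimulationConfig",
    "SpeciesTruth",
    "World",
    "make_time_axis",
    "simulate_climate_history",
    "simulate_phylogeny",
    "simulate_species",
    "simulate_protected_areas",
    "simulate_world",
]

#: unit scale between the precipitation and temperature gradients (mm per °C):
#: anomaly SDs and niche breadths stated in °C apply to BIO12 multiplied by this.
BIO12_PER_BIO1 = 150.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic world (defaults = desk-scale run)."""

    seed: int = 0
    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 4.5  # km
    start_age: float = 610.0  # kyr BP
    end_age: float = 20.0
    step: float = 10.0
    n_indicator: int = 10
    n_focal: int = 40
    core_region: tuple[int, int, int, int] = (35, 65, 35, 65)  # row0,row1,col0,col1
    anomaly_sd_inside: float = 0.2   # °C (×150 for BIO12)
    anomaly_sd_outside: float = 2.0
    niche_breadth: float = 1.2       # Gaussian kernel SD, °C
    niche_skew: float = 0.0          # optional misspecification: skews the truth kernel
    core_affinity: float = 0.5       # fraction of focal species with core optima
    truth_threshold: float = 0.5     # suitability cutoff defining true ranges
    n_occurrences: int = 200
    pa_fraction: float = 0.15
    bio1_range: tuple[float, float] = (18.0, 30.0)    # °C across columns
    bio12_range: tuple[float, float] = (1200.0, 3000.0)  # mm across rows
    tree_density_scale: float = 800.0  # stems/km² at perfect suitability
    tree_density_noise: float = 80.0   # measurement noise SD

    def __post_init__(self) -> None:
        if not self.anomaly_sd_inside < self.anomaly_sd_outside:
            raise ValueError(
                "anomaly_sd_inside must be smaller than anomaly_sd_outside "
                "(this asymmetry is the planted stability signal)"
            )
        r0, r1, c0, c1 = self.core_region
        if not (0 <= r0 < r1 <= self.n_rows and 0 <= c0 < c1 <= self.n_cols):
            raise ValueError("core_region must be a nonempty rectangle inside the grid")
        make_time_axis(self.start_age, self.end_age, self.step)  # validates

    @property
    def grid(self) -> Grid:
        return Grid(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            origin_x=0.0,
            origin_y=self.n_rows * self.cell_size,
            cell_size=self.cell_size,
        )

    @property
    def ages(self) -> list[float]:
        return make_time_axis(self.start_age, self.end_age, self.step)

    @property
    def n_slices(self) -> int:
        return len(self.ages)

    def core_mask(self) -> MaskLayer:
        values = np.zeros((self.n_rows, self.n_cols))
        r0, r1, c0, c1 = self.core_region
        values[r0:r1, c0:c1] = 1.0
        return MaskLayer(self.grid, values, "study_area")

    def _seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the master seed."""
        base = np.random.SeedSequence(self.seed).generate_state(6, dtype=np.uint32)
        names = ("climate", "phylogeny", "species", "occurrences", "pa", "tree_density")
        return {name: int(s % (2**31)) for name, s in zip(names, base)}


@dataclass
class SpeciesTruth:
    """Generator-side ground truth for one species."""

    species: str
    niche_optimum: tuple[float, float]   # (BIO1*, BIO12*)
    niche_breadth: tuple[float, float]   # kernel SDs per variable
    is_indicator: bool
    is_core: bool
    #: equilibrium range: suitability under the mean (gradient) climate above
    #: the truth threshold — the species' range absent year-scale weather noise
    true_range: MaskLayer
    truth_threshold: float
    niche_skew: float = 0.0

    def suitability(self, climate: dict[str, RasterLayer]) -> RasterLayer:
        """True suitability of this species under any climate slice."""
        b1 = climate["BIO1"].values
        b12 = climate["BIO12"].values
        o1, o12 = self.niche_optimum
        s1, s12 = self.niche_breadth
        z1 = (b1 - o1) / s1
        z12 = (b12 - o12) / s12
        suit = np.exp(-0.5 * (z1**2 + z12**2))
        if self.niche_skew:
            # skew-normal style asymmetry; keeps the mode near the optimum
            from scipy.stats import norm
            suit = suit * 2 * norm.cdf(self.niche_skew * z1)
        return RasterLayer(climate["BIO1"].grid, suit, f"suitability_{self.species}")

    def range_mask(self, climate: dict[str, RasterLayer]) -> MaskLayer:
        suit = self.suitability(climate).values
        return MaskLayer(climate["BIO1"].grid,
                         (suit >= self.truth_threshold).astype(float), "range")


@dataclass
class World:
    """Everything one synthetic run produces."""

    config: SimulationConfig
    grid: Grid
    stack: TimeSliceStack
    contemporary: dict[str, RasterLayer]  # BIO1, BIO12, tree_density
    truths: list[SpeciesTruth]
    occurrences: list[OccurrenceSet]
    tree: Phylogeny
    pa_mask: MaskLayer
    pa_polygons: list
    core_mask: MaskLayer

    @property
    def indicator_truths(self) -> list[SpeciesTruth]:
        return [t for t in self.truths if t.is_indicator]

    @property
    def focal_truths(self) -> list[SpeciesTruth]:
        return [t for t in self.truths if not t.is_indicator]


def make_time_axis(start_age: float, end_age: float, step: float) -> list[float]:
    """Strictly decreasing ages from start_age to end_age inclusive (kyr BP)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if not start_age > end_age > 0:
        raise ValueError("require start_age > end_age > 0")
    span = start_age - end_age
    n, rem = divmod(span, step)
    if abs(rem) > 1e-9 * max(1.0, span) and abs(rem - step) > 1e-9 * max(1.0, span):
        raise ValueError(f"(start_age - end_age) = {span} is not divisible by step {step}")
    n_slices = int(round(span / step)) + 1
    return [start_age - i * step for i in range(n_slices)]


def _base_climate(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    rows = (np.arange(cfg.n_rows) + 0.5) / cfg.n_rows
    cols = (np.arange(cfg.n_cols) + 0.5) / cfg.n_cols
    b1 = cfg.bio1_range[0] + (cfg.bio1_range[1] - cfg.bio1_range[0]) * cols
    b12 = cfg.bio12_range[0] + (cfg.bio12_range[1] - cfg.bio12_range[0]) * rows
    return (
        np.broadcast_to(b1, (cfg.n_rows, cfg.n_cols)).copy(),
        np.broadcast_to(b12[:, None], (cfg.n_rows, cfg.n_cols)).copy(),
    )


def _anomaly_sd_map(cfg: SimulationConfig) -> np.ndarray:
    sd = np.full((cfg.n_rows, cfg.n_cols), cfg.anomaly_sd_outside)
    r0, r1, c0, c1 = cfg.core_region
    sd[r0:r1, c0:c1] = cfg.anomaly_sd_inside
    return sd


def simulate_climate_history(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[TimeSliceStack, dict[str, RasterLayer]]:
    """Paleoclimate stack plus contemporary BIO1/BIO12 layers.

    Each slice is the fixed spatial gradient plus an independent zero-mean
    temporal anomaly whose per-cell SD is small inside the core and large
    outside; the contemporary layers are the gradient plus one more draw.
    """
    rng = np.random.default_rng(cfg._seeds()["climate"] if seed is None else seed)
    grid = cfg.grid
    base_b1, base_b12 = _base_climate(cfg)
    sd = _anomaly_sd_map(cfg)
    ages = cfg.ages
    layers: dict[str, list[RasterLayer]] = {"BIO1": [], "BIO12": []}
    for _ in ages:
        layers["BIO1"].append(
            RasterLayer(grid, base_b1 + rng.standard_normal(grid.shape) * sd, "BIO1"))
        layers["BIO12"].append(
            RasterLayer(grid, base_b12 + rng.standard_normal(grid.shape) * sd * BIO12_PER_BIO1,
                        "BIO12"))
    stack = TimeSliceStack(grid, ages, layers)
    contemporary = {
        "BIO1": RasterLayer(grid, base_b1 + rng.standard_normal(grid.shape) * sd, "BIO1"),
        "BIO12": RasterLayer(grid, base_b12 + rng.standard_normal(grid.shape) * sd * BIO12_PER_BIO1,
                             "BIO12"),
    }
    return stack, contemporary


def simulate_phylogeny(n_tips: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with tips sp_001…, lengths in Myr."""
    if n_tips < 2:
        raise ValueError("need at least two tips")
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    # the simulator stops at the nth speciation event, leaving a zero-length
    # cherry; run the clock to just before the (n+1)th event so every pendant
    # branch is positive and the tree stays exactly ultrametric
    extra = np.random.default_rng(seed).exponential(1.0 / n_tips)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += extra
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = dendropy.Taxon(label=f"sp_{i:03d}")
    tree.update_taxon_namespace()
    return Phylogeny(tree)


def _climate_at_cell(base_b1, base_b12, row: int, col: int) -> tuple[float, float]:
    return float(base_b1[row, col]), float(base_b12[row, col])


def simulate_species(
    cfg: SimulationConfig,
    contemporary: dict[str, RasterLayer],
    seed: int | None = None,
    occurrence_seed: int | None = None,
) -> tuple[list[SpeciesTruth], list[OccurrenceSet]]:
    """Niche-structured species and suitability-weighted occurrence samples.

    Indicator species (``ind_01``…) draw optima from the climate of the core's
    central third; a ``core_affinity`` fraction of focal species (``sp_001``…)
    draw optima from anywhere in the core, the rest from the whole grid.
    Occurrences are cell centers sampled without replacement with probability
    proportional to contemporary suitability.
    """
    seeds = cfg._seeds()
    rng = np.random.default_rng(seeds["species"] if seed is None else seed)
    occ_rng = np.random.default_rng(
        seeds["occurrences"] if occurrence_seed is None else occurrence_seed)
    grid = cfg.grid
    base_b1, base_b12 = _base_climate(cfg)
    breadth = (cfg.niche_breadth, cfg.niche_breadth * BIO12_PER_BIO1)
    r0, r1, c0, c1 = cfg.core_region

    def optimum_from(rect) -> tuple[float, float]:
        rr0, rr1, cc0, cc1 = rect
        return _climate_at_cell(base_b1, base_b12,
                                int(rng.integers(rr0, rr1)), int(rng.integers(cc0, cc1)))

    # central third of the core: optima tightly matched to the core climate
    third_r = (r1 - r0) // 3
    third_c = (c1 - c0) // 3
    inner = (r0 + third_r, r1 - third_r, c0 + third_c, c1 - third_c)

    specs: list[tuple[str, tuple[float, float], bool, bool]] = []
    for i in range(cfg.n_indicator):
        specs.append((f"ind_{i + 1:02d}", optimum_from(inner), True, True))
    n_core = int(round(cfg.core_affinity * cfg.n_focal))
    for i in range(cfg.n_focal):
        is_core = i < n_core
        rect = cfg.core_region if is_core else (0, cfg.n_rows, 0, cfg.n_cols)
        specs.append((f"sp_{i + 1:03d}", optimum_from(rect), False, is_core))

    truths, occurrences = [], []
    xs, ys = grid.cell_centers()
    for name, optimum, is_indicator, is_core in specs:
        truth = SpeciesTruth(
            species=name,
            niche_optimum=optimum,
            niche_breadth=breadth,
            is_indicator=is_indicator,
            is_core=is_core,
            true_range=None,  # filled below
            truth_threshold=cfg.truth_threshold,
            niche_skew=cfg.niche_skew,
        )
        base_layers = {
            "BIO1": RasterLayer(grid, base_b1, "BIO1"),
            "BIO12": RasterLayer(grid, base_b12, "BIO12"),
        }
        truth.true_range = truth.range_mask(base_layers)
        if not truth.true_range.bool_array.any():
            raise ValueError(f"species {name!r} has an empty equilibrium range")
        truths.append(truth)

        suit = truth.suitability(contemporary)
        weights = np.nan_to_num(suit.values.ravel(), nan=0.0)
        eligible = weights > 0
        if eligible.sum() < cfg.n_occurrences:
            raise ValueError(
                f"species {name!r}: requested {cfg.n_occurrences} occurrences but only "
                f"{int(eligible.sum())} suitable cells")
        # Efraimidis–Spirakis: weighted sampling without replacement via Gumbel keys
        keys = np.full(weights.size, -np.inf)
        keys[eligible] = np.log(weights[eligible]) + occ_rng.gumbel(size=int(eligible.sum()))
        chosen = np.argpartition(keys, -cfg.n_occurrences)[-cfg.n_occurrences:]
        pts = np.column_stack([xs.ravel()[chosen], ys.ravel()[chosen]])
        occurrences.append(OccurrenceSet(name, pts))
    return truths, occurrences


def simulate_protected_areas(
    cfg: SimulationConfig, seed: int | None = None, max_tries: int = 20_000
) -> tuple[MaskLayer, list]:
    """Union of random non-overlapping rectangles covering pa_fraction ± 0.02."""
    if not 0.0 < cfg.pa_fraction < 1.0:
        raise ValueError("pa_fraction must lie in (0, 1)")
    rng = np.random.default_rng(cfg._seeds()["pa"] if seed is None else seed)
    grid = cfg.grid
    total = grid.n_rows * grid.n_cols
    target = cfg.pa_fraction * total
    tol = 0.02 * total
    occupied = np.zeros(grid.shape, dtype=bool)
    polygons = []
    covered = 0
    tries = 0
    while covered < max(target - tol, 1) and tries < max_tries:
        tries += 1
        remaining = target + tol - covered
        max_side = max(2, int(min(np.sqrt(remaining), grid.n_rows // 4, grid.n_cols // 4)))
        h = int(rng.integers(2, max_side + 1))
        w = int(rng.integers(2, max_side + 1))
        r = int(rng.integers(0, grid.n_rows - h + 1))
        c = int(rng.integers(0, grid.n_cols - w + 1))
        if occupied[r:r + h, c:c + w].any():
            continue
        if covered + h * w > target + tol:
            continue
        occupied[r:r + h, c:c + w] = True
        covered += h * w
        x0, y0 = grid.origin_x + c * grid.cell_size, grid.origin_y - (r + h) * grid.cell_size
        x1, y1 = grid.origin_x + (c + w) * grid.cell_size, grid.origin_y - r * grid.cell_size
        polygons.append(box(x0, y0, x1, y1))
    if covered < target - tol:
        raise ValueError(
            f"could not reach protected fraction {cfg.pa_fraction} ± 0.02 "
            f"after {max_tries} placements")
    return MaskLayer(grid, occupied.astype(float), "protected_area"), polygons


def _assign_focal_tips(tree: Phylogeny, truths: list[SpeciesTruth]) -> Phylogeny:
    """Relabel tips so core-affine species sit on the least-nested tips.

    Tips with fewer branches on their root path have higher single-species
    relative PD; giving them to core-affine species plants the RPD gradient
    alongside the richness gradient.
    """
    focal = [t for t in truths if not t.is_indicator]
    order = sorted(focal, key=lambda t: (not t.is_core, t.species))
    counts = tree.tip_edge_counts()
    tips_by_depth = sorted(tree.tips, key=lambda tip: (counts[tip], tip))
    mapping = {tip: f"__tmp_{i}" for i, tip in enumerate(tips_by_depth)}
    final = {f"__tmp_{i}": truth.species for i, truth in enumerate(order)}
    return tree.rename_tips(mapping).rename_tips(final)


def simulate_world(cfg: SimulationConfig) -> World:
    """Generate the full synthetic study system from one master seed."""
    seeds = cfg._seeds()
    stack, contemporary = simulate_climate_history(cfg, seeds["climate"])
    truths, occurrences = simulate_species(
        cfg, contemporary, seeds["species"], seeds["occurrences"])

    tree = simulate_phylogeny(cfg.n_focal, seeds["phylogeny"])
    tree = _assign_focal_tips(tree, truths)

    # tree density reflects long-term forest suitability (gradient climate),
    # not the contemporary anomaly: tree stands integrate decades of climate
    base_b1, base_b12 = _base_climate(cfg)
    grid = cfg.grid
    base_climate = {
        "BIO1": RasterLayer(grid, base_b1, "BIO1"),
        "BIO12": RasterLayer(grid, base_b12, "BIO12"),
    }
    indicator = [t for t in truths if t.is_indicator]
    mean_suit = np.mean([t.suitability(base_climate).values for t in indicator], axis=0)
    td_rng = np.random.default_rng(seeds["tree_density"])
    density = np.clip(
        cfg.tree_density_scale * mean_suit
        + td_rng.standard_normal(grid.shape) * cfg.tree_density_noise,
        0.0, None)
    contemporary = dict(contemporary)
    contemporary["tree_density"] = RasterLayer(grid, density, "tree_density")

    pa_mask, pa_polygons = simulate_protected_areas(cfg, seeds["pa"])
    return World(
        config=cfg,
        grid=grid,
        stack=stack,
        contemporary=contemporary,
        truths=truths,
        occurrences=occurrences,
        tree=tree,
        pa_mask=pa_mask,
        pa_polygons=pa_polygons,
        core_mask=cfg.core_mask(),
    )
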