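"""Forest-stability surfaces, refugia delineation, and distance-to-refugium.

The stability surface stacks thresholded per-species hindcasts: for each cell,
count the (species, slice) pairs in which the cell was suitable; normalized by
S·T this is a 0–1 spatio-temporal estimate of habitat persistence. Refugia are
nested binary categories: a cell belongs to the fraction-``p`` refugium when
at least ``ceil(p·S)`` species were each suitable there in ``τ`` or more of
the T slices.

The climate-stability statistic is independent of any niche model: per cell,
the mean over consecutive slice pairs of (SD of the pair / elapsed time),
inverted and rescaled to [0, 1] by its maximum. Cells whose series never
change get stability 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .grid import Grid, MaskLayer, RasterLayer, TimeSliceStack, require_same_grid

__all__ = [
    "PersistenceTable",
    "StabilityMap",
    "RefugiaSet",
    "ClimateStabilitySurface",
    "build_persistence",
    "stack_stability",
    "delineate_refugia",
    "refugia_set",
    "climate_stability",
    "distance_to_refugia",
]

REFUGIA_FRACTIONS = (0.50, 0.75, 0.90, 0.95)


@dataclass
class PersistenceTable:
    """Per cell and species: number of slices in which the species is suitable."""

    grid: Grid
    species: list[str]
    counts: np.ndarray  # (S, n_rows, n_cols) int
    n_slices: int

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.species), *self.grid.shape):
            raise ValueError("persistence counts shape mismatch")
        if self.counts.min() < 0 or self.counts.max() > self.n_slices:
            raise ValueError("persistence entries must lie in [0, T]")

    @property
    def n_species(self) -> int:
        return len(self.species)


@dataclass
class StabilityMap:
    """Summed (species × slice) suitability counts and their 0–1 normalization."""

    grid: Grid
    counts: np.ndarray
    n_species: int
    n_slices: int

    @property
    def normalized(self) -> np.ndarray:
        return self.counts / (self.n_species * self.n_slices)

    def as_raster(self) -> RasterLayer:
        return RasterLayer(self.grid, self.normalized.astype(float), "forest_stability")


@dataclass
class RefugiaSet:
    """Nested refugia masks keyed by species fraction, sharing one slice cutoff."""

    masks: dict[float, MaskLayer]
    tau: int

    def __post_init__(self) -> None:
        fracs = sorted(self.masks, reverse=True)
        for stricter, looser in zip(fracs, fracs[1:]):
            a = self.masks[stricter].bool_array
            b = self.masks[looser].bool_array
            if np.any(a & ~b):
                raise ValueError(f"refugia not nested: {stricter} ⊄ {looser}")

    def strictest(self) -> MaskLayer:
        return self.masks[max(self.masks)]


@dataclass
class ClimateStabilitySurface:
    """Per-cell deviation through time and its inverted, rescaled stability."""

    grid: Grid
    variable: str
    deviation: np.ndarray
    stability: np.ndarray

    def as_raster(self) -> RasterLayer:
        return RasterLayer(self.grid, self.stability, f"{self.variable}_stability")


def build_persistence(binary_maps: dict[str, list[MaskLayer]]) -> PersistenceTable:
    """Count suitable slices per cell and species from thresholded hindcasts.

    ``binary_maps`` maps species → one mask per slice; every species must have
    a mask for every slice. Nodata cells never count as suitable.
    """
    if not binary_maps:
        raise ValueError("no binary maps given")
    species = list(binary_maps)
    n_slices = len(binary_maps[species[0]])
    grid = binary_maps[species[0]][0].grid
    counts = np.zeros((len(species), *grid.shape), dtype=np.int32)
    for i, sp in enumerate(species):
        maps = binary_maps[sp]
        if len(maps) != n_slices:
            raise ValueError(f"species {sp!r} has {len(maps)} slices, expected {n_slices}")
        for m in maps:
            require_same_grid(grid, m.grid, f"slice mask of {sp!r}")
            counts[i] += m.bool_array
    return PersistenceTable(grid, species, counts, n_slices)


def stack_stability(table: PersistenceTable) -> StabilityMap:
    """Sum persistence over species into the spatio-temporal stability map."""
    return StabilityMap(
        grid=table.grid,
        counts=table.counts.sum(axis=0),
        n_species=table.n_species,
        n_slices=table.n_slices,
    )


def _required_species(p: float, n_species: int) -> int:
    # strict reading of "p% of species present": round fractional counts up
    return math.ceil(p * n_species - 1e-9)


def delineate_refugia(table: PersistenceTable, p: float, tau: int) -> MaskLayer:
    """Cells where ≥ ceil(p·S) species each persisted ≥ τ slices."""
    if not 0.0 < p <= 1.0:
        raise ValueError("species fraction p must lie in (0, 1]")
    if not 1 <= tau <= table.n_slices:
        raise ValueError(f"slice cutoff τ={tau} outside [1, {table.n_slices}]")
    need = _required_species(p, table.n_species)
    n_persistent = (table.counts >= tau).sum(axis=0)
    return MaskLayer(table.grid, (n_persistent >= need).astype(float), "refugium")


def refugia_set(table: PersistenceTable, fractions=REFUGIA_FRACTIONS, tau: int = 230) -> RefugiaSet:
    """Nested refugia for all species fractions at one slice cutoff."""
    masks = {float(p): delineate_refugia(table, p, tau) for p in fractions}
    return RefugiaSet(masks, tau)


def climate_stability(stack: TimeSliceStack, variable: str) -> ClimateStabilitySurface:
    """Inverse mean deviation of a climate variable through the paleo stack.

    For each consecutive age pair the deviation is the SD of the two values
    (|Δ|/2) divided by the elapsed time; the per-cell deviation is the mean
    over the T−1 pairs. Stability is 1/deviation rescaled by its finite
    maximum; zero-deviation cells map to exactly 1.
    """
    if stack.n_slices < 2:
        raise ValueError("climate stability needs at least two time slices")
    layers = stack.layers[variable]
    cube = np.stack([l.values for l in layers])  # (T, R, C)
    ages = np.asarray(stack.ages, dtype=float)
    gaps = np.abs(np.diff(ages))[:, None, None]
    pair_sd = np.abs(np.diff(cube, axis=0)) / 2.0
    deviation = (pair_sd / gaps).mean(axis=0)
    with np.errstate(divide="ignore"):
        inv = np.where(deviation > 0, 1.0 / deviation, np.inf)
    finite = np.isfinite(inv) & ~np.isnan(deviation)
    if finite.any():
        peak = inv[finite].max()
        stab = np.where(finite, inv / peak, 1.0)
    else:
        stab = np.ones_like(deviation)
    stab = np.minimum(stab, 1.0)
    stab[np.isnan(deviation)] = np.nan
    return ClimateStabilitySurface(stack.grid, variable, deviation, stab)


def distance_to_refugia(refugium: MaskLayer) -> RasterLayer:
    """Center-to-center Euclidean distance (km) to the nearest refugium cell."""
    inside = refugium.bool_array
    if not inside.any():
        raise ValueError("refugium mask is empty")
    cell_km = refugium.grid.cell_size_km
    dist = distance_transform_edt(~inside) * cell_km
    return RasterLayer(refugium.grid, dist.astype(float), "distance_to_refugium")
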