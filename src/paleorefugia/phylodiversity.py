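"""Spatial phylogenetic diversity: SR, Faith PD, relative PD, and PE.

All four metrics are computed per sampling unit (grid cell) from a stack of
per-species presence masks and a rooted phylogeny.

* **SR** — number of species present in the cell.
* **PD** (Faith) — summed length of every branch whose descendant tips
  intersect the cell's species set, root-inclusive: a single species scores
  its full root-to-tip path.
* **RPD** — PD on the true tree divided by PD on a comparison tree of the same
  topology whose branches all equal ``total_length / n_branches``. Total
  length is preserved, so a cell holding the full assemblage has RPD = 1;
  values above/below 1 flag assemblages of unusually long/short branches.
* **PE** — per cell, sum over branches present of ``L_b / range_b`` where
  ``range_b`` is the number of cells (over the PE extent, which may exceed the
  reporting extent) occupied by at least one descendant tip of the branch.
  Summed over all cells of the PE extent, PE equals the total branch length of
  the occurring subtree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import Grid, MaskLayer, RasterLayer, require_same_grid
from .trees import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "AssemblageMatrix",
    "build_assemblages",
    "species_richness",
    "faith_pd",
    "relative_pd",
    "phylogenetic_endemism",
    "pd_surface",
    "diversity_maps",
    "normalize_metric",
    "equalize_branches",
    "graft_taxon",
]

Extent = tuple[int, int, int, int]  # row0, row1, col0, col1 (half-open)


@dataclass
class AssemblageMatrix:
    """Cells × species presences plus per-species range sizes.

    ``presence`` covers the PE extent (the full species masks by default);
    ``report`` marks which of those cells fall inside the reporting extent.
    Range sizes are occupied-cell counts over the PE extent, as required by
    phylogenetic endemism.
    """

    grid: Grid
    species: list[str]
    cells: np.ndarray       # (N, 2) row/col indices over the PE extent
    presence: np.ndarray    # (N, S) uint8
    report: np.ndarray      # (N,) bool, True inside the reporting extent
    extent: Extent

    @property
    def range_sizes(self) -> np.ndarray:
        return self.presence.sum(axis=0).astype(int)

    def species_set(self, i: int) -> set[str]:
        return {s for s, p in zip(self.species, self.presence[i]) if p}

    def to_raster(self, cell_values: np.ndarray, variable: str) -> RasterLayer:
        """Scatter per-cell values (reporting extent only) onto the grid."""
        values = np.full(self.grid.shape, np.nan)
        sel = self.cells[self.report]
        values[sel[:, 0], sel[:, 1]] = np.asarray(cell_values, dtype=float)[self.report]
        return RasterLayer(self.grid, values, variable)


def _full_extent(grid: Grid) -> Extent:
    return (0, grid.n_rows, 0, grid.n_cols)


def build_assemblages(
    species_masks: dict[str, MaskLayer],
    extent: Extent | None = None,
    pe_extent: Extent | None = None,
) -> AssemblageMatrix:
    """Stack per-species masks into an assemblage matrix.

    ``extent`` clips where metrics are reported; ``pe_extent`` (defaults to the
    whole grid) is where range sizes are counted. Species with empty masks are
    retained with range 0 and contribute to no cell.
    """
    if not species_masks:
        raise ValueError("no species masks given")
    species = list(species_masks)
    grids = [m.grid for m in species_masks.values()]
    grid = grids[0]
    for s, g in zip(species, grids):
        require_same_grid(grid, g, f"mask of {s!r}")
    pe_extent = pe_extent or _full_extent(grid)
    extent = extent or pe_extent
    r0, r1, c0, c1 = pe_extent
    rows, cols = np.mgrid[r0:r1, c0:c1]
    cells = np.column_stack([rows.ravel(), cols.ravel()])
    presence = np.column_stack(
        [species_masks[s].bool_array[r0:r1, c0:c1].ravel() for s in species]
    ).astype(np.uint8)
    er0, er1, ec0, ec1 = extent
    report = (
        (cells[:, 0] >= er0) & (cells[:, 0] < er1)
        & (cells[:, 1] >= ec0) & (cells[:, 1] < ec1)
    )
    empty = [s for s, n in zip(species, presence.sum(axis=0)) if n == 0]
    if empty:
        logger.info("species with empty masks (range 0, excluded from PE): %s", empty)
    return AssemblageMatrix(grid, species, cells, presence, report, extent)


# ---------------------------------------------------------------------------
# per-set metrics
# ---------------------------------------------------------------------------

def faith_pd(tree: Phylogeny, cell_species: set[str]) -> float:
    """Faith PD of a species set: root-inclusive spanning branch length."""
    unknown = set(cell_species) - set(tree.tips)
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")
    if not cell_species:
        return 0.0
    return sum(
        length for length, tips in tree.branches() if tips & cell_species
    )


def equalize_branches(tree: Phylogeny) -> Phylogeny:
    """Equal-branch-length comparison tree (total length preserved)."""
    return tree.equalized()


def graft_taxon(tree: Phylogeny, new_tip: str, sister, attach_age: float) -> Phylogeny:
    """Graft an unsequenced taxon next to its hypothesized sister at a given age."""
    return tree.graft(new_tip, sister, attach_age)


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def _branch_matrix(tree: Phylogeny, species: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and branch × species incidence for tree tips in ``species``."""
    branches = tree.branches()
    idx = {s: j for j, s in enumerate(species)}
    lengths = np.array([b[0] for b in branches])
    incidence = np.zeros((len(branches), len(species)), dtype=bool)
    for i, (_, tips) in enumerate(branches):
        for t in tips:
            j = idx.get(t)
            if j is not None:
                incidence[i, j] = True
    keep = incidence.any(axis=1)
    return lengths[keep], incidence[keep]


def _tree_species(tree: Phylogeny, asm: AssemblageMatrix) -> list[str]:
    tips = set(tree.tips)
    present = [s for s in asm.species if s in tips]
    missing = [s for s in asm.species if s not in tips]
    if missing:
        logger.info("species without tree tips, excluded from PD/RPD/PE: %s", missing)
    return present


def species_richness(asm: AssemblageMatrix) -> RasterLayer:
    """Per-cell species count (all species, including tipless ones)."""
    sr = asm.presence.sum(axis=1).astype(float)
    return asm.to_raster(sr, "SR")


def pd_surface(tree: Phylogeny, asm: AssemblageMatrix) -> RasterLayer:
    """Faith PD per cell; empty cells score 0."""
    species = _tree_species(tree, asm)
    cols = [asm.species.index(s) for s in species]
    lengths, inc = _branch_matrix(tree, species)
    present = asm.presence[:, cols].astype(bool)
    branch_in_cell = present @ inc.T > 0  # (N, n_branches)
    values = branch_in_cell @ lengths
    return asm.to_raster(values, "PD")


def relative_pd(tree: Phylogeny, asm: AssemblageMatrix) -> RasterLayer:
    """PD(true tree) / PD(equal-branch tree); empty cells are nodata."""
    pd_true = pd_surface(tree, asm).values
    pd_eq = pd_surface(tree.equalized(), asm).values
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(pd_eq > 0, pd_true / pd_eq, np.nan)
    return RasterLayer(asm.grid, values, "RPD")


def phylogenetic_endemism(tree: Phylogeny, asm: AssemblageMatrix) -> RasterLayer:
    """Range-weighted branch lengths per cell.

    Branch ranges are occupied-cell counts over the PE extent; a branch absent
    everywhere has no defined range and contributes nothing.
    """
    species = _tree_species(tree, asm)
    cols = [asm.species.index(s) for s in species]
    lengths, inc = _branch_matrix(tree, species)
    present = asm.presence[:, cols].astype(bool)
    branch_in_cell = present @ inc.T > 0
    branch_range = branch_in_cell.sum(axis=0)
    occurring = branch_range > 0
    weights = np.zeros_like(lengths)
    weights[occurring] = lengths[occurring] / branch_range[occurring]
    assert not np.any(branch_in_cell[:, ~occurring]), "zero-range branch present in a cell"
    values = branch_in_cell @ weights
    return asm.to_raster(values, "PE")


def normalize_metric(layer: RasterLayer) -> RasterLayer:
    """Rescale to [0, 1] by dividing by the maximum non-nodata value."""
    if not layer.valid.any():
        raise ValueError("layer has no non-nodata cells")
    peak = np.nanmax(layer.values)
    if peak == 0:
        warnings.warn(f"normalize_metric: {layer.variable or 'layer'} is all zero; unchanged")
        return layer.copy(variable=f"{layer.variable}_scaled")
    return layer.copy(values=layer.values / peak, variable=f"{layer.variable}_scaled")


def diversity_maps(tree: Phylogeny, asm: AssemblageMatrix) -> dict[str, RasterLayer]:
    """All four metrics, raw and 0–1 scaled, keyed SR/PD/RPD/PE (+ ``_scaled``)."""
    maps = {
        "SR": species_richness(asm),
        "PD": pd_surface(tree, asm),
        "RPD": relative_pd(tree, asm),
        "PE": phylogenetic_endemism(tree, asm),
    }
    for name in list(maps):
        maps[f"{name}_scaled"] = normalize_metric(maps[name])
    return maps
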