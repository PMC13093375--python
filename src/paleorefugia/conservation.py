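"""Refugia × protected-area gap analysis and protection scenarios.

Overlap and richness statistics are computed on the shared raster grid (cell
counts, not vector areas). The scenario experiment asks what mean per-cell
richness a protection network would sample: existing protected areas alone,
protected areas plus the strictest refugia, or protected areas plus a random
unprotected area of equal size (redrawn every replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import MaskLayer, RasterLayer, require_same_grid

__all__ = [
    "ScenarioResult",
    "overlap_fraction",
    "mean_richness_by_category",
    "protection_scenarios",
]

SCENARIOS = ("PA", "PA_plus_refugia", "PA_plus_random")


@dataclass
class ScenarioResult:
    """Replicate means of one protection scenario."""

    scenario: str
    replicate_means: np.ndarray

    @property
    def grand_mean(self) -> float:
        return float(np.mean(self.replicate_means))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicate_means, ddof=1))

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "grand_mean": self.grand_mean,
            "sd": self.sd,
            "replicate_means": np.asarray(self.replicate_means).tolist(),
        }


def overlap_fraction(refugium: MaskLayer, pa: MaskLayer) -> float:
    """Fraction of refugium cells that are protected."""
    require_same_grid(refugium.grid, pa.grid, "protected areas")
    ref = refugium.bool_array
    if not ref.any():
        raise ValueError("refugium mask is empty")
    return float((ref & pa.bool_array).sum() / ref.sum())


def mean_richness_by_category(richness: RasterLayer,
                              category_masks: dict[str, MaskLayer]) -> dict[str, float]:
    """Mean richness over each category's cells; empty categories are NaN."""
    out = {}
    for name, mask in category_masks.items():
        require_same_grid(richness.grid, mask.grid, f"category {name!r}")
        sel = mask.bool_array & richness.valid
        out[name] = float(richness.values[sel].mean()) if sel.any() else float("nan")
    return out


def protection_scenarios(
    richness: RasterLayer,
    pa: MaskLayer,
    refugium: MaskLayer,
    n_cells: int = 1000,
    n_reps: int = 100,
    seed: int = 0,
) -> list[ScenarioResult]:
    """Mean richness of resampled protection networks.

    Per replicate, ``n_cells`` cells are sampled without replacement from the
    scenario's pool and their mean richness recorded. Pools: protected cells;
    protected ∪ refugium cells; protected ∪ R with R a fresh uniform draw of
    unprotected cells matching the refugium's size. Reproducible from ``seed``.
    """
    require_same_grid(richness.grid, pa.grid, "protected areas")
    require_same_grid(richness.grid, refugium.grid, "refugium")
    valid = richness.valid
    pa_cells = pa.bool_array & valid
    ref_cells = refugium.bool_array & valid
    values = richness.values

    rng = np.random.default_rng(seed)
    flat_pa = np.flatnonzero(pa_cells)
    flat_union = np.flatnonzero(pa_cells | ref_cells)
    unprotected = np.flatnonzero(~pa_cells & valid)
    n_random = int(ref_cells.sum())

    for name, pool in (("PA", flat_pa), ("PA_plus_refugia", flat_union)):
        if pool.size < n_cells:
            raise ValueError(f"scenario {name!r}: pool of {pool.size} cells < n_cells={n_cells}")
    if flat_pa.size + n_random < n_cells:
        raise ValueError("scenario 'PA_plus_random': pool smaller than n_cells")
    if n_random > unprotected.size:
        raise ValueError("not enough unprotected cells to match the refugium area")

    flat_values = values.ravel()
    results = []
    for name in ("PA", "PA_plus_refugia"):
        pool = flat_pa if name == "PA" else flat_union
        means = np.array([
            flat_values[rng.choice(pool, size=n_cells, replace=False)].mean()
            for _ in range(n_reps)
        ])
        results.append(ScenarioResult(name, means))
    means = np.empty(n_reps)
    for r in range(n_reps):
        extra = rng.choice(unprotected, size=n_random, replace=False)
        pool = np.concatenate([flat_pa, extra])
        means[r] = flat_values[rng.choice(pool, size=n_cells, replace=False)].mean()
    results.append(ScenarioResult("PA_plus_random", means))
    return results
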