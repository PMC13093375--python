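"""Stability stacking, refugia delineation, and distance surfaces."""

import numpy as np
import pytest

from paleorefugia import stability
from paleorefugia.grid import Grid, MaskLayer, RasterLayer, TimeSliceStack

from conftest import make_mask


def mask_stack(grid, arrays):
    return [MaskLayer(grid, np.asarray(a, float), "range") for a in arrays]


def random_table(rng, n=8, shape=(6, 6), T=12) -> stability.PersistenceTable:
    grid = Grid(n_rows=shape[0], n_cols=shape[1], origin_y=shape[0] * 4.5)
    counts = rng.integers(0, T + 1, size=(n, *shape)).astype(np.int32)
    return stability.PersistenceTable(grid, [f"s{i}" for i in range(n)], counts, T)


# -- build_persistence / stack_stability --------------------------------------

def test_persistence_counts():
    grid = Grid(n_rows=2, n_cols=2, origin_y=9.0)
    always = mask_stack(grid, [np.ones((2, 2))] * 3)
    never = mask_stack(grid, [np.zeros((2, 2))] * 3)
    cellwise = mask_stack(grid, [[[1, 0], [0, 0]], [[0, 0], [0, 0]], [[1, 0], [0, 0]]])
    table = stability.build_persistence({"a": always, "b": never, "c": cellwise})
    assert np.all(table.counts[0] == 3)
    assert np.all(table.counts[1] == 0)
    assert table.counts[2][0, 0] == 2  # suitable in slices 1 and 3


def test_persistence_missing_slice_rejected():
    grid = Grid(n_rows=2, n_cols=2, origin_y=9.0)
    with pytest.raises(ValueError, match="slices"):
        stability.build_persistence({
            "a": mask_stack(grid, [np.ones((2, 2))] * 3),
            "b": mask_stack(grid, [np.ones((2, 2))] * 2),
        })


def test_stack_stability_arithmetic():
    grid = Grid(n_rows=1, n_cols=1, origin_y=4.5)
    counts = np.array([[[2]], [[3]]], dtype=np.int32)  # S=2, T=3
    table = stability.PersistenceTable(grid, ["a", "b"], counts, 3)
    stab = stability.stack_stability(table)
    assert stab.counts[0, 0] == 5
    assert stab.normalized[0, 0] == pytest.approx(5 / 6)


def test_stability_conservation_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(20):
        table = random_table(rng)
        stab = stability.stack_stability(table)
        np.testing.assert_array_equal(stab.counts, table.counts.sum(axis=0))
        assert stab.normalized.min() >= 0 and stab.normalized.max() <= 1


# -- delineate_refugia ---------------------------------------------------------

def test_refugia_required_species_count():
    rng = np.random.default_rng(1)
    table = random_table(rng, n=10, T=257)
    # ceil arithmetic: p=0.95, S=10 → all 10 species required
    cell_with_9 = (table.counts >= 230).sum(axis=0) == 9
    m95 = stability.delineate_refugia(table, 0.95, 230).bool_array
    m90 = stability.delineate_refugia(table, 0.90, 230).bool_array
    if cell_with_9.any():
        assert not m95[cell_with_9].any()   # 9 < ceil(9.5) = 10
        assert m90[cell_with_9].all()       # 9 ≥ ceil(9) = 9


def test_refugia_loosest_limit():
    rng = np.random.default_rng(2)
    table = random_table(rng, n=4, T=6)
    ever = (table.counts >= 1).any(axis=0)
    mask = stability.delineate_refugia(table, 1e-9, 1).bool_array
    np.testing.assert_array_equal(mask, ever)


def test_refugia_parameter_validation():
    table = random_table(np.random.default_rng(3))
    with pytest.raises(ValueError):
        stability.delineate_refugia(table, 0.0, 1)
    with pytest.raises(ValueError):
        stability.delineate_refugia(table, 0.5, table.n_slices + 1)


def test_refugia_nesting_in_p_and_tau():
    """mask(p₁) ⊆ mask(p₂) for p₁ > p₂; mask(τ₁) ⊆ mask(τ₂) for τ₁ > τ₂."""
    rng = np.random.default_rng(4)
    for _ in range(25):
        table = random_table(rng)
        tau = int(rng.integers(1, table.n_slices + 1))
        masks = {p: stability.delineate_refugia(table, p, tau).bool_array
                 for p in (0.5, 0.75, 0.9, 0.95)}
        assert np.all(masks[0.95] <= masks[0.9])
        assert np.all(masks[0.9] <= masks[0.75])
        assert np.all(masks[0.75] <= masks[0.5])
        t1, t2 = sorted(rng.integers(1, table.n_slices + 1, 2))
        a = stability.delineate_refugia(table, 0.75, int(t2)).bool_array
        b = stability.delineate_refugia(table, 0.75, int(t1)).bool_array
        assert np.all(a <= b)


def test_refugia_set_validates_nesting():
    rng = np.random.default_rng(5)
    table = random_table(rng)
    rs = stability.refugia_set(table, tau=6)
    assert rs.strictest() is rs.masks[0.95]


# -- climate_stability ---------------------------------------------------------

def make_stack(cubes, ages, cell=4.5):
    grid = Grid(n_rows=cubes[0].shape[0], n_cols=cubes[0].shape[1],
                origin_y=cubes[0].shape[0] * cell, cell_size=cell)
    layers = {"BIO1": [RasterLayer(grid, c, "BIO1") for c in cubes]}
    return TimeSliceStack(grid, ages, layers)


def test_climate_stability_constant_series_scores_one():
    cubes = [np.full((2, 2), 7.0) for _ in range(5)]
    surf = stability.climate_stability(make_stack(cubes, [50, 40, 30, 20, 10]), "BIO1")
    np.testing.assert_allclose(surf.stability, 1.0)
    np.testing.assert_allclose(surf.deviation, 0.0)


def test_climate_stability_pair_sd_ratio():
    # one cell changes by 2 per step, the other by 1: deviation ratio 2:1,
    # so after rescaling the steadier cell scores exactly 0.5
    cubes = [np.array([[0.0, 0.0]]) , np.array([[2.0, 1.0]]), np.array([[0.0, 0.0]]),
             np.array([[2.0, 1.0]])]
    surf = stability.climate_stability(make_stack(cubes, [40, 30, 20, 10]), "BIO1")
    assert surf.deviation[0, 0] == pytest.approx(2 * surf.deviation[0, 1])
    assert surf.stability[0, 1] == pytest.approx(1.0)
    assert surf.stability[0, 0] == pytest.approx(0.5)


def test_climate_stability_gap_scaling_invariance():
    rng = np.random.default_rng(6)
    cubes = [rng.random((3, 3)) for _ in range(6)]
    ages1 = [60, 50, 40, 30, 20, 10]
    ages2 = [120, 100, 80, 60, 40, 20]  # every gap doubled
    s1 = stability.climate_stability(make_stack(cubes, ages1), "BIO1")
    s2 = stability.climate_stability(make_stack(cubes, ages2), "BIO1")
    np.testing.assert_allclose(s2.deviation, s1.deviation / 2, atol=1e-12)
    np.testing.assert_allclose(s2.stability, s1.stability, atol=1e-12)


def test_climate_stability_shift_and_scale_invariance():
    rng = np.random.default_rng(7)
    cubes = [rng.random((3, 3)) for _ in range(5)]
    ages = [50, 40, 30, 20, 10]
    base = stability.climate_stability(make_stack(cubes, ages), "BIO1")
    shifted = stability.climate_stability(
        make_stack([c + 100.0 for c in cubes], ages), "BIO1")
    np.testing.assert_allclose(shifted.stability, base.stability, atol=1e-9)
    scaled = stability.climate_stability(
        make_stack([c * 3.0 for c in cubes], ages), "BIO1")
    np.testing.assert_allclose(scaled.deviation, base.deviation * 3.0, atol=1e-9)
    np.testing.assert_allclose(scaled.stability, base.stability, atol=1e-9)


def test_climate_stability_needs_two_slices():
    with pytest.raises(ValueError):
        stability.climate_stability(make_stack([np.zeros((2, 2))], [20]), "BIO1")


# -- distance_to_refugia --------------------------------------------------------

def test_distance_examples():
    vals = np.zeros((5, 5))
    vals[2, 2] = 1
    mask = make_mask(vals, role="refugium")
    dist = stability.distance_to_refugia(mask).values
    assert dist[2, 2] == 0.0
    assert dist[2, 3] == pytest.approx(4.5)  # 4-adjacent cell
    assert dist[0, 0] == pytest.approx(np.hypot(2, 2) * 4.5)


def test_distance_matches_bruteforce_on_20x20():
    rng = np.random.default_rng(9)
    vals = (rng.random((20, 20)) < 0.05).astype(float)
    vals[7, 13] = 1  # ensure nonempty
    mask = make_mask(vals, role="refugium")
    dist = stability.distance_to_refugia(mask).values
    ones = np.argwhere(vals == 1)
    for r in range(20):
        for c in range(20):
            expected = min(np.hypot(r - a, c - b) for a, b in ones) * 4.5
            assert dist[r, c] == pytest.approx(expected, abs=1e-9)


def test_distance_empty_mask_rejected():
    with pytest.raises(ValueError, match="empty"):
        stability.distance_to_refugia(make_mask(np.zeros((3, 3)), role="refugium"))
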