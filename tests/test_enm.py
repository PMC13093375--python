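"""Niche-model fitting, screening, thresholding and projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleorefugia import enm
from paleorefugia.grid import Grid, MaskLayer, OccurrenceSet, RasterLayer

from conftest import make_layer, make_mask


def gradient_climate(n=30, cell=4.5):
    """Monotone BIO1 gradient across columns, BIO12 across rows."""
    grid = Grid(n_rows=n, n_cols=n, origin_y=n * cell, cell_size=cell)
    cols = (np.arange(n) + 0.5) / n
    rows = (np.arange(n) + 0.5) / n
    b1 = np.broadcast_to(18 + 12 * cols, (n, n)).copy()
    b12 = np.broadcast_to((1200 + 1800 * rows)[:, None], (n, n)).copy()
    return {"BIO1": RasterLayer(grid, b1, "BIO1"), "BIO12": RasterLayer(grid, b12, "BIO12")}


def occurrences_at(grid, cells, species="sp"):
    pts = np.array([grid.center_of(r, c) for r, c in cells])
    return OccurrenceSet(species, pts)


# -- evaluate_auc ------------------------------------------------------------

def test_auc_examples():
    assert enm.evaluate_auc([0.9, 0.8], [0.1, 0.2]) == 1.0
    assert enm.evaluate_auc([0.5, 0.5], [0.5, 0.5]) == 0.5
    # enumerate the 4 pairs: 3 wins, 1 loss
    assert enm.evaluate_auc([0.9, 0.8], [0.7, 0.85]) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        enm.evaluate_auc([], [0.5])


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    pres, back = rng.normal(1, 1, 40), rng.normal(0, 1, 60)
    base = enm.evaluate_auc(pres, back)
    for f in (np.exp, lambda x: x**3, lambda x: 1 / (1 + np.exp(-x))):
        assert enm.evaluate_auc(f(pres), f(back)) == pytest.approx(base, abs=1e-12)


# -- minimum_occurrence_threshold -------------------------------------------

def test_threshold_nearest_rank_examples():
    values = np.arange(1, 21) * 0.05  # 0.05 … 1.00
    assert enm.minimum_occurrence_threshold(values) == pytest.approx(0.05)
    assert enm.minimum_occurrence_threshold([0.3] * 7) == pytest.approx(0.3)
    assert enm.minimum_occurrence_threshold([0.42]) == pytest.approx(0.42)
    with pytest.raises(ValueError):
        enm.minimum_occurrence_threshold([])


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=400))
def test_threshold_guarantees_95pct_coverage(values):
    thr = enm.minimum_occurrence_threshold(values)
    covered = np.mean(np.asarray(values) >= thr)
    assert covered >= 0.95


# -- fit_enm -----------------------------------------------------------------

def test_fit_monotone_response_on_gradient():
    """Presences confined to the hottest cells → suitability rises with BIO1."""
    climate = gradient_climate()
    grid = climate["BIO1"].grid
    rng = np.random.default_rng(0)
    cells = [(int(r), int(c)) for r, c in
             zip(rng.integers(0, 30, 40), rng.integers(24, 30, 40))]
    occ = occurrences_at(grid, set(cells))
    model = enm.fit_enm(occ, climate, n_background=500, seed=1)
    suit = enm.project(model, climate).values
    col_means = suit.mean(axis=0)
    # strictly increasing along the temperature gradient over the data range
    assert np.all(np.diff(col_means[:25]) > 0)


def test_fit_random_presences_rejected_by_auc():
    climate = gradient_climate()
    rng = np.random.default_rng(5)
    cells = {(int(r), int(c)) for r, c in zip(rng.integers(0, 30, 500),
                                              rng.integers(0, 30, 500))}
    occ = occurrences_at(climate["BIO1"].grid, cells)
    model = enm.fit_enm(occ, climate, n_background=500, seed=2)
    assert 0.4 <= model.auc <= 0.6
    assert model.status == "rejected_auc"


def test_fit_too_few_records():
    climate = gradient_climate()
    occ = occurrences_at(climate["BIO1"].grid, [(i, i) for i in range(10)])
    model = enm.fit_enm(occ, climate)
    assert model.status == "rejected_records"
    assert model.coefficients is None


def test_fit_degenerate_climate():
    climate = gradient_climate()
    flat = {"BIO1": climate["BIO1"].copy(values=np.ones(climate["BIO1"].grid.shape)),
            "BIO12": climate["BIO12"]}
    occ = occurrences_at(climate["BIO1"].grid, [(i, i) for i in range(15)])
    with pytest.raises(ValueError, match="zero variance"):
        enm.fit_enm(occ, flat)


def test_large_penalty_flattens_suitability():
    climate = gradient_climate()
    grid = climate["BIO1"].grid
    occ = occurrences_at(grid, [(i, 25) for i in range(15)])
    model = enm.fit_enm(occ, climate, n_background=500, reg=1e9, seed=3,
                        auc_cutoff=0.0)
    suit = enm.project(model, climate).values
    assert np.ptp(suit) < 1e-3  # coefficients → 0, suitability → constant


def test_fit_is_deterministic():
    climate = gradient_climate()
    occ = occurrences_at(climate["BIO1"].grid, [(i, 20 + i % 5) for i in range(20)])
    a = enm.fit_enm(occ, climate, n_background=300, seed=11)
    b = enm.fit_enm(occ, climate, n_background=300, seed=11)
    np.testing.assert_array_equal(a.coefficients, b.coefficients)
    assert a.threshold == b.threshold and a.auc == b.auc


# -- project -----------------------------------------------------------------

def fitted_model():
    climate = gradient_climate()
    occ = occurrences_at(climate["BIO1"].grid,
                         [(12 + i % 6, 12 + i // 6) for i in range(24)])
    return enm.fit_enm(occ, climate, n_background=500, seed=4), climate


def test_projection_identity_and_determinism():
    model, climate = fitted_model()
    a = enm.project(model, climate)
    b = enm.project(model, climate)
    np.testing.assert_array_equal(a.values, b.values)
    assert a.values.min() >= 0 and a.values.max() <= 1


def test_projection_extreme_climate_never_nan():
    model, climate = fitted_model()
    grid = climate["BIO1"].grid
    extreme = {
        "BIO1": RasterLayer(grid, np.full(grid.shape, 1e4), "BIO1"),
        "BIO12": RasterLayer(grid, np.full(grid.shape, -1e6), "BIO12"),
    }
    suit = enm.project(model, extreme).values
    assert np.isfinite(suit).all()
    assert ((suit <= 1e-9) | (suit >= 1 - 1e-9)).all()


def test_projection_requires_accepted_model_and_variables():
    model, climate = fitted_model()
    with pytest.raises(ValueError, match="missing"):
        enm.project(model, {"BIO1": climate["BIO1"]})
    model.status = "rejected_auc"
    with pytest.raises(ValueError, match="not accepted"):
        enm.project(model, climate)


# -- binarize ----------------------------------------------------------------

def test_binarize_examples():
    layer = make_layer([[0.2, 0.5], [0.7, 0.4]])
    mask = enm.binarize(layer, 0.5)
    np.testing.assert_array_equal(mask.values, [[0, 1], [1, 0]])
    assert enm.binarize(layer, 0.0).count() == 4
    assert enm.binarize(layer, 0.9).count() == 0
    nd = make_layer([[0.9, np.nan]])
    assert np.isnan(enm.binarize(nd, 0.5).values[0, 1])


def test_binarize_monotone_in_threshold():
    rng = np.random.default_rng(8)
    layer = make_layer(rng.random((6, 6)))
    prev = enm.binarize(layer, 0.2).bool_array
    for thr in (0.4, 0.6, 0.8):
        cur = enm.binarize(layer, thr).bool_array
        assert np.all(cur <= prev)  # stricter thresholds nest
        prev = cur


# -- buffer_restrict ----------------------------------------------------------

def test_buffer_restrict_examples():
    suit = make_layer(np.ones((9, 9)))
    center = np.zeros((9, 9))
    center[4, 4] = 1
    mask = make_mask(center, role="range")
    # buffer 0: only range cells kept
    kept0 = enm.buffer_restrict(suit, mask, 0.0)
    assert kept0.values.sum() == 1
    # buffer larger than the grid diagonal: unchanged
    keptall = enm.buffer_restrict(suit, mask, 1e4)
    assert keptall.values.sum() == 81
    # 10 km buffer on a 4.5 km grid: brute-force center distances
    kept = enm.buffer_restrict(suit, mask, 10.0)
    expected = sum(
        1 for r in range(9) for c in range(9)
        if np.hypot(r - 4, c - 4) * 4.5 <= 10.0
    )
    assert expected == 13
    assert kept.values.sum() == expected


def test_buffer_restrict_empty_range_warns():
    suit = make_layer(np.ones((3, 3)))
    empty = make_mask(np.zeros((3, 3)), role="range")
    with pytest.warns(UserWarning, match="empty range"):
        out = enm.buffer_restrict(suit, empty, 10.0)
    assert out.values.sum() == 0


# -- parameter recovery on the synthetic world --------------------------------

def test_niche_optimum_recovery(default_world, default_result):
    """≥90% of species recover their optimum within 0.5 breadth units."""
    ok = tot = 0
    for truth in default_world.truths:
        model = default_result.models[truth.species]
        if not model.accepted:
            continue
        tot += 1
        err = np.abs(model.niche_optimum() - np.asarray(truth.niche_optimum))
        if np.all(err / np.asarray(truth.niche_breadth) <= 0.5):
            ok += 1
    assert tot >= 45
    assert ok / tot >= 0.9
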