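"""Diversity metrics against hand computations and a brute-force oracle."""

import random

import dendropy
import numpy as np
import pytest

from paleorefugia import phylodiversity as pdiv
from paleorefugia.grid import Grid, MaskLayer
from paleorefugia.trees import Phylogeny

from _bruteforce import bf_metrics, random_fixture
from conftest import WORKED_NEWICK, make_mask


def assemblage_from_presence(n_rows, n_cols, presence, species):
    grid = Grid(n_rows=n_rows, n_cols=n_cols, origin_y=n_rows * 4.5)
    masks = {}
    for sp in species:
        vals = np.zeros((n_rows, n_cols))
        for (r, c), spp in presence.items():
            if sp in spp:
                vals[r, c] = 1.0
        masks[sp] = MaskLayer(grid, vals, "range")
    return pdiv.build_assemblages(masks)


# -- worked examples on ((A:1,B:1):1,C:2) -----------------------------------

def test_faith_pd_worked_examples(worked_tree):
    assert pdiv.faith_pd(worked_tree, set()) == 0.0
    assert pdiv.faith_pd(worked_tree, {"A", "B", "C"}) == pytest.approx(5.0)
    # A, B and their shared stem
    assert pdiv.faith_pd(worked_tree, {"A", "B"}) == pytest.approx(3.0)
    assert pdiv.faith_pd(worked_tree, {"C"}) == pytest.approx(2.0)


def test_faith_pd_unknown_species(worked_tree):
    with pytest.raises(ValueError, match="Z"):
        pdiv.faith_pd(worked_tree, {"Z"})


def test_equalize_branches(worked_tree):
    eq = pdiv.equalize_branches(worked_tree)
    lengths = [l for l, _ in eq.branches()]
    assert lengths == pytest.approx([1.25] * 4)  # total 5 over 4 branches
    assert eq.total_length == pytest.approx(worked_tree.total_length, abs=1e-12)
    # idempotent on an already-equal tree
    eq2 = pdiv.equalize_branches(eq)
    assert [l for l, _ in eq2.branches()] == pytest.approx([1.25] * 4)


def test_rpd_worked_example(worked_tree):
    presence = {(0, 0): {"C"}, (0, 1): {"A", "B", "C"}}
    asm = assemblage_from_presence(1, 2, presence, ["A", "B", "C"])
    rpd = pdiv.relative_pd(worked_tree, asm)
    # cell {C}: the root-to-C path is one branch of length 2, so PD=2 and
    # PD_eq = 1 × 5/4 = 1.25 → RPD = 1.6 (confirmed by the brute-force
    # oracle's path enumeration); full assemblage → exactly 1
    assert rpd.values[0, 0] == pytest.approx(1.6)
    assert rpd.values[0, 1] == pytest.approx(1.0)


def test_rpd_is_one_everywhere_on_equal_branch_tree():
    tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    eq = pdiv.equalize_branches(tree)
    presence = {(0, 0): {"A"}, (0, 1): {"A", "C"}, (0, 2): {"B", "C", "D"}}
    asm = assemblage_from_presence(1, 3, presence, ["A", "B", "C", "D"])
    rpd = pdiv.relative_pd(eq, asm)
    np.testing.assert_allclose(rpd.values[0], 1.0)


def test_pe_star_tree_examples():
    star = Phylogeny.from_newick("(A:2,B:2,C:2);")
    # endemic to one cell: PE there = its branch length
    presence = {(0, 0): {"A"}, (0, 1): set(), (0, 2): set()}
    asm = assemblage_from_presence(1, 3, presence, ["A", "B", "C"])
    pe = pdiv.phylogenetic_endemism(star, asm)
    assert pe.values[0, 0] == pytest.approx(2.0)
    # occupying k cells: each receives L/k
    presence = {(0, 0): {"B"}, (0, 1): {"B"}, (0, 2): {"B"}, (0, 3): set()}
    asm = assemblage_from_presence(1, 4, presence, ["A", "B", "C"])
    pe = pdiv.phylogenetic_endemism(star, asm)
    np.testing.assert_allclose(pe.values[0, :3], 2.0 / 3.0)


def test_graft_cherry_example():
    cherry = Phylogeny.from_newick("(A:2,B:2);")
    grafted = cherry.graft("C", "A", attach_age=1.0)
    assert grafted.n_tips == 3
    assert grafted.total_length == pytest.approx(5.0)
    assert grafted.is_ultrametric(1e-9)
    assert pdiv.faith_pd(grafted, {"A", "C"}) == pytest.approx(3.0)  # ((A:1,C:1):1


def test_graft_boundary_and_errors(worked_tree):
    # at the full stem age the new tip joins at the stem node (zero stem edge)
    g = worked_tree.graft("D", "C", attach_age=2.0)
    assert g.is_ultrametric(1e-9)
    assert g.n_tips == 4
    with pytest.raises(ValueError, match="exceeds"):
        worked_tree.graft("E", "A", attach_age=1.5)  # A's stem node age is 1
    with pytest.raises(ValueError, match="duplicate"):
        worked_tree.graft("A", "C", attach_age=1.0)


def test_graft_onto_clade(worked_tree):
    g = worked_tree.graft("D", ["A", "B"], attach_age=1.5)
    assert g.is_ultrametric(1e-9)
    # D attaches on the (A,B) stem at age 1.5 with a 1.5-long pendant branch
    assert g.total_length == pytest.approx(5.0 + 1.5)


def test_pd_monotone_in_species(worked_tree):
    rng = random.Random(0)
    tips = worked_tree.tips
    for _ in range(20):
        s = {t for t in tips if rng.random() < 0.5}
        extra = rng.choice(tips)
        assert pdiv.faith_pd(worked_tree, s | {extra}) >= pdiv.faith_pd(worked_tree, s)


def test_normalize_metric(grid4):
    from conftest import make_layer

    layer = make_layer([[2.0, 5.0], [10.0, np.nan]])
    scaled = pdiv.normalize_metric(layer)
    np.testing.assert_allclose(scaled.values[:2, :2].ravel()[:3], [0.2, 0.5, 1.0])
    with pytest.warns(UserWarning, match="all zero"):
        pdiv.normalize_metric(make_layer([[0.0, 0.0]]))


def test_pe_extent_larger_than_reporting_extent():
    # species occupying 10 cells total, 4 inside the reporting extent:
    # range size must be 10 (counted over the PE extent)
    grid = Grid(n_rows=2, n_cols=5, origin_y=9.0)
    vals = np.ones((2, 5))
    masks = {"A": MaskLayer(grid, vals, "range")}
    asm = pdiv.build_assemblages(masks, extent=(0, 2, 0, 2))
    assert asm.range_sizes[0] == 10
    assert asm.report.sum() == 4
    star = Phylogeny.from_newick("(A:3,B:1);")
    pe = pdiv.phylogenetic_endemism(star, asm)
    reported = pe.values[~np.isnan(pe.values)]
    assert reported.shape == (4,)
    np.testing.assert_allclose(reported, 3.0 / 10.0)


def test_empty_species_kept_in_sr_excluded_from_pe(worked_tree):
    presence = {(0, 0): {"A"}, (0, 1): {"A", "C"}}
    asm = assemblage_from_presence(1, 2, presence, ["A", "B", "C"])
    assert asm.range_sizes[asm.species.index("B")] == 0
    sr = pdiv.species_richness(asm)
    np.testing.assert_array_equal(sr.values[0], [1, 2])
    pe = pdiv.phylogenetic_endemism(worked_tree, asm)
    assert np.isfinite(pe.values[0]).all()


def test_metrics_match_bruteforce_oracle():
    """SR/PD/RPD/PE equal explicit path enumeration on random fixtures."""
    rng = random.Random(7)
    for _ in range(30):
        newick, n_rows, n_cols, presence = random_fixture(rng)
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  preserve_underscores=True)
        expected = bf_metrics(dtree, presence)
        tree = Phylogeny.from_newick(newick)
        asm = assemblage_from_presence(n_rows, n_cols, presence, sorted(
            {sp for s in presence.values() for sp in s} | set(tree.tips)))
        maps = {
            "SR": pdiv.species_richness(asm).values,
            "PD": pdiv.pd_surface(tree, asm).values,
            "RPD": pdiv.relative_pd(tree, asm).values,
            "PE": pdiv.phylogenetic_endemism(tree, asm).values,
        }
        for (r, c), (sr, pd, rpd, pe) in expected.items():
            assert maps["SR"][r, c] == pytest.approx(sr, abs=1e-12)
            assert maps["PD"][r, c] == pytest.approx(pd, abs=1e-12)
            if np.isnan(rpd):
                assert np.isnan(maps["RPD"][r, c])
            else:
                assert maps["RPD"][r, c] == pytest.approx(rpd, abs=1e-12)
            assert maps["PE"][r, c] == pytest.approx(pe, abs=1e-12)


def test_pe_sums_to_occurring_subtree_length():
    """Conservation: ΣPE over the PE extent = total occurring branch length."""
    rng = random.Random(11)
    for _ in range(30):
        newick, n_rows, n_cols, presence = random_fixture(rng)
        tree = Phylogeny.from_newick(newick)
        asm = assemblage_from_presence(n_rows, n_cols, presence, sorted(tree.tips))
        pe = pdiv.phylogenetic_endemism(tree, asm)
        occurring = {sp for s in presence.values() for sp in s}
        total = sum(l for l, tips in tree.branches() if tips & occurring)
        assert np.nansum(pe.values) == pytest.approx(total, abs=1e-9)
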