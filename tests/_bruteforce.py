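"""Independent brute-force diversity metrics for oracle tests.

Deliberately shares no code with the package: trees are handled as raw
dendropy objects and every metric is computed by explicit root-to-tip path
enumeration over every cell, one species at a time.
"""

from __future__ import annotations

import random

import dendropy
import numpy as np


def _paths(tree: dendropy.Tree) -> dict[str, list]:
    """Root-to-tip edge lists per tip label."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        edges, node = [], leaf
        while node.parent_node is not None:
            edges.append(node.edge)
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    return paths


def _edges(tree: dendropy.Tree) -> list:
    return [n.edge for n in tree.preorder_node_iter() if n.parent_node is not None]


def bf_pd(tree: dendropy.Tree, species: set[str]) -> float:
    paths = _paths(tree)
    spanning = set()
    for sp in species:
        spanning.update(id(e) for e in paths[sp])
    lengths = {id(e): e.length for e in _edges(tree)}
    return sum(lengths[i] for i in spanning)


def bf_pd_equal(tree: dendropy.Tree, species: set[str]) -> float:
    """PD on the equal-branch comparison tree (total length preserved)."""
    edges = _edges(tree)
    equal = sum(e.length for e in edges) / len(edges)
    paths = _paths(tree)
    spanning = set()
    for sp in species:
        spanning.update(id(e) for e in paths[sp])
    return equal * len(spanning)


def bf_metrics(tree: dendropy.Tree, presence: dict[tuple, set[str]]):
    """SR, PD, RPD, PE per cell by enumeration.

    ``presence`` maps cell id → species set. PE branch ranges are counted over
    all cells of ``presence``.
    """
    paths = _paths(tree)
    edges = _edges(tree)
    ranges = {}
    for e in edges:
        ranges[id(e)] = sum(
            1 for cell, spp in presence.items()
            if any(e2 is e for sp in spp for e2 in paths[sp])
        )
    out = {}
    for cell, spp in presence.items():
        sr = float(len(spp))
        pd = bf_pd(tree, spp)
        pd_eq = bf_pd_equal(tree, spp)
        rpd = pd / pd_eq if pd_eq > 0 else np.nan
        spanning = set()
        for sp in spp:
            spanning.update(id(e) for e in paths[sp])
        pe = sum(e.length / ranges[id(e)] for e in edges if id(e) in spanning)
        out[cell] = (sr, pd, rpd, pe)
    return out


def random_tree(rng: random.Random, n_tips: int) -> str:
    """Random binary newick with random branch lengths."""
    nodes = [f"t{i}:{rng.uniform(0.1, 3.0):.6f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = rng.sample(range(len(nodes)), 2)
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b}):{rng.uniform(0.1, 3.0):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    # strip the root edge length
    return nodes[0].rsplit(":", 1)[0] + ";"


def random_fixture(rng: random.Random, max_tips: int = 8, max_dim: int = 5):
    """(newick, n_rows, n_cols, presence dict) with every species occurring."""
    n_tips = rng.randint(2, max_tips)
    newick = random_tree(rng, n_tips)
    n_rows = rng.randint(1, max_dim)
    n_cols = rng.randint(1, max_dim)
    species = [f"t{i}" for i in range(n_tips)]
    presence = {}
    for r in range(n_rows):
        for c in range(n_cols):
            presence[(r, c)] = {sp for sp in species if rng.random() < 0.4}
    # guarantee every species a nonempty range
    cells = list(presence)
    for sp in species:
        if not any(sp in s for s in presence.values()):
            presence[rng.choice(cells)].add(sp)
    return newick, n_rows, n_cols, presence
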