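"""Rooted ultrametric phylogeny wrapper.

Thin layer over :mod:`dendropy` exposing exactly what the diversity metrics
need: the branch index (every branch with its length and descendant tip set),
total tree length, tip-grafting for taxa without sequence data, and the
equal-branch-length comparison tree used by relative PD.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import dendropy

logger = logging.getLogger(__name__)

__all__ = ["Phylogeny"]


class Phylogeny:
    """Rooted tree with branch lengths and unique tip labels."""

    def __init__(self, tree: dendropy.Tree):
        if not tree.is_rooted and tree.is_rooted is not None:
            # dendropy records an explicit [&U] annotation as is_rooted=False
            raise ValueError("tree is explicitly unrooted; a rooted tree is required")
        tree.is_rooted = True
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip names: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue  # root edge carries no branch
            if edge.length is None:
                raise ValueError("tree has a branch without a length")
            if edge.length < 0:
                raise ValueError("negative branch length")
            if edge.length == 0:
                logger.warning("tree contains a zero-length branch (accepted)")
        self._tree = tree

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
            raise ValueError(f"duplicate tip names: {e}") from e
        return cls(tree)

    @classmethod
    def read(cls, path) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(path=str(path), schema="newick",
                                     preserve_underscores=True)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
            raise ValueError(f"duplicate tip names: {e}") from e
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def clone(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    # -- basic queries -----------------------------------------------------

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def branches(self) -> list[tuple[float, frozenset[str]]]:
        """Every branch as ``(length, descendant tip set)``, root edge excluded."""
        out = []
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            tips = frozenset(l.taxon.label for l in node.leaf_iter())
            out.append((float(node.edge.length), tips))
        return out

    @property
    def total_length(self) -> float:
        return sum(length for length, _ in self.branches())

    def root_to_tip_depths(self) -> dict[str, float]:
        depths = {}
        self._tree.calc_node_root_distances(return_leaf_distances_only=False)
        for leaf in self._tree.leaf_node_iter():
            depths[leaf.taxon.label] = float(leaf.root_distance)
        return depths

    def tip_edge_counts(self) -> dict[str, int]:
        """Number of branches on each tip's root-to-tip path (nesting depth)."""
        counts = {}
        for leaf in self._tree.leaf_node_iter():
            n, node = 0, leaf
            while node.parent_node is not None:
                n += 1
                node = node.parent_node
            counts[leaf.taxon.label] = n
        return counts

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.root_to_tip_depths().values())
        return max(depths) - min(depths) <= tol

    def rename_tips(self, mapping: dict[str, str]) -> "Phylogeny":
        """New phylogeny with tip labels replaced via ``mapping``."""
        clone = self._tree.clone(depth=1)
        for leaf in clone.leaf_node_iter():
            if leaf.taxon.label in mapping:
                leaf.taxon = dendropy.Taxon(label=mapping[leaf.taxon.label])
        clone.update_taxon_namespace()
        return Phylogeny(clone)

    # -- tree surgery ------------------------------------------------------

    def equalized(self) -> "Phylogeny":
        """Same topology with every branch set to total_length / n_branches.

        The comparison tree for relative PD: total length is preserved, so the
        full assemblage has RPD exactly 1.
        """
        clone = self._tree.clone(depth=1)
        edges = [n.edge for n in clone.preorder_node_iter() if n.parent_node is not None]
        total = sum(e.length for e in edges)
        equal = total / len(edges)
        for e in edges:
            e.length = equal
        return Phylogeny(clone)

    def graft(self, new_tip: str, sister: str | Sequence[str], attach_age: float) -> "Phylogeny":
        """Attach ``new_tip`` on the stem branch of ``sister`` at depth ``attach_age``.

        ``attach_age`` is time before present (same units as branch lengths).
        On an ultrametric tree the new tip's branch length equals
        ``attach_age``, preserving ultrametricity. ``sister`` may be a tip
        label or a collection of tip labels designating a clade (their MRCA).
        """
        if new_tip in self.tips:
            raise ValueError(f"duplicate tip label {new_tip!r}")
        if attach_age <= 0:
            raise ValueError("attach_age must be positive")
        clone = self._tree.clone(depth=1)
        if isinstance(sister, str):
            labels = [sister]
        else:
            labels = list(sister)
        taxa = [clone.taxon_namespace.get_taxon(l) for l in labels]
        if any(t is None for t in taxa):
            missing = [l for l, t in zip(labels, taxa) if t is None]
            raise ValueError(f"sister taxa not in tree: {missing}")
        node = clone.mrca(taxa=taxa)
        if node.parent_node is None:
            raise ValueError("cannot graft onto the root branch")

        clone.calc_node_root_distances(return_leaf_distances_only=False)
        height = max(l.root_distance for l in clone.leaf_node_iter())
        node_age = height - node.root_distance  # age of sister's crown node
        stem_age = node_age + node.edge.length  # age of sister's stem (parent) node
        if attach_age > stem_age + 1e-12:
            raise ValueError(
                f"attach_age {attach_age} exceeds the sister stem node age {stem_age}"
            )
        if attach_age < node_age - 1e-12:
            raise ValueError(
                f"attach_age {attach_age} is younger than the sister crown age {node_age}"
            )

        parent = node.parent_node
        split = dendropy.Node()
        split.edge.length = stem_age - attach_age
        parent.remove_child(node)
        parent.add_child(split)
        node.edge.length = attach_age - node_age
        split.add_child(node)
        taxon = dendropy.Taxon(label=new_tip)
        clone.taxon_namespace.add_taxon(taxon)
        tip = dendropy.Node(taxon=taxon)
        tip.edge.length = attach_age
        split.add_child(tip)
        clone.update_taxon_namespace()
        return Phylogeny(clone)
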