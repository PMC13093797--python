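"""Faith's phylogenetic diversity on a fixed haplotype tree.

PD for a set of tips is the sum of branch lengths of the tree structure
connecting those tips.  Two conventions are supported:

``root_inclusive`` (default)
    Sum over every edge that lies on a path from a subset tip to the root,
    i.e. the minimal spanning subtree plus the path from the subset's MRCA
    up to the root.  A singleton's PD is its tip-to-root path length.  This
    matches the common default of R phylogenetic-diversity tooling and is
    the convention consistent with strictly positive PD values on
    single-haplotype islands.

``mrca_subtree``
    Sum over the minimal spanning subtree only; a singleton's PD is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import pandas as pd

__all__ = ["PhyloTree", "PDResult", "faith_pd", "pd_by_island"]

CONVENTIONS = ("root_inclusive", "mrca_subtree")


@dataclass
class PDResult:
    subset: frozenset[str]
    pd: float
    convention: str


class PhyloTree:
    """Rooted tree with unique tip labels and mandatory branch lengths.

    Wraps a :class:`dendropy.Tree`; parent pointers and a label->leaf map
    are prepared once so repeated PD queries stay cheap.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._leaf: dict[str, dendropy.Node] = {}
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else leaf.label
            if label is None:
                raise ValueError("tree has an unlabelled tip")
            label = label.replace(" ", "_")
            if label in self._leaf:
                raise ValueError(f"duplicate tip label {label!r}")
            self._leaf[label] = leaf
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                raise ValueError(
                    "tree has an edge without a branch length; lengths are required"
                )

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    @property
    def tip_labels(self) -> list[str]:
        return list(self._leaf)

    @property
    def n_tips(self) -> int:
        return len(self._leaf)

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self._tree.preorder_edge_iter()
        )

    def _edge_len(self, node: dendropy.Node) -> float:
        return node.edge.length or 0.0

    def faith_pd(self, subset: Iterable[str], convention: str = "root_inclusive") -> float:
        """Faith's PD of ``subset`` under the given convention."""
        if convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {convention!r}")
        tips = list(dict.fromkeys(subset))
        if not tips:
            raise ValueError("empty tip subset")
        unknown = [t for t in tips if t not in self._leaf]
        if unknown:
            raise KeyError(f"tip label(s) not in tree: {unknown}")

        # union of tip-to-root paths; visit counts locate the MRCA
        marked: set[int] = set()
        total = 0.0
        visits: dict[int, int] = {}
        nodes: dict[int, dendropy.Node] = {}
        for t in tips:
            node = self._leaf[t]
            while node is not None:
                nid = id(node)
                visits[nid] = visits.get(nid, 0) + 1
                nodes[nid] = node
                if nid in marked:
                    # ancestors already counted; still bump their visit tally
                    anc = node.parent_node
                    while anc is not None:
                        visits[id(anc)] = visits.get(id(anc), 0) + 1
                        nodes[id(anc)] = anc
                        anc = anc.parent_node
                    break
                marked.add(nid)
                if node.parent_node is not None:
                    total += self._edge_len(node)
                node = node.parent_node

        if convention == "root_inclusive":
            return total
        # deepest node through which every tip path passes
        k = len(tips)
        mrca = self._tree.seed_node
        node = self._leaf[tips[0]]
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        for node in chain:  # tip upward: first all-visits node is the MRCA
            if visits.get(id(node), 0) >= k:
                mrca = node
                break
        root_path = 0.0
        node = mrca
        while node.parent_node is not None:
            root_path += self._edge_len(node)
            node = node.parent_node
        return total - root_path


def faith_pd(
    tree: PhyloTree | dendropy.Tree | str,
    subset: Iterable[str],
    convention: str = "root_inclusive",
) -> PDResult:
    """Functional wrapper returning a :class:`PDResult`."""
    pt = _as_phylo(tree)
    subset = frozenset(subset)
    return PDResult(subset=subset, pd=pt.faith_pd(subset, convention), convention=convention)


def _as_phylo(tree) -> PhyloTree:
    if isinstance(tree, PhyloTree):
        return tree
    if isinstance(tree, dendropy.Tree):
        return PhyloTree(tree)
    return PhyloTree.from_newick(tree)


def pd_by_island(
    tree: PhyloTree | dendropy.Tree | str,
    occurrence: pd.DataFrame,
    convention: str = "root_inclusive",
) -> pd.Series:
    """Faith's PD of each island's present-haplotype set.

    ``occurrence`` is a haplotype-by-island count matrix.  Islands with no
    haplotypes are excluded (with a warning).
    """
    import warnings

    pt = _as_phylo(tree)
    out: dict[str, float] = {}
    for island in occurrence.columns:
        present = occurrence.index[occurrence[island] > 0].tolist()
        if not present:
            warnings.warn(f"island {island!r} has no haplotypes; excluded")
            continue
        out[island] = pt.faith_pd(present, convention)
    return pd.Series(out, name="PD")
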