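"""Phylogeny proxy built from Linnaean ranks.

With no time-calibrated phylogeny available for the zooplankton pool, the
nested taxonomy (species, genus, family, order, class) stands in for
relatedness.  The tree is ultrametric with unit branch lengths per rank
step, so the patristic distance between two tips is exactly twice their
taxonomic distance (0 = same species ... 5 = different classes).
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

RANKS = ("species", "genus", "family", "order", "class")
ROOT_LEVEL = len(RANKS)  # 5: lowest shared rank above class is the root

__all__ = [
    "RANKS",
    "taxonomic_distance",
    "TaxonomyTree",
    "build_tree",
    "write_newick",
    "read_newick",
]


def taxonomic_distance(lineage_a, lineage_b) -> int:
    """Rank steps to the lowest shared rank of two complete lineages.

    Lineages are mappings with keys ``species, genus, family, order, class``.
    Scale: same species = 0, congeners = 1, ..., different classes = 5.
    """
    for lin in (lineage_a, lineage_b):
        missing = [r for r in RANKS if r not in lin or lin[r] in (None, "")]
        if missing:
            raise ValueError(f"incomplete lineage, missing ranks: {missing}")
    for level, rank in enumerate(RANKS):
        if lineage_a[rank] == lineage_b[rank]:
            return level
    return ROOT_LEVEL


class TaxonomyTree:
    """Ultrametric rank tree over a taxon pool.

    Thin wrapper around a rooted :class:`dendropy.Tree` whose tip labels are
    taxon ids and whose branch lengths are in rank-level units.  Exposes the
    structures the diversity metrics consume: per-tip root-path edge sets and
    the full patristic distance matrix.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._index()

    def _index(self) -> None:
        t = self.tree
        self.tip_labels = [lf.taxon.label for lf in t.leaf_node_iter()]
        self.tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}
        # enumerate edges with a branch length (root edge excluded)
        self.edges = [
            e for e in t.preorder_edge_iter()
            if e.head_node is not t.seed_node and e.length is not None
        ]
        eidx = {id(e): i for i, e in enumerate(self.edges)}
        self.edge_lengths = np.array([e.length for e in self.edges])
        n_tip, n_edge = len(self.tip_labels), len(self.edges)
        # ancestry matrix: ancestry[i, j] = tip i's root path uses edge j
        self.ancestry = np.zeros((n_tip, n_edge), dtype=bool)
        for lf in t.leaf_node_iter():
            i = self.tip_index[lf.taxon.label]
            node = lf
            while node is not t.seed_node:
                j = eidx.get(id(node.edge))
                if j is not None:
                    self.ancestry[i, j] = True
                node = node.parent_node
        depths = self.ancestry @ self.edge_lengths
        self.tip_depths = depths
        # patristic distances from shared root paths (tree is ultrametric)
        shared = (self.ancestry.astype(float) * self.edge_lengths) @ self.ancestry.T
        self.patristic = depths[:, None] + depths[None, :] - 2.0 * shared
        np.fill_diagonal(self.patristic, 0.0)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        return float(self.tip_depths.max() - self.tip_depths.min()) < tol

    def indices_of(self, taxon_ids) -> np.ndarray:
        try:
            return np.array([self.tip_index[t] for t in taxon_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"taxon {exc.args[0]!r} is not a tip of the tree") from exc


def build_tree(taxa: pd.DataFrame) -> TaxonomyTree:
    """Construct the rank tree for a taxon table with complete lineages.

    The topology is the nested taxonomy itself: root -> classes -> orders ->
    families -> genera -> species tips, every edge of length 1.  Chains of
    single-child nodes are collapsed with summed branch lengths, which leaves
    all tip-to-tip patristic distances (and ultrametricity) intact.

    Raises ``ValueError`` if any name is nested inconsistently (e.g. one
    genus recorded under two families).
    """
    required = [r for r in RANKS if r != "species"]
    for r in required:
        if r not in taxa.columns:
            raise ValueError(f"taxon table lacks rank column {r!r}")
    # consistency: each name at rank r has exactly one parent name at rank r+1
    for child, parent in zip(RANKS[1:-1], RANKS[2:]):
        counts = taxa.groupby(child)[parent].nunique()
        bad = counts[counts > 1]
        if len(bad):
            name = bad.index[0]
            raise ValueError(
                f"inconsistent nesting: {child} {name!r} appears under "
                f"{int(bad.iloc[0])} different {parent} names"
            )

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    nodes: dict[tuple, dendropy.Node] = {}

    def get_node(rank_level: int, path: tuple) -> dendropy.Node:
        # rank_level: 4=class ... 1=genus; path identifies the clade
        key = (rank_level, path)
        if key in nodes:
            return nodes[key]
        parent = root if rank_level == 4 else get_node(rank_level + 1, path[:-1])
        node = parent.new_child(edge_length=1.0)
        nodes[key] = node
        return node

    records = taxa.to_dict("records")  # 'class' is a keyword; avoid itertuples
    for rec in records:
        path = (rec["class"], rec["order"], rec["family"], rec["genus"])
        genus_node = get_node(1, path)
        tip = genus_node.new_child(edge_length=1.0)
        tip.taxon = tns.new_taxon(label=str(rec["taxon_id"]))

    _collapse_unifurcations(tree)
    return TaxonomyTree(tree)


def _collapse_unifurcations(tree: dendropy.Tree) -> None:
    """Merge single-child chains, summing branch lengths.

    Unlike a generic suppression, the root always survives, so a pool that
    collapses to a single clade keeps its full rank depth (e.g. two congeners
    sit on a cherry hanging from a root path of length 4).
    """
    for node in list(tree.postorder_internal_node_iter()):
        if node is tree.seed_node:
            continue
        children = node.child_nodes()
        if len(children) == 1:
            child = children[0]
            child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
            parent = node.parent_node
            node.remove_child(child)
            parent.add_child(child)
            parent.remove_child(node)


def write_newick(tree: TaxonomyTree) -> str:
    """Serialize with branch lengths; tip labels are taxon ids verbatim."""
    return tree.tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def read_newick(text: str) -> TaxonomyTree:
    """Parse a Newick string back into a :class:`TaxonomyTree`."""
    try:
        t = dendropy.Tree.get(
            data=text, schema="newick",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    return TaxonomyTree(t)
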