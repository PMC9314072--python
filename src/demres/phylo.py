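"""Phylogeny handling for the comparative analyses.

Trees are rooted, time-calibrated and read from Newick (via dendropy).
Polytomies are resolved into random dichotomies with near-zero branch
lengths before building the phylogenetic variance-covariance (VCV) matrix,
whose entry (i, j) is the shared root-to-MRCA path length of tips i and j —
the covariance of a Brownian trait.  The standardized (unit-diagonal,
correlation-form) VCV is what enters the multilevel models as the
phylogenetic random-effect covariance.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloVCV",
    "parse_newick",
    "resolve_polytomies",
    "vcv_from_tree",
    "match_tree_to_data",
    "normalize_species_name",
]


class PhyloError(ValueError):
    """Raised for malformed trees or tree/data mismatches."""


@dataclass(frozen=True)
class PhyloVCV:
    """Species-by-species phylogenetic covariance with its label order."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    standardized: bool

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise PhyloError("VCV shape does not match label count")
        if np.abs(m - m.T).max() > 1e-12:
            raise PhyloError("VCV is not symmetric")
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise PhyloError("VCV is not positive semidefinite")
        if self.standardized and np.abs(np.diag(m) - 1.0).max() > 1e-10:
            raise PhyloError("standardized VCV must have a unit diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def normalize_species_name(name: str) -> str:
    """Canonical species label: underscores for whitespace, collapsed runs."""
    return re.sub(r"[\s_]+", "_", name.strip())


def parse_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string or file path into a rooted tree.

    Raises :class:`PhyloError` for malformed input, duplicate tip labels or
    negative branch lengths.
    """
    try:
        if "(" in source:
            tree = dendropy.Tree.get(
                data=source, schema="newick", suppress_internal_node_taxa=True
            )
        else:
            tree = dendropy.Tree.get(
                path=source, schema="newick", suppress_internal_node_taxa=True
            )
    except Exception as exc:  # dendropy raises several parse-error types
        raise PhyloError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise PhyloError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise PhyloError(f"negative branch length {edge.length}")
    tree.is_rooted = True
    return tree


def tree_height(tree: dendropy.Tree) -> float:
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def is_binary(tree: dendropy.Tree) -> bool:
    return all(
        len(n.child_nodes()) in (0, 2) for n in tree.preorder_node_iter()
    )


def resolve_polytomies(
    tree: dendropy.Tree, epsilon: float | None = None, seed: int = 0
) -> dendropy.Tree:
    """Resolve multifurcations into random dichotomies with tiny new branches.

    Inserted internal branches get length ``epsilon`` (default 1e-6 x tree
    height), so every root-to-tip path and pairwise covariance moves by at
    most the number of insertions on it times epsilon.  The resolution order
    is driven by ``seed``; an already binary tree is returned unchanged.
    """
    if is_binary(tree):
        return tree
    if epsilon is None:
        epsilon = 1e-6 * tree_height(tree)
    clone = tree.clone(depth=1)
    clone.resolve_polytomies(limit=2, update_bipartitions=False, rng=random.Random(seed))
    for edge in clone.preorder_edge_iter():
        if edge.head_node.is_leaf() or edge.tail_node is None:
            continue
        if edge.length is None or edge.length == 0:
            edge.length = epsilon
    return clone


def vcv_from_tree(tree: dendropy.Tree, standardize: bool = True) -> PhyloVCV:
    """Phylogenetic VCV: shared root-to-MRCA path length per tip pair.

    The diagonal holds root-to-tip depths.  With ``standardize`` the matrix
    is scaled to unit diagonal (correlation form), the default used for the
    random-effect covariance.
    """
    leaves = list(tree.leaf_node_iter())
    labels = tuple(normalize_species_name(l.taxon.label) for l in leaves)
    index = {id(l): i for i, l in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))

    # postorder sweep: a node's depth is the covariance of tip pairs whose
    # MRCA it is, i.e. pairs drawn from distinct child subtrees
    tips_below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            V[i, i] = node.distance_from_root()
            tips_below[id(node)] = [i]
            continue
        depth = node.distance_from_root()
        child_tip_sets = [tips_below.pop(id(c)) for c in node.child_nodes()]
        for a in range(len(child_tip_sets)):
            for b in range(a + 1, len(child_tip_sets)):
                ia = np.array(child_tip_sets[a])
                ib = np.array(child_tip_sets[b])
                V[np.ix_(ia, ib)] = depth
                V[np.ix_(ib, ia)] = depth
        tips_below[id(node)] = [i for s in child_tip_sets for i in s]

    if np.any(np.diag(V) <= 0):
        raise PhyloError("tree has zero-depth tips; cannot build a VCV")
    if standardize:
        d = 1.0 / np.sqrt(np.diag(V))
        V = V * d[:, None] * d[None, :]
        np.fill_diagonal(V, 1.0)
    return PhyloVCV(labels=labels, matrix=V, standardized=standardize)


def match_tree_to_data(
    tree: dendropy.Tree,
    table: pd.DataFrame,
    species_column: str = "species_name",
    standardize: bool = True,
) -> tuple[dendropy.Tree, PhyloVCV, pd.DataFrame, list[str]]:
    """Align a tree and a population table on their shared species.

    Species names are matched after whitespace/underscore normalization.
    Returns the pruned tree, the VCV over the shared species (tree tip
    order), the table restricted to shared species with a normalized
    ``species_name``, and the list of names dropped from either side.
    Multiple populations of one species all map to that species' VCV row.
    """
    tip_names = {
        normalize_species_name(l.taxon.label): l.taxon.label
        for l in tree.leaf_node_iter()
    }
    table = table.copy()
    table[species_column] = table[species_column].map(normalize_species_name)
    data_names = set(table[species_column])
    shared = set(tip_names) & data_names
    if len(shared) < 2:
        raise PhyloError(
            f"tree/data intersection has {len(shared)} species; need at least 2"
        )
    dropped = sorted((set(tip_names) | data_names) - shared)

    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels([tip_names[s] for s in shared])
    vcv = vcv_from_tree(pruned, standardize=standardize)
    order = {s: i for i, s in enumerate(vcv.labels)}
    table = table[table[species_column].isin(shared)].copy()
    table = table.sort_values(
        by=[species_column], key=lambda col: col.map(order), kind="stable"
    ).reset_index(drop=True)
    return pruned, vcv, table, dropped
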