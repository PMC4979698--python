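"""Tree I/O, arbitrary branch-length transforms, and Brownian covariance.

Composite phylogenies assembled from literature have no meaningful branch
lengths, so comparative analyses assign them arbitrarily: unit lengths
(every branch 1, with polytomies contributing no length), or the Grafen,
Pagel and Nee schemes in which node heights are functions of the number of
descendant tips, rescaled to unit root height.  The definitions used here
follow the PDAP/PDTREE lineage:

* grafen -- node height proportional to (number of descendant tips - 1)
* nee    -- node height proportional to log(number of descendant tips)
* pagel  -- all branches 1, then terminal branches extended until the tree
  is ultrametric

A rooted tree with branch lengths induces the Brownian-motion covariance
C[i, j] = shared root-to-MRCA path length of tips i and j; Pagel's lambda
rescales the off-diagonal entries to interpolate between the full Brownian
expectation (lambda = 1) and a star phylogeny (lambda = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import dendropy
import numpy as np

__all__ = [
    "PhyloCovariance",
    "BRANCH_LENGTH_METHODS",
    "read_newick",
    "write_newick",
    "transform_branch_lengths",
    "phylo_covariance",
    "lambda_transform",
    "prune_to_species",
]

BRANCH_LENGTH_METHODS = ("unit", "grafen", "pagel", "nee")


@dataclass(frozen=True)
class PhyloCovariance:
    """Species-by-species shared branch-length matrix with a lambda scaling."""

    species: tuple[str, ...]
    matrix: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.species), len(self.species)):
            raise ValueError("matrix shape does not match species list")
        if not np.allclose(m, m.T):
            raise ValueError("covariance matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    def reorder(self, species: list[str]) -> "PhyloCovariance":
        idx = [self.species.index(s) for s in species]
        return PhyloCovariance(
            tuple(species), self.matrix[np.ix_(idx, idx)], self.lam
        )


def read_newick(path) -> dendropy.Tree:
    """Read one rooted Newick tree; tip labels must be unique and non-empty."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    _validate_tips(tree)
    return tree


def read_newick_string(s: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=s, schema="newick", preserve_underscores=True
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    _validate_tips(tree)
    return tree


def _validate_tips(tree: dendropy.Tree) -> None:
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree contains an unlabeled tip")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    """Canonical single-line Newick string with branch lengths."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree(tree)


def _collapse_zero_internodes(tree: dendropy.Tree) -> dendropy.Tree:
    """Turn zero-length internal edges into true polytomies.

    Composite trees often encode polytomies as bifurcations with zero-length
    internodes; collapsing first makes the tip-count-based transforms
    independent of that encoding.
    """
    out = _clone(tree)
    to_collapse = [
        e
        for e in out.preorder_edge_iter()
        if e.head_node is not None
        and not e.head_node.is_leaf()
        and e.tail_node is not None
        and (e.length is not None and e.length == 0)
    ]
    for edge in to_collapse:
        edge.collapse()
    return out


def _n_descendant_tips(tree: dendropy.Tree) -> dict:
    counts = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            counts[node] = 1
        else:
            counts[node] = sum(counts[c] for c in node.child_nodes())
    return counts


def transform_branch_lengths(tree: dendropy.Tree, method: str) -> dendropy.Tree:
    """Assign arbitrary branch lengths; returns a new tree.

    Zero-length internal edges (polytomy encodings) are collapsed first, so
    the result depends only on the multifurcating topology.
    """
    if method not in BRANCH_LENGTH_METHODS:
        raise ValueError(
            f"unknown method {method!r}; choose from {BRANCH_LENGTH_METHODS}"
        )
    out = _collapse_zero_internodes(tree)
    root = out.seed_node
    root.edge.length = None

    if method == "unit":
        for node in out.preorder_node_iter():
            if node is not root:
                node.edge.length = 1.0
        return out

    if method == "pagel":
        for node in out.preorder_node_iter():
            if node is not root:
                node.edge.length = 1.0
        depths = {root: 0.0}
        for node in out.preorder_node_iter():
            if node is not root:
                depths[node] = depths[node.parent_node] + node.edge.length
        max_depth = max(depths[l] for l in out.leaf_node_iter())
        for leaf in out.leaf_node_iter():
            leaf.edge.length += max_depth - depths[leaf]
        return out

    counts = _n_descendant_tips(out)
    n_total = counts[root]
    if method == "grafen":
        height = {nd: (counts[nd] - 1) / (n_total - 1) for nd in counts}
    else:  # nee
        height = {nd: np.log(counts[nd]) / np.log(n_total) for nd in counts}
    for node in out.preorder_node_iter():
        if node is not root:
            node.edge.length = height[node.parent_node] - height[node]
    return out


def phylo_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Brownian covariance: C[i, j] = shared root-to-MRCA path length."""
    species = tuple(sorted(tip_labels(tree)))
    index = {s: i for i, s in enumerate(species)}
    n = len(species)
    C = np.zeros((n, n))
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        idx = [index[leaf.taxon.label] for leaf in node.leaf_iter()]
        C[np.ix_(idx, idx)] += length
    return PhyloCovariance(species, C, lam=1.0)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Scale off-diagonal covariance by Pagel's lambda (diagonal unchanged)."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    m = cov.matrix.copy()
    off = ~np.eye(len(cov.species), dtype=bool)
    m[off] *= lam
    return _dc_replace(cov, matrix=m, lam=lam)


def lambda_scaled_matrix(C: np.ndarray, lam: float) -> np.ndarray:
    """Fast in-place-free lambda scaling of a raw covariance array."""
    d = np.diag(C).copy()
    m = C * lam
    np.fill_diagonal(m, d)
    return m


def prune_to_species(tree: dendropy.Tree, species: list[str]) -> dendropy.Tree:
    """Prune the tree down to the given tip labels (all must be present)."""
    have = set(tip_labels(tree))
    missing = sorted(set(species) - have)
    if missing:
        raise ValueError(f"species absent from tree: {missing}")
    out = _clone(tree)
    out.retain_taxa_with_labels(species)
    return out
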