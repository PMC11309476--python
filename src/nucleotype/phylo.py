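"""Phylogeny handling and phylogenetic covariance matrices.

A rooted, dated (ultrametric) phylogeny underlies every comparative analysis
in this package: the expected covariance of a Brownian-motion trait between
two species is the shared root-to-ancestor path length, and Pagel's lambda
rescales the off-diagonal (shared) part of that matrix to interpolate between
pure Brownian structure (lambda = 1) and a star phylogeny (lambda = 0).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "read_newick",
    "write_newick",
    "is_ultrametric",
    "phylo_covariance",
    "lambda_transform",
]


class NewickParseError(ValueError):
    """Raised when a newick string violates the expected dialect."""


@dataclass
class Phylogeny:
    """A rooted tree with named tips and nonnegative branch lengths.

    Thin wrapper around a :class:`dendropy.Tree`; polytomies are allowed.
    Tip labels must be unique and there must be at least one tip (two for
    any covariance work).
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickParseError(f"duplicate tip labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue  # root edge length optional
            if edge.length is None:
                name = edge.head_node.taxon.label if edge.head_node.taxon else "<internal>"
                raise NewickParseError(f"missing branch length on edge to {name!r}")
            if edge.length < 0:
                raise NewickParseError(f"negative branch length {edge.length}")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {
            leaf.taxon.label: float(leaf.root_distance)
            for leaf in self.tree.leaf_node_iter()
        }

    def prune_to(self, labels: list[str]) -> "Phylogeny":
        """Return a new tree restricted to ``labels`` (order irrelevant)."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        clone = self.tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in keep]
        clone.retain_taxa(taxa)
        return Phylogeny(clone)

    def to_newick(self) -> str:
        return write_newick(self)


def read_newick(text: str) -> Phylogeny:
    """Parse a newick string (branch lengths required on non-root edges)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several unrelated types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    if not tree.leaf_nodes() or tree.seed_node.is_leaf() and tree.seed_node.taxon is None:
        raise NewickParseError("newick string contains no labelled tips")
    return Phylogeny(tree)


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick(phy: Phylogeny) -> str:
    out = io.StringIO()
    phy.tree.write(
        file=out,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return out.getvalue().strip()


def is_ultrametric(phy: Phylogeny, rel_tol: float = 1e-6) -> bool:
    """True iff all root-to-tip depths agree within ``rel_tol`` of the max."""
    depths = np.array(list(phy.depths().values()))
    dmax = depths.max()
    if dmax == 0:
        return True
    return bool(np.all(dmax - depths <= rel_tol * dmax))


@dataclass
class PhyloCovariance:
    """Brownian-motion covariance matrix of a set of tips.

    ``matrix[i, j]`` is the root-to-MRCA path length of tips ``labels[i]``
    and ``labels[j]``; the diagonal holds root-to-tip depths. ``lam`` records
    the Pagel's-lambda scaling already applied to the off-diagonal.
    """

    labels: list[str]
    matrix: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")

    def to_correlation(self) -> np.ndarray:
        s = np.sqrt(np.diag(self.matrix))
        return self.matrix / np.outer(s, s)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def phylo_covariance(phy: Phylogeny) -> PhyloCovariance:
    """Covariance matrix from shared path lengths, tips in sorted-label order.

    Downstream modules align their data to this sorted order, which makes
    joins deterministic.
    """
    if phy.n_tips < 2:
        raise ValueError("need at least 2 tips for a covariance matrix")
    labels = sorted(phy.tip_labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    cov = np.zeros((n, n))

    phy.tree.calc_node_root_distances(return_leaf_distances_only=False)
    # Postorder: at each internal node, tips in different child subtrees have
    # their MRCA here, so their covariance is this node's depth.
    tipsets: dict[int, list[int]] = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[id(node)] = [idx[node.taxon.label]]
            continue
        depth = float(node.root_distance or 0.0)
        child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
        merged: list[int] = []
        for a_i, a in enumerate(child_sets):
            for b in child_sets[a_i + 1 :]:
                for i in a:
                    cov[i, b] = depth
                    cov[np.ix_(b, [i])] = depth
            merged.extend(a)
        tipsets[id(node)] = merged
    for lab, d in phy.depths().items():
        i = idx[lab]
        cov[i, i] = d
    return PhyloCovariance(labels=labels, matrix=cov, lam=1.0)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal covariances by ``lam`` (Pagel's lambda scaling).

    The result is positive semidefinite for lam in [0, 1] because it is a
    convex combination of the original matrix and its diagonal.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    m = cov.matrix.copy()
    d = np.diag(m).copy()
    m *= lam
    np.fill_diagonal(m, d)
    return PhyloCovariance(labels=list(cov.labels), matrix=m, lam=lam * cov.lam)
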