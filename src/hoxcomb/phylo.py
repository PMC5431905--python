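"""Desk-scale phylogenetic corroboration: p-distances, neighbor joining,
column bootstrap.

This module is an explicit stand-in for full Bayesian/ML tree inference:
it gives the pipeline an independent, fast line of evidence alongside the
residue-based classifier, not publishable support values.  Distances are
uncorrected p-distances over the 72-position analysis segment (pluggable —
a model-corrected distance can be swapped in later); trees are built with
the Saitou–Nei neighbor-joining algorithm, deterministically (Q-matrix
ties broken by lexicographic leaf-name pairs); clade support comes from
resampling the 72 segment columns with replacement and counting, for each
internal edge of the original tree, the fraction of replicate trees
containing the same bipartition.

Negative NJ branch-length estimates are clamped to zero (standard
practice; each clamp is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError
from .io_formats import escape_newick_label
from .locator import SEGMENT_LENGTH, AnalysisSegment

logger = logging.getLogger(__name__)


# -- distances ---------------------------------------------------------------


def p_distance(a: AnalysisSegment, b: AnalysisSegment) -> float:
    """Uncorrected proportion of mismatched positions between two segments.

    Compared over positions 1..min(common covered length); positions where
    either residue is ``X`` are skipped.  No comparable positions is an
    error.
    """
    n = min(a.length, b.length)
    compared = 0
    mismatches = 0
    for p in range(1, n + 1):
        ra, rb = a.residue_at(p), b.residue_at(p)
        if ra == "X" or rb == "X":
            continue
        compared += 1
        if ra != rb:
            mismatches += 1
    if compared == 0:
        raise DataError("no comparable positions between segments")
    return mismatches / compared


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal over named taxa."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise DataError("duplicate taxon ids in distance matrix")
        if d.shape != (n, n):
            raise DataError(f"distance matrix shape {d.shape} does not match {n} ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise DataError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise DataError("distances must be non-negative")
        object.__setattr__(self, "d", d)

    def __len__(self) -> int:
        return len(self.ids)


def segments_to_distance_matrix(
    segments: Sequence[AnalysisSegment], ids: Sequence[str]
) -> DistanceMatrix:
    """Pairwise p-distance matrix over a set of segments."""
    if len(segments) != len(ids):
        raise DataError("segments and ids differ in length")
    n = len(segments)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(segments[i], segments[j])
    return DistanceMatrix(ids=tuple(ids), d=d)


# -- trees -------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of an unrooted tree rendered with a basal trifurcation.

    ``length`` is the branch to the parent (None at the root); ``support``
    is bootstrap support of the edge above an internal node, when computed.
    """

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())  # type: ignore[misc]


@dataclass
class Tree:
    """Unrooted tree over a fixed leaf set (root is a trifurcation for
    n >= 3 taxa, so the edge count is 2n - 3)."""

    root: TreeNode

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalised as the side not
        containing the lexicographically smallest leaf."""
        all_leaves = self.leaf_names()
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> None:
            for child in node.children:
                below = child.leaf_names()
                if 1 < len(below) < len(all_leaves) - 1:
                    side = below if ref not in below else all_leaves - below
                    out.add(side)
                walk(child)

        walk(self.root)
        return out

    def internal_edges(self) -> list[tuple[TreeNode, frozenset[str]]]:
        """(node, canonical split) for every internal non-root node that
        defines a non-trivial bipartition."""
        all_leaves = self.leaf_names()
        ref = min(all_leaves)
        out = []

        def walk(node: TreeNode) -> None:
            for child in node.children:
                if not child.is_leaf:
                    below = child.leaf_names()
                    if 1 < len(below) < len(all_leaves) - 1:
                        side = below if ref not in below else all_leaves - below
                        out.append((child, side))
                walk(child)

        walk(self.root)
        return out

    def n_edges(self) -> int:
        def count(node: TreeNode) -> int:
            return len(node.children) + sum(count(c) for c in node.children)

        return count(self.root)

    def to_newick(self) -> str:
        """Newick string; branch lengths to 6 significant digits, bootstrap
        supports (fraction in [0, 1]) as internal node labels."""

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                body = escape_newick_label(node.name or "")
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = "" if node.support is None else f"{node.support:.6g}"
                body = f"({inner}){label}"
            if node.length is not None:
                body += f":{node.length:.6g}"
            return body

        return fmt(self.root) + ";"


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining, deterministic under input reordering.

    Q-matrix ties are broken by the lexicographically smallest pair of
    cluster keys (a cluster's key is its smallest leaf name).  Negative
    branch-length estimates are clamped to zero with a log note.
    """
    n = len(dm)
    if n < 3:
        raise DataError("neighbor joining needs at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    keys: list[str] = list(dm.ids)
    d = dm.d.copy()

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("negative NJ branch length %.3g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        # evaluate Q on the upper triangle only: r[i]+r[j] rounds differently
        # from r[j]+r[i] at the last bit, so the full matrix is not exactly
        # symmetric and the minimum must be taken over one triangle
        iu, ju = np.triu_indices(m, k=1)
        qvals = (m - 2) * d[iu, ju] - r[iu] - r[ju]
        qmin = qvals.min()
        best: tuple[str, str] | None = None
        bi = bj = -1
        for i, j, qv in zip(iu, ju, qvals):
            if qv == qmin:
                pair = tuple(sorted((keys[i], keys[j])))
                if best is None or pair < best:
                    best, bi, bj = pair, int(i), int(j)  # type: ignore[assignment]
        i, j = bi, bj
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        parent = TreeNode(children=[child_i, child_j])

        new_row = (d[i, :] + d[j, :] - d[i, j]) / 2
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d_new[m - 2, : m - 2] = d_new[: m - 2, m - 2] = new_row[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # terminal 3-cluster join: closed-form branch lengths to a trifurcating root
    (a, b, c) = nodes
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
    a.length, b.length, c.length = clamp(la), clamp(lb), clamp(lc)
    order = np.argsort(keys)  # deterministic child order at the root
    root = TreeNode(children=[nodes[k] for k in order])
    return Tree(root=root)


# -- bootstrap ---------------------------------------------------------------


def _segment_matrix(segments: Sequence[AnalysisSegment]) -> np.ndarray:
    """Segments as a (n, 72) character matrix, short flanks padded with X."""
    rows = [s.residues.ljust(SEGMENT_LENGTH, "X") for s in segments]
    return np.array([list(r) for r in rows], dtype="U1")


def _distances_from_matrix(mat: np.ndarray, ids: Sequence[str]) -> DistanceMatrix:
    n = mat.shape[0]
    valid = mat != "X"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise DataError(
                    f"no comparable positions between {ids[i]!r} and {ids[j]!r}"
                )
            d[i, j] = d[j, i] = float((mat[i][both] != mat[j][both]).sum()) / compared
    return DistanceMatrix(ids=tuple(ids), d=d)


def bootstrap_support(
    segments: Sequence[AnalysisSegment],
    ids: Sequence[str],
    n_replicates: int = 100,
    seed: int = 0,
) -> Tree:
    """NJ tree with column-resampling bootstrap supports on internal edges.

    The 72 segment columns are resampled with replacement ``n_replicates``
    times; the support of each internal edge of the original tree is the
    fraction of replicate trees containing the same bipartition.  Seeded
    and fully reproducible.
    """
    if n_replicates < 1:
        raise DataError("n_replicates must be >= 1")
    mat = _segment_matrix(segments)
    tree = neighbor_joining(_distances_from_matrix(mat, ids))
    edges = tree.internal_edges()
    if not edges:
        return tree

    counts = {split: 0 for _, split in edges}
    rng = np.random.default_rng(seed)
    n_cols = mat.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_tree = neighbor_joining(_distances_from_matrix(mat[:, cols], ids))
        rep_splits = rep_tree.splits()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    for node, split in edges:
        node.support = counts[split] / n_replicates
    return tree
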