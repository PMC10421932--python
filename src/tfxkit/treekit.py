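"""Desk-scale tree construction and comparison.

Distance matrices (p-distance on alignments, Euclidean or cosine on
feature vectors), classical neighbor-joining with documented tie-breaking
(lowest label pair lexicographically) and negative-branch clamping,
Robinson-Foulds bipartition distance, and unrooted monophyly testing.
Trees are dendropy objects so externally computed Newick trees can be
compared directly; Bayesian/ML inference itself is out of scope and enters
only via Newick import.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.labels)
        if v.shape != (n, n):
            raise TreeError("matrix shape does not match label count")
        if not np.all(np.isfinite(v)):
            raise TreeError("non-finite distances")
        if not np.allclose(v, v.T):
            raise TreeError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise TreeError("nonzero diagonal")
        if (v < -1e-12).any():
            raise TreeError("negative distances")

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def p_distance(seq_a: str, seq_b: str, gap_chars: str = "-.") -> float:
    """Mismatches over comparable (both non-gap) columns of two aligned rows."""
    if len(seq_a) != len(seq_b):
        raise TreeError("aligned sequences differ in length")
    comparable = mismatch = 0
    for a, b in zip(seq_a, seq_b):
        if a in gap_chars or b in gap_chars:
            continue
        comparable += 1
        if a != b:
            mismatch += 1
    if comparable == 0:
        raise TreeError("no comparable columns")
    return mismatch / comparable


def distance_matrix(inputs, mode: str = "p_distance_on_alignment"
                    ) -> DistanceMatrix:
    """Build a labeled distance matrix.

    `inputs` is a list of records (id, sequence) for p-distance mode, or an
    (ids, matrix) pair for the feature modes.
    """
    if mode == "p_distance_on_alignment":
        records = list(inputs)
        lengths = {len(r.sequence) for r in records}
        if len(lengths) > 1:
            raise TreeError(f"ragged alignment: lengths {sorted(lengths)}")
        labels = tuple(r.id for r in records)
        n = len(records)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = p_distance(records[i].sequence, records[j].sequence)
                values[i, j] = values[j, i] = d
        return DistanceMatrix(labels, values)
    if mode in {"feature_euclidean", "feature_cosine"}:
        ids, matrix = inputs
        metric = "euclidean" if mode == "feature_euclidean" else "cosine"
        values = squareform(pdist(np.asarray(matrix, dtype=float), metric=metric))
        np.fill_diagonal(values, 0.0)
        return DistanceMatrix(tuple(ids), np.clip(values, 0, None))
    raise TreeError(f"unknown distance mode {mode!r}")


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Classical Saitou-Nei neighbor joining.

    Q-criterion ties are broken toward the lexicographically lowest label
    pair; negative branch lengths are clamped to 0 with a warning. Exact on
    additive matrices.
    """
    n = len(dm.labels)
    if n < 3:
        raise TreeError(f"neighbor joining needs >= 3 taxa (got {n})")
    taxa = dendropy.TaxonNamespace([str(l) for l in dm.labels])
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes: dict[str, dendropy.Node] = {}
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(str(label))
        nodes[label] = node

    labels = list(dm.labels)
    d = {a: {b: float(dm.values[i, j]) for j, b in enumerate(labels)}
         for i, a in enumerate(labels)}
    # sort key: labels may be arbitrary tokens; compare as strings
    active = sorted(labels, key=str)
    clamped = False
    counter = 0
    while len(active) > 2:
        m = len(active)
        totals = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best_q, best_pair = np.inf, None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (m - 2) * d[a][b] - totals[a] - totals[b]
                pair = tuple(sorted((str(a), str(b))))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12
                                          and (best_pair is None or pair < best_pair)):
                    best_q, best_pair = q, pair
                    best_ab = (a, b)
        a, b = best_ab
        la = 0.5 * d[a][b] + (totals[a] - totals[b]) / (2 * (m - 2))
        lb = d[a][b] - la
        if la < 0 or lb < 0:
            clamped = True
        la, lb = max(la, 0.0), max(lb, 0.0)
        counter += 1
        u = f"__internal_{counter}"
        parent = dendropy.Node()
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.edge.length, child_b.edge.length = la, lb
        parent.add_child(child_a)
        parent.add_child(child_b)
        nodes[u] = parent
        d[u] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[u][c] = duc
            d[c][u] = duc
        d[u][u] = 0.0
        active = sorted([c for c in active if c not in (a, b)] + [u], key=str)
    a, b = active
    node_a, node_b = nodes[a], nodes[b]
    length = max(d[a][b], 0.0)
    # join the last two lineages along one edge (no degree-2 root)
    if node_b.is_leaf():
        root, child = node_a, node_b
    else:
        root, child = node_b, node_a
    tree.seed_node = root
    root.add_child(child)
    child.edge.length = length
    if clamped:
        warnings.warn("negative branch lengths clamped to 0", stacklevel=2)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Tree comparison
# ---------------------------------------------------------------------------

def _leaf_labels(tree: dendropy.Tree) -> set:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _nontrivial_bipartitions(tree: dendropy.Tree) -> set:
    """Nontrivial splits as frozensets of the side not containing an
    arbitrary fixed reference leaf."""
    leaves = _leaf_labels(tree)
    ref = min(leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        side = below if ref not in below else leaves - below
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset(side))
    return splits


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Count of nontrivial bipartitions present in exactly one tree."""
    l1, l2 = _leaf_labels(t1), _leaf_labels(t2)
    if l1 != l2:
        raise TreeError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}")
    s1, s2 = _nontrivial_bipartitions(t1), _nontrivial_bipartitions(t2)
    return len(s1 ^ s2)


def is_monophyletic(tree: dendropy.Tree, leaf_subset: Sequence[str]) -> bool:
    """True iff removing some edge separates exactly `leaf_subset` from the
    rest (unrooted sense)."""
    subset = set(leaf_subset)
    if not subset:
        raise TreeError("empty leaf subset")
    leaves = _leaf_labels(tree)
    unknown = subset - leaves
    if unknown:
        raise TreeError(f"unknown leaves: {sorted(unknown)}")
    if len(subset) in (1, len(leaves)):
        return True
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        if below == subset or (leaves - below) == subset:
            return True
    return False


# ---------------------------------------------------------------------------
# Random additive matrices (test/benchmark substrate)
# ---------------------------------------------------------------------------

def random_additive_matrix(n_leaves: int, seed: int
                           ) -> tuple[DistanceMatrix, dendropy.Tree]:
    """A random binary tree with positive branch lengths and its additive
    path-length distance matrix."""
    rng = np.random.default_rng(seed)
    if n_leaves < 3:
        raise TreeError("need >= 3 leaves")
    labels = [f"t{i}" for i in range(n_leaves)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    # grow by random edge subdivision
    nodes = []
    for i in range(3):
        child = dendropy.Node()
        child.taxon = taxa.get_taxon(labels[i])
        child.edge.length = float(rng.uniform(0.5, 3.0))
        tree.seed_node.add_child(child)
        nodes.append(child)
    for i in range(3, n_leaves):
        attach = nodes[int(rng.integers(len(nodes)))]
        parent = attach.parent_node
        mid = dendropy.Node()
        orig_len = attach.edge.length
        parent.remove_child(attach)
        parent.add_child(mid)
        split = float(rng.uniform(0.2, 0.8))
        mid.edge.length = orig_len * split
        attach.edge.length = orig_len * (1 - split)
        mid.add_child(attach)
        leaf = dendropy.Node()
        leaf.taxon = taxa.get_taxon(labels[i])
        leaf.edge.length = float(rng.uniform(0.5, 3.0))
        mid.add_child(leaf)
        nodes.append(leaf)
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    values = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(labels):
        for j in range(i + 1, n_leaves):
            dist = pdm.distance(taxa.get_taxon(a), taxa.get_taxon(labels[j]))
            values[i, j] = values[j, i] = dist
    return DistanceMatrix(tuple(labels), values), tree
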