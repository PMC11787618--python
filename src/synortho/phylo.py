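"""Distance-based phylogenetics: neighbor joining and Robinson-Foulds.

The family tree is built by canonical neighbor joining (Saitou-Nei Q
criterion with the standard branch-length formulas) from alignment-derived
distances; topological agreement with a reference tree — e.g. a core-gene
species tree — is quantified as the Robinson-Foulds distance, the number of
non-trivial bipartitions present in exactly one of the two trees.

Trees are dendropy objects throughout; Newick read/write are thin wrappers
over dendropy's parser.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .msa import MSA
from .align import GAP


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")


def distances_from_msa(msa: MSA, poisson: bool = False) -> DistanceMatrix:
    """Pairwise-deletion identity distances from an alignment.

    For each pair of rows, columns where either row is gapped are dropped and
    d = 1 - (identical / compared). With ``poisson`` the distance is the
    Poisson-corrected -ln(1 - p), clamped below saturation.
    """
    ids = msa.ids
    n = len(ids)
    d = np.zeros((n, n))
    rows = [msa.aligned(rid) for rid in ids]
    for i in range(n):
        for j in range(i + 1, n):
            same = total = 0
            for x, y in zip(rows[i], rows[j]):
                if x == GAP or y == GAP:
                    continue
                total += 1
                if x == y:
                    same += 1
            if total == 0:
                raise ValueError(f"rows {ids[i]} and {ids[j]} share no ungapped columns")
            p = 1.0 - same / total
            if poisson:
                p = -np.log(max(1.0 - p, 1e-10))
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=list(ids), d=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining; deterministic tie-breaking.

    Clusters are agglomerated by the Saitou-Nei Q criterion; ties break by
    the lexicographically smallest (min-label, min-label) pair. Negative
    branch lengths are clamped to zero. The result is an unrooted tree whose
    internal nodes have degree 3.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least three labels")
    ns = dendropy.TaxonNamespace(sorted(dm.labels))
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False

    nodes: list[dendropy.Node] = []
    minlab: list[str] = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(node)
        minlab.append(lab)
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for i in active:
            for j in active:
                if i == j:
                    continue
                pair = tuple(sorted((minlab[i], minlab[j])))
                if (minlab[i], minlab[j]) != pair:
                    continue  # visit each unordered pair once
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        assert best is not None
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances from the new cluster, stored in slot i
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes[i] = parent
        minlab[i] = min(minlab[i], minlab[j])
        active.remove(j)

    # final trifurcation via the three-point formulas
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    center = dendropy.Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree.seed_node = center
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def _nontrivial_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-label sets.

    Each internal edge splits the leaves in two; the side not containing the
    lexicographically smallest label represents the split.
    """
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    all_labels = set(labels)
    anchor = labels[0]
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if anchor in side:
            side = frozenset(all_labels - side)
        if 2 <= len(side) <= len(all_labels) - 2:
            splits.add(side)
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance between two trees on the same leaf set."""
    l1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    l2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf label sets")
    s1, s2 = _nontrivial_splits(t1), _nontrivial_splits(t2)
    return len(s1 ^ s2)


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string (optionally with branch lengths)."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise ValueError(f"cannot parse Newick: {exc}") from exc
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
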