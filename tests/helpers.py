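"""Independent oracles used by the tests.

The alignment oracles enumerate order-preserving sets of matched residue
pairs (every alignment is such a set plus gap runs, and interleaved gap runs
are never cheaper than one run per sequence), so they share no code with the
dynamic-programming implementation they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from synortho.align import BLOSUM62, encode


def _pair_score(a: str, b: str, i: int, j: int) -> float:
    return float(BLOSUM62[encode(a[i])[0], encode(b[j])[0]])


def _gap_cost(length: int, go: float, ge: float) -> float:
    return (go + ge * length) if length > 0 else 0.0


def oracle_global(a: str, b: str, go: float, ge: float) -> float:
    """Optimal global affine-gap score by exhaustive matched-set enumeration."""
    la, lb = len(a), len(b)
    best = -_gap_cost(la, go, ge) - _gap_cost(lb, go, ge)  # k = 0
    for k in range(1, min(la, lb) + 1):
        for ia in combinations(range(la), k):
            for ib in combinations(range(lb), k):
                score = 0.0
                prev_a, prev_b = -1, -1
                for x, y in zip(ia, ib):
                    score += _pair_score(a, b, x, y)
                    score -= _gap_cost(x - prev_a - 1, go, ge)
                    score -= _gap_cost(y - prev_b - 1, go, ge)
                    prev_a, prev_b = x, y
                score -= _gap_cost(la - 1 - prev_a, go, ge)
                score -= _gap_cost(lb - 1 - prev_b, go, ge)
                best = max(best, score)
    return best


def oracle_local(a: str, b: str, go: float, ge: float) -> float:
    """Optimal local affine-gap score (floor 0) by matched-set enumeration."""
    la, lb = len(a), len(b)
    best = 0.0
    for k in range(1, min(la, lb) + 1):
        for ia in combinations(range(la), k):
            for ib in combinations(range(lb), k):
                score = 0.0
                prev_a, prev_b = ia[0], ib[0]
                score += _pair_score(a, b, ia[0], ib[0])
                for x, y in zip(ia[1:], ib[1:]):
                    score -= _gap_cost(x - prev_a - 1, go, ge)
                    score -= _gap_cost(y - prev_b - 1, go, ge)
                    score += _pair_score(a, b, x, y)
                    prev_a, prev_b = x, y
                best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# random trees and additive matrices


def random_binary_tree(labels: list[str], rng: np.random.Generator):
    """Random unrooted binary tree as (adjacency {node: {nbr: length}}).

    Built by repeatedly splitting a random edge and attaching the next leaf.
    Internal nodes are integers, leaves are the given labels.
    """
    adj: dict = {}

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def disconnect(u, v):
        del adj[u][v]
        del adj[v][u]

    counter = [0]

    def new_internal():
        counter[0] += 1
        return counter[0]

    center = new_internal()
    for lab in labels[:3]:
        connect(center, lab, float(rng.uniform(0.1, 1.0)))
    for lab in labels[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if str(u) < str(v)]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        disconnect(u, v)
        mid = new_internal()
        split = float(rng.uniform(0.2, 0.8))
        connect(u, mid, w * split)
        connect(mid, v, w * (1 - split))
        connect(mid, lab, float(rng.uniform(0.1, 1.0)))
    return adj


def path_distances(adj: dict, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix of an adjacency-map tree."""
    n = len(labels)
    d = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    return d


def adjacency_to_newick(adj: dict, root=None) -> str:
    """Render an adjacency-map tree as Newick with branch lengths."""
    if root is None:
        root = next(u for u in adj if isinstance(u, int))

    def render(u, parent) -> str:
        children = [v for v in adj[u] if v != parent]
        if not children:
            return str(u)
        inner = ",".join(f"{render(v, u)}:{adj[u][v]:.6f}" for v in children)
        return f"({inner})"

    return render(root, None) + ";"


def newick_splits(newick: str) -> set[frozenset]:
    """Non-trivial bipartitions of a Newick tree, via an adjacency graph.

    Independent of the package's split extraction: the tree is rebuilt as an
    undirected graph and each edge's side is collected by flood fill.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    adj: dict = {}
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        adj.setdefault(id(edge.tail_node), set()).add(id(edge.head_node))
        adj.setdefault(id(edge.head_node), set()).add(id(edge.tail_node))
    leaf_of = {id(lf): lf.taxon.label for lf in tree.leaf_node_iter()}
    all_leaves = set(leaf_of.values())
    anchor = min(all_leaves)
    splits: set[frozenset] = set()
    for u in adj:
        for v in adj[u]:
            side: set[str] = set()
            seen = {u}
            stack = [v]
            while stack:
                w = stack.pop()
                if w in seen:
                    continue
                seen.add(w)
                if w in leaf_of:
                    side.add(leaf_of[w])
                stack.extend(x for x in adj[w] if x not in seen)
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(frozenset(side))
    return splits
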