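"""Independent oracles for neighbor-joining tests.

Random additive matrices are produced from explicitly constructed random
unrooted binary trees (the generating tree is an exact oracle for
additive data).  For small taxon counts, an exhaustive enumeration of
all unrooted topologies with least-squares branch fitting provides a
second, fully brute-force oracle.
"""

import itertools

import numpy as np


def _insert_leaf(edges, leaf, edge_idx, next_internal):
    a, b = edges[edge_idx]
    new = [e for i, e in enumerate(edges) if i != edge_idx]
    m = next_internal
    new.extend([(a, m), (b, m), (leaf, m)])
    return new


def all_topologies(n_leaves):
    """All unrooted binary topologies over leaves 0..n-1 as edge lists.

    Internal nodes are negative integers.  3 leaves -> 1 topology,
    5 -> 15, 6 -> 105.
    """
    base = [(0, -1), (1, -1), (2, -1)]
    trees = [base]
    for leaf in range(3, n_leaves):
        nxt = []
        for t in trees:
            for i in range(len(t)):
                nxt.append(_insert_leaf(t, leaf, i, -(leaf - 1)))
        trees = nxt
    return trees


def random_tree(n_leaves, rng, min_len=0.1, max_len=1.0):
    """Random unrooted binary tree with random branch lengths."""
    edges = [(0, -1), (1, -1), (2, -1)]
    for leaf in range(3, n_leaves):
        edges = _insert_leaf(edges, leaf, int(rng.integers(0, len(edges))), -(leaf - 1))
    lengths = {e: float(rng.uniform(min_len, max_len)) for e in edges}
    return edges, lengths


def _adjacency(edges):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    return adj


def _path_edges(edges, src, dst):
    adj = _adjacency(edges)
    stack = [(src, None, [])]
    while stack:
        node, prev, path = stack.pop()
        if node == dst:
            return path
        for nxt in adj[node]:
            if nxt != prev:
                e = (node, nxt) if (node, nxt) in dict.fromkeys(edges) else (nxt, node)
                stack.append((nxt, node, path + [e]))
    raise RuntimeError("disconnected tree")


def additive_matrix(edges, lengths, n_leaves):
    d = np.zeros((n_leaves, n_leaves))
    for i, j in itertools.combinations(range(n_leaves), 2):
        dist = sum(lengths[e] for e in _path_edges(edges, i, j))
        d[i, j] = d[j, i] = dist
    return d


def bipartitions(edges, n_leaves):
    """Nontrivial leaf bipartitions induced by internal edges."""
    all_leaves = frozenset(range(n_leaves))
    adj = _adjacency(edges)
    parts = set()
    for a, b in edges:
        if a >= 0 or b >= 0:
            continue  # only internal-internal edges split nontrivially
        # leaves on a's side when edge (a,b) is cut
        seen = {b}
        stack = [a]
        side = set()
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            if node >= 0:
                side.add(node)
            else:
                stack.extend(adj[node])
        side = frozenset(side)
        if 1 < len(side) < n_leaves - 1:
            parts.add(frozenset({side, all_leaves - side}))
    return parts


def least_squares_fit(edges, dmatrix, n_leaves):
    """Fit branch lengths by ordinary least squares; returns SSE."""
    pairs = list(itertools.combinations(range(n_leaves), 2))
    X = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    eindex = {e: k for k, e in enumerate(edges)}
    for r, (i, j) in enumerate(pairs):
        for e in _path_edges(edges, i, j):
            X[r, eindex[e]] = 1.0
        y[r] = dmatrix[i, j]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = X @ beta - y
    return float(resid @ resid)


def best_topology_by_enumeration(dmatrix, n_leaves):
    """Exhaustive oracle: the topology with minimum least-squares SSE."""
    best, best_sse = None, np.inf
    for t in all_topologies(n_leaves):
        sse = least_squares_fit(t, dmatrix, n_leaves)
        if sse < best_sse:
            best, best_sse = t, sse
    return best, best_sse
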