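"""Independent brute-force oracles for the graph metrics.

Everything here is deliberately naive — exhaustive enumeration of
paths, subsets and partitions — and shares no code path with the
package implementation.  Graphs are given as (n, edges) with 0-based
nodes and undirected edges.
"""

from __future__ import annotations

import itertools
from collections import deque


def adjacency(n, edges):
    adj = {v: set() for v in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def all_distances(n, edges):
    adj = adjacency(n, edges)
    return {v: bfs_distances(adj, v) for v in range(n)}


def is_connected(n, edges):
    if n == 0:
        return False
    return len(bfs_distances(adjacency(n, edges), 0)) == n


def shortest_paths_between(adj, s, t):
    """Every shortest s-t path, by DFS restricted to distance-decreasing steps."""
    dist_t = bfs_distances(adj, t)
    if s not in dist_t:
        return []
    paths = []

    def extend(path):
        v = path[-1]
        if v == t:
            paths.append(tuple(path))
            return
        for u in adj[v]:
            if u in dist_t and dist_t[u] == dist_t[v] - 1:
                extend(path + [u])

    extend([s])
    return paths


def node_betweenness(n, edges):
    """Freeman betweenness, fractional tied-path counting, endpoints excluded."""
    adj = adjacency(n, edges)
    score = [0.0] * n
    for s, t in itertools.combinations(range(n), 2):
        paths = shortest_paths_between(adj, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return score


def edge_betweenness(n, edges):
    """Per-edge betweenness (endpoint pairs included), same edge order."""
    adj = adjacency(n, edges)
    index = {frozenset(e): k for k, e in enumerate(edges)}
    score = [0.0] * len(edges)
    for s, t in itertools.combinations(range(n), 2):
        paths = shortest_paths_between(adj, s, t)
        for path in paths:
            for a, b in zip(path, path[1:]):
                score[index[frozenset((a, b))]] += 1.0 / len(paths)
    return score


def closeness(n, edges):
    dists = all_distances(n, edges)
    return [(n - 1) / sum(dists[v].values()) for v in range(n)]


def burt_constraint(n, edges):
    adj = adjacency(n, edges)

    def p(i, j):
        return (1.0 / len(adj[i])) if j in adj[i] else 0.0

    out = []
    for i in range(n):
        total = 0.0
        for j in adj[i]:
            indirect = sum(p(i, q) * p(q, j) for q in range(n)
                           if q not in (i, j))
            total += (p(i, j) + indirect) ** 2
        out.append(total)
    return out


def hub_score(n, edges, tol=1e-12, iterations=1_000_000):
    """Power iteration on A+I (strictly dominant eigenvalue), max scaled to 1."""
    import numpy as np

    a = np.eye(n)
    for u, v in edges:
        a[u, v] = a[v, u] = 1.0
    x = np.ones(n)
    for _ in range(iterations):
        y = a @ x
        y /= y.max()
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    return list(x / x.max())


def coreness(n, edges):
    adj = {v: set(nb) for v, nb in adjacency(n, edges).items()}
    core = [0] * n
    alive = set(range(n))
    k = 0
    while alive:
        k = max(k, min(len(adj[v]) for v in alive))
        peel = {v for v in alive if len(adj[v]) <= k}
        while peel:
            v = peel.pop()
            core[v] = k
            alive.discard(v)
            for u in adj[v]:
                adj[u].discard(v)
                if u in alive and len(adj[u]) <= k:
                    peel.add(u)
            adj[v] = set()
    return core


def common_neighbor_pairs(n, edges):
    """Common-neighbour count per unordered pair, in triu order."""
    adj = adjacency(n, edges)
    return [len(adj[a] & adj[b])
            for a, b in itertools.combinations(range(n), 2)]


def path_length_multiset(n, edges):
    dists = all_distances(n, edges)
    return [dists[a][b] for a, b in itertools.combinations(range(n), 2)]


def girth(n, edges):
    """Shortest cycle via edge removal + BFS; 0 if acyclic."""
    best = None
    adj = adjacency(n, edges)
    for a, b in edges:
        adj[a].discard(b)
        adj[b].discard(a)
        dist = bfs_distances(adj, a)
        if b in dist:
            cycle = dist[b] + 1
            best = cycle if best is None else min(best, cycle)
        adj[a].add(b)
        adj[b].add(a)
    return 0 if best is None else best


def transitivity(n, edges):
    adj = adjacency(n, edges)
    triangles = sum(1 for a, b, c in itertools.combinations(range(n), 3)
                    if b in adj[a] and c in adj[a] and c in adj[b])
    triples = sum(len(adj[v]) * (len(adj[v]) - 1) // 2 for v in range(n))
    return 0.0 if triples == 0 else 3.0 * triangles / triples


def density(n, edges):
    return 2.0 * len(edges) / (n * (n - 1))


def articulation_points(n, edges):
    count = 0
    for v in range(n):
        rest = [e for e in edges if v not in e]
        nodes = [u for u in range(n) if u != v]
        if not nodes:
            continue
        adj = {u: set() for u in nodes}
        for a, b in rest:
            adj[a].add(b)
            adj[b].add(a)
        seen = bfs_distances(adj, nodes[0])
        if len(seen) != len(nodes):
            count += 1
    return count


def motif4_census(n, edges):
    """Counts of connected induced 4-node subgraphs by isomorphism class."""
    adj = adjacency(n, edges)
    counts = {"path": 0, "star": 0, "cycle": 0, "paw": 0, "diamond": 0,
              "clique": 0}
    for quad in itertools.combinations(range(n), 4):
        qset = set(quad)
        degs = tuple(sorted(len(adj[v] & qset) for v in quad))
        m = sum(degs) // 2
        if m < 3 or 0 in degs:
            continue  # cannot be connected (3 edges + deg-0 = triangle+isolate)
        if m == 3:
            counts["path" if degs == (1, 1, 2, 2) else "star"] += 1
        elif m == 4:
            counts["cycle" if degs == (2, 2, 2, 2) else "paw"] += 1
        elif m == 5:
            counts["diamond"] += 1
        else:
            counts["clique"] += 1
    return counts


def modularity_q(n, edges, partition):
    """Newman-Girvan Q of a given partition (iterable of node sets)."""
    m = len(edges)
    deg = [0] * n
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    q = 0.0
    for comm in partition:
        comm = set(comm)
        internal = sum(1 for a, b in edges if a in comm and b in comm)
        d = sum(deg[v] for v in comm)
        q += internal / m - (d / (2.0 * m)) ** 2
    return q


def set_partitions(items):
    """All partitions of a list (exhaustive; use only for small n)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for k in range(len(partition)):
            yield (partition[:k] + [[first] + partition[k]]
                   + partition[k + 1:])
        yield [[first]] + partition


def max_modularity(n, edges):
    return max(modularity_q(n, edges, part)
               for part in set_partitions(list(range(n))))


def pair_table_oracle(structure):
    """Stack matching, written independently of the package parser."""
    table = [0] * (len(structure) + 1)
    stack = []
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            opener = stack.pop()
            table[opener], table[pos] = pos, opener
    assert not stack
    return {i: table[i] for i in range(1, len(structure) + 1)}


def auc_pair_counting(scores, labels, positive="positive"):
    """AUC as the Mann-Whitney pair statistic (ties count one half)."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
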