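"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive — exhaustive enumeration, direct
combinatorial summation, BFS path counting — and shares no code with the
package under test.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb


def bfs_shortest_path_counts(adj: dict, source):
    """Distances and shortest-path counts from source over an adjacency dict."""
    dist = {source: 0}
    sigma = {source: 1}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_betweenness(nodes, edges, directed: bool) -> dict:
    """Unnormalized betweenness by explicit enumeration of all node pairs.

    For each (s, t) pair and each intermediate v, counts the fraction of
    shortest s-t paths through v by combining path counts from s and
    reversed path counts to t.  Undirected graphs use unordered pairs.
    """
    adj: dict = {n: set() for n in nodes}
    radj: dict = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        radj[v].add(u)
        if not directed:
            adj[v].add(u)
            radj[u].add(v)

    bc = {n: 0.0 for n in nodes}
    pairs = (
        itertools.permutations(nodes, 2) if directed else itertools.combinations(nodes, 2)
    )
    for s, t in pairs:
        dist_s, sig_s = bfs_shortest_path_counts(adj, s)
        if t not in dist_s:
            continue
        dist_t, sig_t = bfs_shortest_path_counts(radj, t)
        d = dist_s[t]
        for v in nodes:
            if v in (s, t):
                continue
            if v in dist_s and v in dist_t and dist_s[v] + dist_t[v] == d:
                bc[v] += sig_s[v] * sig_t[v] / sig_s[t]
    return bc


def set_partitions(items):
    """All partitions of a list (restricted-growth-string enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def modularity(nodes, weighted_edges, partition) -> float:
    """Newman modularity Q of a partition of an undirected weighted graph."""
    m2 = 2.0 * sum(w for _, _, w in weighted_edges)
    if m2 == 0:
        return 0.0
    comm = {}
    for i, block in enumerate(partition):
        for n in block:
            comm[n] = i
    deg = {n: 0.0 for n in nodes}
    within = 0.0
    for u, v, w in weighted_edges:
        deg[u] += w
        deg[v] += w
        if comm[u] == comm[v]:
            within += w
    q = within / (m2 / 2.0)
    for block in partition:
        s = sum(deg[n] for n in block)
        q -= (s / m2) ** 2
    return q


def max_modularity(nodes, weighted_edges):
    """Exhaustive-search maximum modularity over all partitions (<= 8 nodes)."""
    best_q, best_p = float("-inf"), None
    for partition in set_partitions(list(nodes)):
        q = modularity(nodes, weighted_edges, partition)
        if q > best_q:
            best_q, best_p = q, partition
    return best_q, best_p


def sensitivity_points(ranked_pairs, ims, gold, thresholds):
    """Brute-force (n_predictions, tp, sensitivity) at each threshold."""
    gold = set(gold)
    out = []
    for thr in thresholds:
        kept = [p for p, im in zip(ranked_pairs, ims) if im >= thr]
        tp = sum(1 for p in kept if p in gold)
        out.append((len(kept), tp, tp / len(gold)))
    return out


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct combinatorial summation with exact integers."""
    total = comb(N, n)
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return num / total


def pairwise_auroc(scores_true, scores_false) -> float:
    """AUROC as the exhaustive probability a true edge outscores a false one."""
    wins = 0.0
    for st in scores_true:
        for sf in scores_false:
            if st > sf:
                wins += 1.0
            elif st == sf:
                wins += 0.5
    return wins / (len(scores_true) * len(scores_false))
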