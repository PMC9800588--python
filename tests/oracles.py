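"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately written from first principles (plain
loops, math.comb, DFS path enumeration) so the checks do not share code
paths with the package or its library dependencies.
"""

from __future__ import annotations

import math
from itertools import combinations


def average_ranks(values):
    """Midrank assignment computed by sorting positions by hand."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        rank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = rank
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of hand-computed average ranks."""
    rx = average_ranks(list(x))
    ry = average_ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    if vx == 0 or vy == 0:
        return float("nan")
    return cov / math.sqrt(vx * vy)


def hypergeom_tail(overlap, universe_size, term_size, deg_size):
    """P(X >= overlap) as an explicit sum of hypergeometric point masses."""
    total = math.comb(universe_size, deg_size)
    upper = min(term_size, deg_size)
    acc = 0
    for k in range(overlap, upper + 1):
        if universe_size - term_size < deg_size - k:
            continue
        acc += math.comb(term_size, k) * math.comb(universe_size - term_size, deg_size - k)
    return acc / total


def betweenness_by_path_enumeration(nodes, edges):
    """Normalized directed betweenness via DFS enumeration of simple paths.

    For every ordered pair (s, t) all simple paths are enumerated, the
    shortest length found, and each interior node of each shortest path
    credited with 1/#shortest_paths.  Feasible only for tiny graphs.
    """
    adj = {u: [] for u in nodes}
    for u, v in edges:
        if u != v:
            adj[u].append(v)
    bt = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = []
            stack = [(s, (s,))]
            while stack:
                u, path = stack.pop()
                if u == t:
                    paths.append(path)
                    continue
                for w in adj[u]:
                    if w not in path:
                        stack.append((w, path + (w,)))
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            sp = [p for p in paths if len(p) == shortest]
            for path in sp:
                for v in path[1:-1]:
                    bt[v] += 1.0 / len(sp)
    n = len(nodes)
    if n > 2:
        scale = 1.0 / ((n - 1) * (n - 2))
        bt = {v: b * scale for v, b in bt.items()}
    return bt


def betweenness_by_sigma_counting(nodes, edges):
    """Normalized directed betweenness via BFS shortest-path counting.

    Uses the combinatorial identity sigma_st(v) = sigma_sv * sigma_vt when
    d(s,v) + d(v,t) = d(s,t); independent of Brandes' dependency
    accumulation and feasible for mid-size graphs.
    """
    adj = {u: [] for u in nodes}
    for u, v in edges:
        if u != v:
            adj[u].append(v)

    def bfs(s):
        dist = {s: 0}
        sigma = {s: 1}
        queue = [s]
        for u in queue:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        return dist, sigma

    sp = {s: bfs(s) for s in nodes}
    bt = {v: 0.0 for v in nodes}
    for s in nodes:
        dist_s, sigma_s = sp[s]
        for t in nodes:
            if t == s or t not in dist_s:
                continue
            for v in nodes:
                if v in (s, t) or v not in dist_s:
                    continue
                dist_v, sigma_v = sp[v]
                if t in dist_v and dist_s[v] + dist_v[t] == dist_s[t]:
                    bt[v] += sigma_s[v] * sigma_v[t] / sigma_s[t]
    n = len(nodes)
    if n > 2:
        scale = 1.0 / ((n - 1) * (n - 2))
        bt = {v: b * scale for v, b in bt.items()}
    return bt


def wilcoxon_exact_greater(x, y):
    """Exact one-sided (greater) rank-sum p by full C(n+m, n) enumeration.

    Assumes a tie-free pooled sample.
    """
    pooled = list(x) + list(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = average_ranks(pooled)
    n = len(x)
    u_obs = sum(ranks[:n]) - n * (n + 1) / 2.0
    count = 0
    total = 0
    for subset in combinations(range(len(pooled)), n):
        u = sum(ranks[i] for i in subset) - n * (n + 1) / 2.0
        count += u >= u_obs
        total += 1
    return count / total


def bh_oracle(pvalues):
    """Step-up BH adjustment applied literally: q_i = min_{j>=i} m p_(j) / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        q[i] = running
    return q
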