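"""Independent brute-force oracles used to validate the library.

Everything here is deliberately naive — direct formulas, exhaustive
enumeration, recursive path search — and shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np

EPS = 1e-12


def average_ranks(values) -> list[float]:
    """Ranks with ties replaced by their average rank, 1-based."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def spearman_rho(x, y) -> float:
    return pearson(average_ranks(x), average_ranks(y))


def spearman_exact_permutation_p(x, y) -> float:
    """Two-tailed p over all n! orderings of y, |rho| >= |rho_obs| - EPS."""
    obs = abs(spearman_rho(x, y))
    y = list(y)
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(spearman_rho(x, perm)) >= obs - EPS:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# graph metrics by exhaustive enumeration (adjacency dict of |weights|)

def _all_simple_paths(adj: dict, src: int, dst: int):
    stack = [(src, [src])]
    while stack:
        node, path = stack.pop()
        if node == dst:
            yield path
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + [nxt]))


def shortest_paths(adj: dict, src: int, dst: int) -> tuple[float, list[list[int]]]:
    """(distance, list of shortest paths) with edge length 1/|w|; inf if none."""
    best = float("inf")
    paths: list[list[int]] = []
    for path in _all_simple_paths(adj, src, dst):
        length = sum(1.0 / adj[a][b] for a, b in zip(path, path[1:]))
        if length < best - EPS:
            best, paths = length, [path]
        elif abs(length - best) <= EPS:
            paths.append(path)
    return best, paths


def graph_metrics(weights: np.ndarray) -> dict:
    """Degree, strength, betweenness, global efficiency, transitivity."""
    n = weights.shape[0]
    adj = {
        i: {j: float(weights[i, j]) for j in range(n) if weights[i, j] > 0 and j != i}
        for i in range(n)
    }
    degree = np.array([len(adj[i]) for i in range(n)], dtype=float)
    strength = np.array([sum(adj[i].values()) for i in range(n)])
    betweenness = np.zeros(n)
    inv_dist_sum = 0.0
    for s, t in itertools.combinations(range(n), 2):
        dist, paths = shortest_paths(adj, s, t)
        if np.isfinite(dist):
            inv_dist_sum += 2.0 / dist  # both ordered pairs
            for path in paths:
                for node in path[1:-1]:
                    betweenness[node] += 1.0 / len(paths)
    efficiency = inv_dist_sum / (n * (n - 1)) if n > 1 else 0.0
    triangles = 0
    triplets = 0
    for i, j, k in itertools.combinations(range(n), 3):
        e = (j in adj[i]) + (k in adj[i]) + (k in adj[j])
        if e == 3:
            triangles += 1
        triplets += {0: 0, 1: 0, 2: 1, 3: 3}[e]
    transitivity = 3.0 * triangles / triplets if triplets else 0.0
    return {
        "degree": degree,
        "strength": strength,
        "betweenness": betweenness,
        "efficiency": efficiency,
        "transitivity": transitivity,
    }


def modularity_q(weights: np.ndarray, communities: list[set[int]]) -> float:
    """Direct evaluation of Newman's weighted modularity at resolution 1."""
    m2 = weights.sum()  # == 2m for a symmetric matrix
    if m2 == 0:
        return 0.0
    q = 0.0
    deg = weights.sum(axis=1)
    for comm in communities:
        idx = sorted(comm)
        within = weights[np.ix_(idx, idx)].sum()
        dc = deg[idx].sum()
        q += within / m2 - (dc / m2) ** 2
    return q


# ---------------------------------------------------------------------------
# microcircuit covariance algebra

def microcircuit_covariance(a1, a2, b1, b2, b3, residual_sds=(1.0, 1.0, 1.0)) -> dict:
    """All pairwise covariances of (PV_H, MC, PV_GL, GC) by path algebra."""
    s1, s2, s3 = (s**2 for s in residual_sds)
    v_pvh = 1.0
    v_mc = a1**2 * v_pvh + s1
    c_mc_pvh = a1 * v_pvh
    v_pvgl = a2**2 * v_mc + s2
    c_pvgl_mc = a2 * v_mc
    c_pvgl_pvh = a2 * c_mc_pvh
    c_gc_mc = b1 * v_mc + b2 * c_pvgl_mc + b3 * c_mc_pvh
    c_gc_pvgl = b1 * c_pvgl_mc + b2 * v_pvgl + b3 * c_pvgl_pvh
    c_gc_pvh = b1 * c_mc_pvh + b2 * c_pvgl_pvh + b3 * v_pvh
    v_gc = b1 * c_gc_mc + b2 * c_gc_pvgl + b3 * c_gc_pvh + s3
    return {
        ("PV_H", "PV_H"): v_pvh,
        ("MC", "MC"): v_mc,
        ("PV_GL", "PV_GL"): v_pvgl,
        ("GC", "GC"): v_gc,
        ("MC", "PV_H"): c_mc_pvh,
        ("PV_GL", "MC"): c_pvgl_mc,
        ("PV_GL", "PV_H"): c_pvgl_pvh,
        ("GC", "MC"): c_gc_mc,
        ("GC", "PV_GL"): c_gc_pvgl,
        ("GC", "PV_H"): c_gc_pvh,
    }
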