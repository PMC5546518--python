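"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as directly as possible from the definitions
(Floyd-Warshall relaxation, explicit pair enumeration, textbook ANOVA
sums of squares, step-up FDR) and never calls the code under test.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest hop counts by triple-loop relaxation."""
    n = adj.shape[0]
    d = np.where(np.asarray(adj, bool), 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_global_efficiency(adj: np.ndarray) -> float:
    """Mean of 1/L over ordered pairs, disconnected pairs contributing 0."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                s += 1.0 / d[i, j]
        out[i] = s / (n - 1)
    return out


def brute_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) >= 2:
            sub = adj[np.ix_(nbrs, nbrs)]
            total += brute_global_efficiency(sub)
    return total / n


def hand_anova_f(a, b) -> float:
    """Textbook one-way two-group ANOVA F from between/within mean squares."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    grand = (a.sum() + b.sum()) / (na + nb)
    ss_between = na * (a.mean() - grand) ** 2 + nb * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    return (ss_between / 1.0) / (ss_within / (na + nb - 2))


def hand_benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p values, computed from the definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def random_graph(rng: np.random.Generator, n_max: int = 12) -> np.ndarray:
    """Random small undirected graph (possibly disconnected/edgeless)."""
    n = int(rng.integers(4, n_max + 1))
    density = rng.uniform(0.05, 0.9)
    upper = rng.random((n, n)) < density
    adj = np.triu(upper, 1)
    return (adj | adj.T).astype(np.uint8)
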