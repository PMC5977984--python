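"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths (and the graph/SVM
libraries behind them): shortest paths are enumerated by exhaustive DFS,
the SVM dual is solved as an explicit box-constrained QP, and AUC is
counted pair by pair.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.optimize


def _all_simple_paths(adj: dict, s, t):
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nb in adj[node]:
            if nb not in path:
                stack.append((nb, path + [nb]))


def _shortest_paths(adj: dict, s, t):
    paths = list(_all_simple_paths(adj, s, t))
    if not paths:
        return []
    d = min(len(p) for p in paths)
    return [p for p in paths if len(p) == d]


def _adjacency(edges, nodes):
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def brute_betweenness(nodes, edges) -> dict:
    """Relative betweenness by exhaustive shortest-path enumeration."""
    nodes = list(nodes)
    n = len(nodes)
    adj = _adjacency(edges, nodes)
    pref = 2.0 / (n * n - 3 * n + 2)
    out = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        sps = _shortest_paths(adj, s, t)
        if not sps:
            continue
        sigma = len(sps)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in sps if v in p)
            out[v] += through / sigma
    return {v: pref * c for v, c in out.items()}


def brute_closeness(nodes, edges) -> dict:
    nodes = list(nodes)
    adj = _adjacency(edges, nodes)
    out = {}
    for v in nodes:
        farness = 0
        for u in nodes:
            if u == v:
                continue
            sps = _shortest_paths(adj, v, u)
            if sps:
                farness += len(sps[0]) - 1
        out[v] = 1.0 / farness if farness > 0 else 0.0
    return out


def brute_edge_betweenness(nodes, edges) -> dict:
    nodes = list(nodes)
    adj = _adjacency(edges, nodes)
    out = {tuple(sorted(e)): 0.0 for e in edges}
    for s, t in itertools.combinations(nodes, 2):
        sps = _shortest_paths(adj, s, t)
        if not sps:
            continue
        sigma = len(sps)
        for e in out:
            through = sum(
                1 for p in sps
                if any(tuple(sorted((p[i], p[i + 1]))) == e
                       for i in range(len(p) - 1)))
            out[e] += through / sigma
    return out


def qp_svm_rbf(x: np.ndarray, y: np.ndarray, c: float, gamma: float):
    """Soft-margin RBF-SVM dual solved as an explicit QP (SLSQP).

    Returns (alpha, bias, decision_function).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    sq = (np.sum(x ** 2, axis=1)[:, None] + np.sum(x ** 2, axis=1)[None, :]
          - 2.0 * x @ x.T)
    k = np.exp(-gamma * np.maximum(sq, 0.0))
    q = k * np.outer(y, y)

    def obj(a):
        return 0.5 * a @ q @ a - a.sum()

    def grad(a):
        return q @ a - 1.0

    res = scipy.optimize.minimize(
        obj, np.zeros(n), jac=grad, method="SLSQP",
        bounds=[(0.0, c)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y,
                      "jac": lambda a: y}],
        options={"ftol": 1e-14, "maxiter": 1000})
    alpha = res.x
    free = (alpha > 1e-6 * c) & (alpha < c * (1 - 1e-6))
    if free.any():
        b = float(np.mean(y[free] - (alpha * y) @ k[:, free]))
    else:
        sv = alpha > 1e-8
        vals = y[sv] - (alpha * y) @ k[:, sv]
        b = float(np.mean(vals)) if sv.any() else 0.0

    def decision(z):
        z = np.atleast_2d(np.asarray(z, dtype=float))
        sqz = (np.sum(z ** 2, axis=1)[:, None] + np.sum(x ** 2, axis=1)[None, :]
               - 2.0 * z @ x.T)
        kz = np.exp(-gamma * np.maximum(sqz, 0.0))
        return kz @ (alpha * y) + b

    return alpha, b, decision


def pair_count_auc(scores: np.ndarray, labels: np.ndarray,
                   pos_label=1) -> float:
    """AUC by counting concordant pairs; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == pos_label]
    neg = scores[labels != pos_label]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def step_up_bh(p: np.ndarray) -> np.ndarray:
    """Direct BH step-up computation (sorted cummin from the top)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
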