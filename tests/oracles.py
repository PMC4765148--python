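"""Independent brute-force oracles used to check sparseloc's implementations.

Everything here is deliberately naive (coordinate descent, BFS, direct set
arithmetic) and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def cd_penalized_ls(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    gamma: float = 0.0,
    n_iter: int = 200000,
    tol: float = 1e-12,
) -> np.ndarray:
    """Cyclic coordinate descent for sum(r^2) + lam*|b|_1 + gamma*|b|_2^2."""
    n, T = X.shape
    beta = np.zeros(T)
    col2 = (X ** 2).sum(axis=0)
    r = y.copy()
    for _ in range(n_iter):
        delta = 0.0
        for j in range(T):
            if col2[j] == 0:
                continue
            rho = 2 * X[:, j] @ r + 2 * col2[j] * beta[j]
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / (2 * (col2[j] + gamma))
            if new != beta[j]:
                r -= X[:, j] * (new - beta[j])
                delta = max(delta, abs(new - beta[j]))
                beta[j] = new
        if delta < tol:
            break
    return beta


def bfs_distance(adjacency: dict[str, set[str]], a: str, b: str) -> float:
    """Plain breadth-first shortest path on an undirected adjacency dict."""
    if a == b:
        return 0.0
    frontier = [a]
    seen = {a}
    d = 0
    while frontier:
        d += 1
        nxt = []
        for node in frontier:
            for nb in adjacency.get(node, ()):
                if nb == b:
                    return float(d)
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
        frontier = nxt
    return float("inf")


def metric_oracle(pairs, M):
    """All nine multi-label metrics by direct set arithmetic / bit matrices."""
    N = len(pairs)
    exact = sum(1 for t, p in pairs if set(t) == set(p)) / N
    ola = sum(len(set(t) & set(p)) for t, p in pairs) / sum(len(t) for t, _ in pairs)
    acc = sum(len(set(t) & set(p)) / len(set(t) | set(p)) for t, p in pairs) / N
    prec = sum(len(set(t) & set(p)) / len(set(p)) for t, p in pairs) / N
    rec = sum(len(set(t) & set(p)) / len(set(t)) for t, p in pairs) / N
    f1 = sum(2 * len(set(t) & set(p)) / (len(set(t)) + len(set(p))) for t, p in pairs) / N
    # hamming loss via dense 0/1 matrices
    Tm = np.zeros((N, M), dtype=int)
    Pm = np.zeros((N, M), dtype=int)
    for i, (t, p) in enumerate(pairs):
        for m in t:
            Tm[i, m - 1] = 1
        for m in p:
            Pm[i, m - 1] = 1
    hl = float((Tm != Pm).mean())
    tp = ((Tm == 1) & (Pm == 1)).sum(axis=0)
    fp = ((Tm == 0) & (Pm == 1)).sum(axis=0)
    fn = ((Tm == 1) & (Pm == 0)).sum(axis=0)
    micro = 2 * tp.sum() / (2 * tp.sum() + fp.sum() + fn.sum())
    per_class = np.where(2 * tp + fp + fn > 0, 2 * tp / np.maximum(2 * tp + fp + fn, 1), 0.0)
    macro = float(per_class.mean())
    return {
        "oaa": exact, "ola": ola, "accuracy": acc, "precision": prec,
        "recall": rec, "f1": f1, "hamming_loss": hl,
        "micro_f1": float(micro), "macro_f1": macro,
    }


def random_pairs(rng: np.random.Generator, n: int, M: int):
    """Random non-empty (truth, prediction) label-set pairs."""
    pairs = []
    for _ in range(n):
        t = set(rng.choice(M, size=rng.integers(1, M + 1), replace=False) + 1)
        p = set(rng.choice(M, size=rng.integers(1, M + 1), replace=False) + 1)
        pairs.append(({int(x) for x in t}, {int(x) for x in p}))
    return pairs
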