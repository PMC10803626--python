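"""Independent naive re-implementations used as test oracles.

Everything here is deliberately written the slow, literal way (path
enumeration, double loops, all-pairs statistics) and shares no code with
the package implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# -- DAG semantic similarity -------------------------------------------------

def enumerate_paths(parents: dict[str, set[str]], start: str, end: str) -> list[int]:
    """Lengths of every upward path from start to end."""
    if start == end:
        return [0]
    out = []
    for p in parents.get(start, ()):
        out.extend(1 + L for L in enumerate_paths(parents, p, end))
    return out


def naive_sc(parents: dict[str, set[str]], d: str, decay: float) -> dict[str, float]:
    """SC_d(t) = decay^(shortest upward path d->t), by path enumeration."""
    sc = {}
    stack, seen = [d], {d}
    while stack:
        node = stack.pop()
        for p in parents.get(node, ()):
            if p not in seen:
                seen.add(p)
                stack.append(p)
    for t in seen:
        lengths = enumerate_paths(parents, d, t)
        sc[t] = max(decay ** L for L in lengths)
    return sc


def naive_dss(parents: dict[str, set[str]], i: str, j: str, decay: float = 0.5) -> float:
    si, sj = naive_sc(parents, i, decay), naive_sc(parents, j, decay)
    shared = set(si) & set(sj)
    if not shared:
        return 0.0
    return sum(si[d] + sj[d] for d in shared) / (sum(si.values()) + sum(sj.values()))


# -- profile similarities ----------------------------------------------------

def naive_cosine(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
                continue
            ni = np.sqrt(sum(x * x for x in M[i]))
            nj = np.sqrt(sum(x * x for x in M[j]))
            if ni == 0 or nj == 0:
                out[i, j] = 0.0
            else:
                out[i, j] = sum(a * b for a, b in zip(M[i], M[j])) / (ni * nj)
    return out


def naive_gip(P: np.ndarray, gamma_prime: float = 1.0) -> np.ndarray:
    n = P.shape[0]
    gamma = gamma_prime / np.mean([sum(x * x for x in p) for p in P])
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2 = sum((a - b) ** 2 for a, b in zip(P[i], P[j]))
            out[i, j] = np.exp(-gamma * d2)
    np.fill_diagonal(out, 1.0)
    return out


def naive_lfs(dss: np.ndarray, sets_: list[list[int]]) -> np.ndarray:
    n = len(sets_)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            Di, Dj = sets_[i], sets_[j]
            if not Di or not Dj:
                out[i, j] = 0.0
                continue
            s1 = sum(max(dss[d, dp] for dp in Dj) for d in Di)
            s2 = sum(max(dss[d, dp] for dp in Di) for d in Dj)
            out[i, j] = (s1 + s2) / (len(Di) + len(Dj))
    return out


# -- sequences ---------------------------------------------------------------

def naive_lcs(s1: str, s2: str) -> int:
    dp = [[0] * (len(s2) + 1) for _ in range(len(s1) + 1)]
    for i in range(1, len(s1) + 1):
        for j in range(1, len(s2) + 1):
            if s1[i - 1] == s2[j - 1]:
                dp[i][j] = dp[i - 1][j - 1] + 1
            else:
                dp[i][j] = max(dp[i - 1][j], dp[i][j - 1])
    return dp[-1][-1]


def lcs_edit_cost(s1: str, s2: str) -> int:
    """Closed form for the ins=1/del=1/sub=2 cost."""
    return len(s1) + len(s2) - 2 * naive_lcs(s1, s2)


def brute_force_edit_cost(s1: str, s2: str) -> int:
    """Exhaustive recursion over edit scripts (tiny strings only)."""
    if not s1:
        return len(s2)
    if not s2:
        return len(s1)
    sub = brute_force_edit_cost(s1[1:], s2[1:]) + (0 if s1[0] == s2[0] else 2)
    ins = brute_force_edit_cost(s1, s2[1:]) + 1
    dele = brute_force_edit_cost(s1[1:], s2) + 1
    return min(sub, ins, dele)


# -- clustering / silhouette -------------------------------------------------

def naive_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    n = len(X)
    dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        own = labels == labels[i]
        a = dist[i, own & (np.arange(n) != i)].mean() if own.sum() > 1 else 0.0
        others = [dist[i, labels == c].mean() for c in np.unique(labels) if c != labels[i]]
        b = min(others)
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(vals))


# -- ranking metrics ---------------------------------------------------------

def allpairs_auc(y: np.ndarray, s: np.ndarray) -> float:
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum(1.0 if p > q else (0.5 if p == q else 0.0)
               for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def step_aupr(y: np.ndarray, s: np.ndarray) -> float:
    """AP = sum over thresholds of (recall step) * precision."""
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    total_pos = y.sum()
    ap = 0.0
    prev_recall = 0.0
    for thr in sorted(set(s), reverse=True):
        sel = s >= thr
        tp = y[sel].sum()
        precision = tp / sel.sum()
        recall = tp / total_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return float(ap)


# -- GAT layer ---------------------------------------------------------------

def naive_gat_forward(H, W, a_src, a_dst, weights, slope=0.2):
    """Per-node loop GAT layer: additive attention + log-weight, softmax,
    weighted sum, LeakyReLU."""
    def lrelu(x):
        return np.where(x > 0, x, slope * x)

    Hp = H @ W
    n = H.shape[0]
    out = np.zeros_like(Hp)
    for i in range(n):
        nbrs = np.flatnonzero(weights[i] > 0)
        logits = np.array([
            lrelu((Hp[i] @ a_src).item() + (Hp[j] @ a_dst).item()) + np.log(weights[i, j])
            for j in nbrs
        ])
        e = np.exp(logits - logits.max())
        alpha = e / e.sum()
        out[i] = lrelu((alpha[:, None] * Hp[nbrs]).sum(0))
    return out
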