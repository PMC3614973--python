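"""Independent brute-force oracles used only by the test suite.

Every function here recomputes a quantity by direct enumeration (double
loops, exhaustive simple-path search, power iteration), deliberately sharing
no code with the package implementation.
"""

from itertools import permutations

import numpy as np


# ---------------------------------------------------------------- SL oracle

def sl_oracle(epoch, m, lag, w1, w2, p_ref):
    """Synchronization likelihood by direct double loop over time pairs."""
    n_ch, n = epoch.shape
    n_emb = n - (m - 1) * lag
    rec = []
    for c in range(n_ch):
        E = np.array([[epoch[c, t + k * lag] for k in range(m)]
                      for t in range(n_emb)])
        R = np.zeros((n_emb, n_emb), dtype=bool)
        for i in range(n_emb):
            dists, js = [], []
            for j in range(n_emb):
                if w1 < abs(i - j) <= w2:
                    d2 = 0.0
                    for k in range(m):
                        d2 += (E[i, k] - E[j, k]) ** 2
                    dists.append(d2)
                    js.append(j)
            k_i = max(1, int(np.rint(p_ref * len(js))))
            eps = sorted(dists)[k_i - 1]
            for j, d2 in zip(js, dists):
                if d2 <= eps:
                    R[i, j] = True
        rec.append(R)
    S = np.zeros((n_ch, n_ch))
    for x in range(n_ch):
        for y in range(n_ch):
            if x == y:
                continue
            joint = np.sum(rec[x] & rec[y])
            S[x, y] = joint / rec[x].sum()
    out = 0.5 * (S + S.T)
    np.fill_diagonal(out, 0.0)
    return out


# -------------------------------------------------------- graph metric oracles

def _all_simple_paths(n, s, t):
    """Every simple s-t path in the complete graph on n nodes."""
    others = [v for v in range(n) if v not in (s, t)]
    paths = [(s, t)]
    for k in range(1, len(others) + 1):
        for mid in permutations(others, k):
            paths.append((s, *mid, t))
    return paths


def shortest_paths_oracle(w):
    """All-pairs shortest 1/w distances by exhaustive path enumeration."""
    n = w.shape[0]
    dist = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            best = np.inf
            for path in _all_simple_paths(n, s, t):
                length = sum(1.0 / w[a, b] for a, b in zip(path, path[1:]))
                best = min(best, length)
            dist[s, t] = best
    return dist


def betweenness_oracle(w, tol=1e-9):
    """Ordered-pair transit counts from exhaustive path enumeration."""
    n = w.shape[0]
    dist = shortest_paths_oracle(w)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            shortest = [
                p for p in _all_simple_paths(n, s, t)
                if abs(sum(1.0 / w[a, b] for a, b in zip(p, p[1:]))
                       - dist[s, t]) <= tol
            ]
            for i in range(n):
                if i in (s, t):
                    continue
                through = sum(1 for p in shortest if i in p[1:-1])
                bc[i] += through / len(shortest)
    return bc


def eigenvector_oracle(w, iters=10000, tol=1e-15):
    """Perron vector by plain power iteration."""
    n = w.shape[0]
    v = np.ones(n) / np.sqrt(n)
    for _ in range(iters):
        nxt = w @ v
        nxt = nxt / np.linalg.norm(nxt)
        if np.linalg.norm(nxt - v) < tol:
            v = nxt
            break
        v = nxt
    return v


def clustering_oracle(w):
    """Onnela weighted clustering by triple loop."""
    n = w.shape[0]
    what = w / w.max()
    C = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and w[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if len({i, j, h}) < 3:
                    continue
                total += (what[i, j] * what[j, h] * what[h, i]) ** (1.0 / 3.0)
        C[i] = total / (k * (k - 1))
    return C


# ------------------------------------------------------------------ AUC oracle

def auc_pair_counting(scores, labels):
    """Concordant-pair fraction: ties between case and control count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))
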