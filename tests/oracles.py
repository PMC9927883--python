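"""Independent brute-force reference implementations used as test oracles.

Deliberately naive and written against the definitions directly, sharing no
code with the package: an LZ76 parser on strings, a dict-based plug-in
transfer entropy, and graph metrics via explicit triangle enumeration,
Floyd-Warshall shortest paths and exhaustive partition search.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


# ---------------------------------------------------------------------------
# LZ76 exhaustive-history parser (string based)
# ---------------------------------------------------------------------------

def lz76_reference(bits) -> int:
    """Parse into words: extend the current word until it is not a substring
    of everything seen before it; then start a new word."""
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    words = 0
    i = 0
    while i < n:
        k = 1
        # grow while the candidate word appears in the history + prefix
        while i + k <= n and s[: i + k - 1].find(s[i : i + k]) != -1:
            k += 1
        words += 1
        i += k
    return words


# ---------------------------------------------------------------------------
# plug-in transfer entropy from explicit joint counts
# ---------------------------------------------------------------------------

def te_reference(x, y, delay: int) -> float:
    """TE_{x->y} = sum p(y+, y, x) log[ p(y+|y, x) / p(y+|y) ], natural log."""
    x, y = list(x), list(y)
    n = len(x) - delay
    triples = Counter((y[t + delay], y[t], x[t]) for t in range(n))
    pair_yx = Counter((y[t], x[t]) for t in range(n))
    pair_yy = Counter((y[t + delay], y[t]) for t in range(n))
    single_y = Counter(y[t] for t in range(n))
    te = 0.0
    for (ynext, ynow, xnow), c in triples.items():
        p3 = c / n
        p_cond_full = c / pair_yx[(ynow, xnow)]
        p_cond_self = pair_yy[(ynext, ynow)] / single_y[ynow]
        te += p3 * math.log(p_cond_full / p_cond_self)
    return max(te, 0.0)


# ---------------------------------------------------------------------------
# graph metrics by enumeration
# ---------------------------------------------------------------------------

def clustering_reference(w: np.ndarray) -> float:
    """Fagiolo directed weighted clustering via explicit triangle enumeration."""
    n = w.shape[0]
    a = (w > 0).astype(int)
    cw = np.cbrt(w)
    coefs = []
    for i in range(n):
        t = 0.0
        for j in range(n):
            for k in range(n):
                if j == i or k == i:
                    continue
                t += (
                    (cw[i, j] + cw[j, i])
                    * (cw[i, k] + cw[k, i])
                    * (cw[j, k] + cw[k, j])
                )
        t /= 2.0
        d_tot = a[i, :].sum() + a[:, i].sum()
        d_bi = sum(a[i, j] * a[j, i] for j in range(n))
        denom = d_tot * (d_tot - 1) - 2 * d_bi
        coefs.append(t / denom if denom > 0 else 0.0)
    return float(np.mean(coefs))


def efficiency_reference(w: np.ndarray) -> float:
    """Global efficiency via Floyd-Warshall on 1/weight path lengths."""
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                dist[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def strength_reference(w: np.ndarray) -> float:
    return float(np.mean([w[i, :].sum() + w[:, i].sum() for i in range(w.shape[0])]))


def partitions_reference(items: list[int]):
    """All set partitions, generated by assignment vectors (restricted growth)."""
    n = len(items)
    if n == 0:
        yield []
        return
    codes = [0] * n
    while True:
        groups: dict[int, set] = {}
        for it, c in zip(items, codes):
            groups.setdefault(c, set()).add(it)
        yield list(groups.values())
        # next restricted-growth string
        i = n - 1
        while i > 0:
            if codes[i] <= max(codes[:i]):
                codes[i] += 1
                for j in range(i + 1, n):
                    codes[j] = 0
                break
            i -= 1
        else:
            return


def modularity_q_reference(sym: np.ndarray, partition) -> float:
    """Newman weighted modularity of an undirected matrix, direct formula."""
    two_m = sym.sum()
    k = sym.sum(axis=1)
    comm_of = {}
    for ci, comm in enumerate(partition):
        for node in comm:
            comm_of[node] = ci
    q = 0.0
    n = sym.shape[0]
    for i in range(n):
        for j in range(n):
            if comm_of[i] == comm_of[j]:
                q += sym[i, j] - k[i] * k[j] / two_m
    return q / two_m


def best_modularity_reference(w: np.ndarray) -> tuple[float, list[set[int]]]:
    """Exhaustive maximum-modularity partition of the symmetrized graph."""
    sym = (w + w.T) / 2.0
    best_q, best_p = -np.inf, None
    for part in partitions_reference(list(range(w.shape[0]))):
        q = modularity_q_reference(sym, part)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p


def participation_reference(w: np.ndarray, partition, direction: str) -> float:
    """P_i = 1 - sum_m (k_im / k_i)^2 from the definition; zero-strength -> 0."""
    n = w.shape[0]
    vals = []
    for i in range(n):
        k_i = w[i, :].sum() if direction == "out" else w[:, i].sum()
        if k_i == 0:
            vals.append(0.0)
            continue
        acc = 0.0
        for comm in partition:
            idx = sorted(comm)
            k_im = w[i, idx].sum() if direction == "out" else w[idx, i].sum()
            acc += (k_im / k_i) ** 2
        vals.append(1.0 - acc)
    return float(np.mean(vals))
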