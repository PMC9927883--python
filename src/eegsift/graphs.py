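"""Global graph metrics of directed weighted connectivity networks.

Matrices are proportionally thresholded (top fraction of off-diagonal
weights retained, weights kept not binarized) over a sweep from 90% down to
10% in 2.5% steps, and six global metrics are averaged over the sweep:
directed weighted clustering coefficient (Fagiolo geometric-triangle form),
weighted global efficiency (shortest paths on 1/weight lengths), graph
strength, modularity of the symmetrized graph, and in-/out-strength
participation coefficients with respect to the detected partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectivity import ConnectivityMatrix

#: Retained fractions of the default threshold sweep: 0.90 down to 0.10 in 0.025 steps.
DEFAULT_SWEEP: tuple[float, ...] = tuple(
    float(f) for f in np.round(np.arange(0.90, 0.10 - 1e-9, -0.025), 3)
)

#: Graphs up to this size get exact (exhaustive-partition) modularity
#: (Bell(6) = 203 partitions; beyond this the sweep cost explodes).
_EXACT_MODULARITY_MAX_N = 6

METRIC_NAMES: tuple[str, ...] = (
    "clustering_coefficient",
    "global_efficiency",
    "strength",
    "modularity",
    "participation_in",
    "participation_out",
)


@dataclass
class GraphMetricSet:
    clustering_coefficient: float
    global_efficiency: float
    strength: float
    modularity: float
    participation_in: float
    participation_out: float
    band: str = ""

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def _as_matrix(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    w = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square weight matrix")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    return w.copy()


def proportional_threshold(
    m: ConnectivityMatrix | np.ndarray, retain_fraction: float
) -> np.ndarray:
    """Keep the strongest ``retain_fraction`` of off-diagonal weights.

    The cut keeps the top ``ceil(f * n_offdiag)`` entries by weight; ties at
    the cut value are all kept, and surviving weights are preserved (not
    binarized). ``retain_fraction=1`` is the identity on off-diagonal
    entries.
    """
    if not (0 < retain_fraction <= 1):
        raise ValueError("retain_fraction must be in (0, 1]")
    w = _as_matrix(m)
    np.fill_diagonal(w, 0.0)
    if retain_fraction == 1.0:
        return w
    n = w.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = w[off]
    k = int(np.ceil(retain_fraction * vals.size))
    cut = np.sort(vals)[::-1][k - 1]
    out = np.where(w >= cut, w, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def _clustering_coefficient_wd(w: np.ndarray) -> float:
    """Directed weighted clustering coefficient, averaged over nodes (Fagiolo)."""
    a = (w > 0).astype(float)
    wr = np.cbrt(w)
    t = np.diag((wr + wr.T) @ (wr + wr.T) @ (wr + wr.T)) / 2.0
    d_tot = a.sum(axis=0) + a.sum(axis=1)
    d_bi = np.diag(a @ a)
    denom = d_tot * (d_tot - 1) - 2 * d_bi
    c = np.zeros(w.shape[0])
    ok = denom > 0
    c[ok] = t[ok] / denom[ok]
    return float(c.mean())


def _global_efficiency_wd(w: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered pairs; 1/inf -> 0."""
    n = w.shape[0]
    if n < 2:
        return 0.0
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    d = dijkstra(csr_matrix(lengths), directed=True)
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].mean())


def _strength(w: np.ndarray) -> float:
    """Mean over nodes of total (in + out) connection weight."""
    return float((w.sum(axis=0) + w.sum(axis=1)).mean())


def _modularity_q(sym: np.ndarray, communities: list[set[int]]) -> float:
    two_m = sym.sum()
    if two_m == 0:
        return 0.0
    k = sym.sum(axis=1)
    q = 0.0
    for comm in communities:
        idx = sorted(comm)
        q += sym[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
    return float(q)


def _set_partitions(items: list[int]):
    """All partitions of a set (restricted growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] | {first}] + smaller[i + 1 :]
        yield [{first}] + smaller


def detect_communities(w: np.ndarray) -> list[set[int]]:
    """Community partition of the symmetrized graph (W + W^T) / 2.

    Exhaustive maximum-modularity search for tiny graphs (n <= 6),
    greedy agglomerative modularity optimization otherwise.
    """
    sym = (w + w.T) / 2.0
    n = sym.shape[0]
    if sym.sum() == 0:
        return [set(range(n))]
    if n <= _EXACT_MODULARITY_MAX_N:
        best_q, best = -np.inf, [set(range(n))]
        for part in _set_partitions(list(range(n))):
            q = _modularity_q(sym, part)
            if q > best_q:
                best_q, best = q, part
        return best
    g = nx.from_numpy_array(sym)
    comms = nx.community.greedy_modularity_communities(g, weight="weight")
    return [set(c) for c in comms]


def _participation(w: np.ndarray, communities: list[set[int]], axis: int) -> float:
    """Mean participation coefficient; axis=1 -> out-strength, axis=0 -> in-strength."""
    n = w.shape[0]
    strength = w.sum(axis=1) if axis == 1 else w.sum(axis=0)
    p = np.zeros(n)
    for comm in communities:
        idx = sorted(comm)
        if axis == 1:
            kc = w[:, idx].sum(axis=1)
        else:
            kc = w[idx, :].sum(axis=0)
        ok = strength > 0
        p[ok] += (kc[ok] / strength[ok]) ** 2
    out = np.zeros(n)
    ok = strength > 0
    out[ok] = 1.0 - p[ok]
    return float(out.mean())


def compute_metrics(
    w: ConnectivityMatrix | np.ndarray, band: str = ""
) -> GraphMetricSet:
    """All six global metrics of one (thresholded) directed weighted matrix.

    An empty graph returns zeros (modularity defined as 0 with a warning).
    """
    w = _as_matrix(w)
    np.fill_diagonal(w, 0.0)
    if not (w > 0).any():
        warnings.warn("empty graph: all metrics set to 0", RuntimeWarning)
        return GraphMetricSet(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, band=band)
    communities = detect_communities(w)
    sym = (w + w.T) / 2.0
    return GraphMetricSet(
        clustering_coefficient=_clustering_coefficient_wd(w),
        global_efficiency=_global_efficiency_wd(w),
        strength=_strength(w),
        modularity=_modularity_q(sym, communities),
        participation_in=_participation(w, communities, axis=0),
        participation_out=_participation(w, communities, axis=1),
        band=band,
    )


def metrics_over_sweep(
    m: ConnectivityMatrix | np.ndarray,
    fractions: tuple[float, ...] = DEFAULT_SWEEP,
    band: str = "",
) -> GraphMetricSet:
    """Arithmetic mean of each metric over the proportional-threshold sweep."""
    if not fractions:
        raise ValueError("empty threshold sweep")
    acc = {k: 0.0 for k in METRIC_NAMES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for f in fractions:
            ms = compute_metrics(proportional_threshold(m, f), band=band)
            for k in METRIC_NAMES:
                acc[k] += getattr(ms, k)
    n = len(fractions)
    return GraphMetricSet(**{k: v / n for k, v in acc.items()}, band=band)
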