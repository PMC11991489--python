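"""Binary graph metrics over sparsity-thresholded connectivity matrices.

A weighted PLV matrix is binarized by *sparsity*: the strongest
``round(s * N(N-1)/2)`` off-diagonal weights become edges.  On the binary
graph the module computes

* ``C``     -- binary (Watts-Strogatz) clustering coefficient, the mean over
  nodes of triangle density among neighbors;
* ``L``     -- characteristic path length, mean shortest-path length over
  connected ordered pairs;
* ``E_g``   -- global efficiency, ``1/(N(N-1)) * sum_{i!=j} 1/d_ij`` with a
  zero contribution for disconnected pairs;
* ``E_loc`` -- local efficiency, the mean over nodes of the efficiency of the
  neighbor subgraph with the ``1/(k_i(k_i-1))`` normalization (degree < 2
  contributes 0);
* ``sigma = gamma / lambda = (C/C_random) / (L/L_random)`` against an
  ensemble of degree-preserving rewired null networks (Maslov-Sneppen double
  edge swaps, 100 x E attempted swaps per null).  ``sigma > 1`` is the usual
  small-world criterion.

Shortest paths use scipy's C-level BFS so 1000-null ensembles on 100-node
graphs stay fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path


class GraphError(ValueError):
    """Degenerate graph for the requested metric."""


def _check_adjacency(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise GraphError(f"adjacency must be square, got {a.shape}")
    a = (a != 0).astype(np.int8)
    if not np.array_equal(a, a.T):
        raise GraphError("adjacency must be symmetric")
    np.fill_diagonal(a, 0)
    return a


def threshold_by_sparsity(w: np.ndarray, s: float) -> np.ndarray:
    """Binarize a symmetric weight matrix keeping the top ``round(s*N(N-1)/2)``
    off-diagonal weights as edges.

    Tie-break is deterministic: weights sorted descending, then by (row, col)
    index of the upper triangle.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise GraphError(f"weight matrix must be square, got {w.shape}")
    if not np.allclose(w, w.T):
        raise GraphError("weight matrix must be symmetric")
    if not 0 < s <= 1:
        raise GraphError(f"sparsity must lie in (0, 1], got {s}")
    n = w.shape[0]
    n_possible = n * (n - 1) // 2
    n_edges = int(round(s * n_possible))
    if n_edges == 0:
        raise GraphError(f"sparsity {s} yields 0 edges for N={n}")
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, -w[iu, ju]))  # weight desc, then (i, j)
    keep = order[:n_edges]
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[keep], ju[keep]] = 1
    return a | a.T


def _distances(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths (inf for disconnected pairs)."""
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def clustering_coefficient(a: np.ndarray) -> float:
    """Binary clustering: mean over nodes of 2*triangles / (k*(k-1)); k<2 -> 0."""
    a = _check_adjacency(a).astype(np.int64)
    deg = a.sum(axis=1).astype(float)
    tri = np.diag(a @ a @ a).astype(float)  # 2 * triangles per node
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return float(c.mean())


def char_path_length(a: np.ndarray) -> float:
    """Mean shortest-path length over connected ordered pairs.

    Raises on an edgeless graph; a disconnected graph is averaged over its
    connected pairs only (flag this upstream if it matters).
    """
    a = _check_adjacency(a)
    if a.sum() == 0:
        raise GraphError("characteristic path length undefined for an edgeless graph")
    d = _distances(a)
    mask = np.isfinite(d) & ~np.eye(a.shape[0], dtype=bool)
    return float(d[mask].mean())


def global_efficiency(a: np.ndarray) -> float:
    """1/(N(N-1)) * sum of inverse shortest-path lengths (disconnected -> 0)."""
    a = _check_adjacency(a)
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = _distances(a)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def local_efficiency(a: np.ndarray) -> float:
    """Mean over nodes of sum_{j,h in N_i} (1/d_jh) / (k_i (k_i - 1)).

    Distances d_jh are taken within node i's neighbor subgraph; nodes of
    degree < 2 contribute 0.
    """
    a = _check_adjacency(a)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(a[i])
        k = nb.size
        if k < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        d = _distances(sub)
        off = ~np.eye(k, dtype=bool)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
        total += inv[off].sum() / (k * (k - 1))
    return float(total / n)


# ---------------------------------------------------------------------------
# Degree-preserving null ensemble
# ---------------------------------------------------------------------------

def double_edge_swap(a: np.ndarray, n_swaps: int, rng: np.random.Generator) -> np.ndarray:
    """Maslov-Sneppen rewiring: ``n_swaps`` attempted double-edge swaps.

    Picks two edges (u,v), (x,y) and rewires to (u,x), (v,y) when this
    creates no self-loop or multi-edge.  Degree sequence is preserved exactly.
    """
    a = _check_adjacency(a).copy()
    iu, ju = np.nonzero(np.triu(a, k=1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    m = len(edges)
    if m < 2:
        return a
    pick = rng.integers(0, m, size=(n_swaps, 2))
    flip = rng.integers(0, 2, size=n_swaps)
    for t in range(n_swaps):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flip[t]:
            x, y = y, x
        if len({u, v, x, y}) < 4:
            continue
        if a[u, x] or a[v, y]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, x] = a[x, u] = 1
        a[v, y] = a[y, v] = 1
        edges[e1] = (u, x)
        edges[e2] = (v, y)
    return a


@dataclass
class NetworkNull:
    """Ensemble means of the rewired null networks."""

    c_random: float
    l_random: float
    n_random: int
    degenerate: bool = False  # True when the degree sequence admitted no rewiring


def random_null(
    a: np.ndarray,
    n_random: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
    swaps_per_edge: int = 100,
) -> NetworkNull:
    """Degree-preserving null ensemble: C_random and L_random means."""
    a = _check_adjacency(a)
    n_edges = int(a.sum() // 2)
    if n_edges < 2:
        raise GraphError("need at least 2 edges to build a null ensemble")
    rng = np.random.default_rng(seed)
    cs = np.empty(n_random)
    ls = np.empty(n_random)
    changed = False
    for r in range(n_random):
        b = double_edge_swap(a, swaps_per_edge * n_edges, rng)
        changed = changed or not np.array_equal(a, b)
        cs[r] = clustering_coefficient(b)
        ls[r] = char_path_length(b)
    return NetworkNull(
        c_random=float(cs.mean()),
        l_random=float(ls.mean()),
        n_random=n_random,
        degenerate=not changed,
    )


def small_world_sigma(
    a: np.ndarray,
    n_random: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
) -> dict:
    """sigma = gamma/lambda = (C/C_random)/(L/L_random) plus its ingredients."""
    a = _check_adjacency(a)
    c = clustering_coefficient(a)
    l = char_path_length(a)
    null = random_null(a, n_random=n_random, seed=seed)
    gamma = c / null.c_random if null.c_random > 0 else np.nan
    lam = l / null.l_random if null.l_random > 0 else np.nan
    return {
        "C_actual": c,
        "L_actual": l,
        "C_random": null.c_random,
        "L_random": null.l_random,
        "gamma": float(gamma),
        "lambda": float(lam),
        "sigma": float(gamma / lam),
        "degenerate_null": null.degenerate,
    }


def metrics_over_sparsity(
    w: np.ndarray,
    sparsities=None,
    n_random: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
) -> dict:
    """Threshold at each sparsity level and compute sigma, E_g, E_loc per level.

    Returns ``{"levels": [...], "aggregate": {...}}`` where each level holds
    sparsity, sigma/gamma/lambda, C/L (actual and random means), E_g, E_loc,
    and the aggregate is the arithmetic mean of each metric across levels.
    """
    if sparsities is None:
        sparsities = np.round(np.arange(0.22, 0.295, 0.01), 10)
    seq = (seed if isinstance(seed, np.random.SeedSequence)
           else np.random.SeedSequence(seed))
    children = seq.spawn(len(list(sparsities)))
    levels = []
    for s, child in zip(sparsities, children):
        a = threshold_by_sparsity(w, float(s))
        entry = {"sparsity": float(s), "n_edges": int(a.sum() // 2)}
        try:
            entry.update(small_world_sigma(a, n_random=n_random, seed=child))
            entry["E_g"] = global_efficiency(a)
            entry["E_loc"] = local_efficiency(a)
        except GraphError as exc:
            entry["error"] = str(exc)
        levels.append(entry)
    keys = ("sigma", "gamma", "lambda", "C_actual", "L_actual", "E_g", "E_loc")
    ok = [lv for lv in levels if "error" not in lv]
    aggregate = {k: float(np.mean([lv[k] for lv in ok])) for k in keys} if ok else {}
    return {"levels": levels, "aggregate": aggregate}
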