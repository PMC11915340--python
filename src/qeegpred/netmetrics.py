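"""Graph-theoretical metrics of 19-node weighted functional networks.

Edges are band-limited PLV values between electrode pairs.  Because graph
metrics depend on how many edges are retained, each metric is computed over
a proportional-threshold sparsity grid (0.10 to 0.50 in steps of 0.05) and
summarised by its normalised area under the curve - the trapezoidal
integral divided by the grid width, i.e. the sparsity-averaged metric on
its own scale.

* CPL: characteristic path length over edge lengths 1/weight (integration);
  computed within the largest connected component when thresholding
  disconnects the graph.
* CC: mean weighted clustering coefficient, Onnela geometric-mean-triangle
  formulation on max-normalised weights (segregation).
* Sigma: small-worldness gamma/lambda, where gamma = CC / <CC_null> and
  lambda = CPL / <CPL_null> over an ensemble of degree-preserving
  (Maslov-Sneppen rewired) null networks with the original weights
  shuffled onto the rewired topology; Sigma > 1 indicates small-world
  organisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numba
import numpy as np

logger = logging.getLogger(__name__)


@numba.njit(cache=True)
def _floyd_warshall(dist: np.ndarray) -> np.ndarray:
    """In-place all-pairs shortest paths on a dense length matrix (inf = no edge)."""
    n = dist.shape[0]
    for k in range(n):
        for i in range(n):
            dik = dist[i, k]
            if dik == np.inf:
                continue
            for j in range(n):
                d = dik + dist[k, j]
                if d < dist[i, j]:
                    dist[i, j] = d
    return dist


@numba.njit(cache=True)
def _rewire_kernel(edges: np.ndarray, n_nodes: int, target: int,
                   e1s: np.ndarray, e2s: np.ndarray, flips: np.ndarray) -> int:
    """Maslov-Sneppen double-edge swaps in place; returns swaps performed."""
    m = edges.shape[0]
    present = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    for k in range(m):
        a, b = edges[k, 0], edges[k, 1]
        present[a, b] = True
        present[b, a] = True
    done = 0
    for t in range(e1s.shape[0]):
        if done >= target:
            break
        e1, e2 = e1s[t], e2s[t]
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if flips[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if present[a, d] or present[c, b]:
            continue
        present[a, b] = False
        present[b, a] = False
        present[c, d] = False
        present[d, c] = False
        present[a, d] = True
        present[d, a] = True
        present[c, b] = True
        present[b, c] = True
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        done += 1
    return done

__all__ = [
    "SPARSITIES",
    "ThresholdedGraph",
    "NetMetricCurve",
    "threshold_proportional",
    "characteristic_path_length",
    "clustering_coefficient",
    "small_worldness",
    "auc_over_sparsities",
    "metric_curves",
]

#: Sparsity grid: 0.10 to 0.50, step 0.05.
SPARSITIES: np.ndarray = np.round(np.arange(0.10, 0.5001, 0.05), 2)


@dataclass
class ThresholdedGraph:
    """Weighted adjacency after keeping the strongest fraction of edges."""

    adjacency: np.ndarray
    sparsity: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int((self.adjacency[iu] > 0).sum())


@dataclass
class NetMetricCurve:
    metric: str                      # CPL | CC | Sigma
    band: str
    sparsities: np.ndarray
    values: np.ndarray
    auc_value: float
    n_null: int = 0
    gamma: np.ndarray | None = None
    lam: np.ndarray | None = None


def threshold_proportional(values: np.ndarray, sparsity: float) -> ThresholdedGraph:
    """Keep the top round(sparsity * n_pairs) edges by weight.

    Ties at the cutoff are broken by fixed lexicographic electrode-pair
    order, so the retained edge set is deterministic.  Retained weights are
    the original values (weighted graph); self-loops are removed.
    """
    if not 0.0 < sparsity <= 1.0:
        raise ValueError("sparsity must lie in (0, 1]")
    w = np.asarray(values, dtype=float)
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    flat = w[iu]
    k = int(np.rint(sparsity * flat.size))
    # sort by descending weight, then (i, j) lexicographic for ties
    order = np.lexsort((iu[1], iu[0], -flat))
    keep = order[:k]
    adj = np.zeros_like(w)
    adj[iu[0][keep], iu[1][keep]] = flat[keep]
    adj = adj + adj.T
    return ThresholdedGraph(adjacency=adj, sparsity=float(sparsity))


def _shortest_path_matrix(adj: np.ndarray) -> np.ndarray:
    lengths = np.full(adj.shape, np.inf)
    mask = adj > 0
    lengths[mask] = 1.0 / adj[mask]
    np.fill_diagonal(lengths, 0.0)
    return _floyd_warshall(lengths)


def _cpl_array(adj: np.ndarray) -> float:
    if not (adj > 0).any():
        logger.warning("empty graph: CPL undefined")
        return float("nan")
    dist = _shortest_path_matrix(adj)
    finite = np.isfinite(dist)
    reach = finite.sum(axis=1)                  # component size per node
    n = adj.shape[0]
    if reach.min() < n:
        anchor = int(reach.argmax())            # first largest component
        nodes = np.flatnonzero(finite[anchor])
        logger.debug("graph disconnected: CPL over largest component (%d/%d nodes)",
                     len(nodes), n)
        dist = dist[np.ix_(nodes, nodes)]
    m = dist.shape[0]
    if m < 2:
        return float("nan")
    return float(dist.sum() / (m * (m - 1)))    # symmetric, zero diagonal


def _cc_array(adj: np.ndarray) -> float:
    w_max = adj.max()
    if w_max <= 0:
        return 0.0
    w = np.cbrt(adj / w_max)
    t = np.diagonal(w @ w @ w)  # 2 x triangle intensity per node
    k = (adj > 0).sum(axis=1)
    denom = k * (k - 1)
    c = np.where(denom > 0, t / np.maximum(denom, 1), 0.0)
    return float(c.mean())


def characteristic_path_length(g: ThresholdedGraph) -> float:
    """Mean shortest path length (edge length = 1/weight) between node pairs.

    If thresholding disconnects the graph, the mean is taken within the
    largest connected component and the disconnection is logged.
    """
    return _cpl_array(g.adjacency)


def clustering_coefficient(g: ThresholdedGraph) -> float:
    """Mean weighted clustering coefficient (Onnela formulation).

    Weights are normalised by the maximum; per-node coefficient is the sum
    of geometric-mean triangle intensities over k(k-1); degree < 2 nodes
    contribute 0.
    """
    return _cc_array(g.adjacency)


def _rewire_edges(edges: np.ndarray, n_nodes: int, rng: np.random.Generator,
                  swaps_per_edge: int = 10) -> np.ndarray:
    """Degree-preserving Maslov-Sneppen rewiring of an undirected edge list."""
    edges = np.ascontiguousarray(edges, dtype=np.int64).copy()
    m = len(edges)
    if m < 2:
        return edges
    target = swaps_per_edge * m
    max_attempts = 30 * target
    r = rng.integers(0, np.int64(m) * m * 2, size=max_attempts)
    e1s = (r % m).astype(np.int64)
    e2s = ((r // m) % m).astype(np.int64)
    flips = (r // (m * m) > 0).astype(np.bool_)
    done = _rewire_kernel(edges, n_nodes, target, e1s, e2s, flips)
    if done < target:
        logger.debug("rewiring reached %d of %d target swaps", done, target)
    return edges


def small_worldness(g: ThresholdedGraph, n_null: int = 100, seed=None,
                    swaps_per_edge: int = 10) -> tuple[float, float, float]:
    """Sigma = gamma / lambda against degree-preserving rewired nulls.

    Returns ``(sigma, gamma, lam)``.  Null networks keep the degree
    sequence; the original edge weights are randomly re-assigned to the
    rewired edges.  Too-sparse graphs (no valid nulls) yield NaN.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    adj = g.adjacency
    n = adj.shape[0]
    iu = np.triu_indices(n, k=1)
    mask = adj[iu] > 0
    edges = np.column_stack([iu[0][mask], iu[1][mask]])
    weights = adj[iu][mask]
    if len(edges) < 2:
        logger.warning("too few edges for null-model generation")
        return float("nan"), float("nan"), float("nan")
    cc = clustering_coefficient(g)
    cpl = characteristic_path_length(g)

    def null_ensemble(k):
        ccs = np.empty(k)
        cpls = np.empty(k)
        for i in range(k):
            e = _rewire_edges(edges, n, rng, swaps_per_edge)
            w = rng.permutation(weights)
            null_adj = np.zeros_like(adj)
            null_adj[e[:, 0], e[:, 1]] = w
            null_adj = null_adj + null_adj.T
            ccs[i] = _cc_array(null_adj)
            cpls[i] = _cpl_array(null_adj)
        return ccs, cpls

    cc_null, cpl_null = null_ensemble(n_null)
    if np.nanmean(cc_null) == 0 and n_null > 0:
        # sparse graphs can draw an all-triangle-free ensemble; one redraw
        extra_cc, extra_cpl = null_ensemble(n_null)
        cc_null = np.concatenate([cc_null, extra_cc])
        cpl_null = np.concatenate([cpl_null, extra_cpl])
    mean_cc = np.nanmean(cc_null)
    mean_cpl = np.nanmean(cpl_null)
    if not (mean_cc > 0 and np.isfinite(mean_cpl) and mean_cpl > 0):
        return float("nan"), float("nan"), float("nan")
    gamma = cc / mean_cc
    lam = cpl / mean_cpl
    return float(gamma / lam), float(gamma), float(lam)


def auc_over_sparsities(values: np.ndarray, sparsities: np.ndarray = SPARSITIES) -> float:
    """Normalised area under the metric-vs-sparsity curve.

    Trapezoidal integral over the grid divided by the grid width, i.e. the
    sparsity-averaged metric on its own scale.  Any missing grid value makes
    the summary missing.
    """
    values = np.asarray(values, dtype=float)
    sparsities = np.asarray(sparsities, dtype=float)
    if values.shape != sparsities.shape:
        raise ValueError("values and sparsities must align")
    if not np.isfinite(values).all():
        logger.warning("missing values on the sparsity grid: AUC flagged missing")
        return float("nan")
    width = sparsities[-1] - sparsities[0]
    return float(np.trapezoid(values, sparsities) / width)


def metric_curves(values: np.ndarray, band: str = "",
                  sparsities: np.ndarray = SPARSITIES,
                  n_null: int = 100, seed=None) -> dict[str, NetMetricCurve]:
    """CPL, CC and Sigma curves plus AUC summaries over the sparsity grid.

    One thresholded graph per sparsity is shared by all three metrics;
    Sigma is computed per sparsity and then AUC-summarised like the others.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sparsities = np.asarray(sparsities, dtype=float)
    cpl = np.empty_like(sparsities)
    cc = np.empty_like(sparsities)
    sig = np.empty_like(sparsities)
    gam = np.empty_like(sparsities)
    lam = np.empty_like(sparsities)
    for i, s in enumerate(sparsities):
        g = threshold_proportional(values, s)
        cpl[i] = characteristic_path_length(g)
        cc[i] = clustering_coefficient(g)
        sig[i], gam[i], lam[i] = small_worldness(g, n_null=n_null, seed=rng)
    return {
        "CPL": NetMetricCurve("CPL", band, sparsities, cpl, auc_over_sparsities(cpl, sparsities)),
        "CC": NetMetricCurve("CC", band, sparsities, cc, auc_over_sparsities(cc, sparsities)),
        "Sigma": NetMetricCurve("Sigma", band, sparsities, sig,
                                auc_over_sparsities(sig, sparsities),
                                n_null=n_null, gamma=gam, lam=lam),
    }
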