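"""Global graph measures on masked weighted connectomes.

Four measures summarize each network: overall connectivity (computed in
:mod:`connqc.connectome`), average binary node degree (nu), normalized
weighted clustering coefficient (gamma) and normalized weighted global
efficiency (e_global). Clustering and efficiency are normalized by their mean
over an ensemble of degree-preserving random rewirings of the network (default
100 nulls), so gamma > 1 indicates more segregation, and e_global < 1 less
integration, than expected for the network's size, sparsity and degree
sequence.

Conventions follow the standard brain-connectivity-toolbox definitions:
weighted clustering uses the Onnela geometric-mean triangle intensity on
max-normalized weights; efficiency uses shortest paths under edge length
1 / weight, with disconnected pairs contributing zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectome import Connectome, overall_connectivity

log = logging.getLogger(__name__)


def _as_weights(c) -> np.ndarray:
    return c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)


def average_node_degree(c) -> float:
    """Mean over nodes of the count of incident nonzero-weight edges."""
    W = _as_weights(c)
    return float((W > 0).sum(axis=1).mean())


def weighted_clustering(c) -> float:
    """Network-average weighted clustering coefficient.

    Per node: sum over neighbour pairs of the geometric mean of the three
    max-normalized triangle weights, divided by k (k - 1). Nodes with degree
    < 2 contribute 0. For binary weights this reduces to the fraction of
    closed neighbour pairs.
    """
    W = _as_weights(c)
    wmax = W.max()
    if wmax == 0:
        return 0.0
    Wn = W / wmax
    cr = np.cbrt(Wn)
    # diag(cr^3)[i] = 2 * sum of triangle intensities at node i
    tri2 = np.einsum("ij,jk,ki->i", cr, cr, cr)
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(denom > 0, tri2 / denom, 0.0)
    return float(ci.mean())


def weighted_global_efficiency(c) -> float:
    """Mean over ordered node pairs of 1 / shortest-path distance.

    Edge length is 1 / weight (stronger connections are shorter); pairs with
    no connecting path contribute zero.
    """
    W = _as_weights(c)
    n = W.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, 0.0)
    D = dijkstra(csr_matrix(L), directed=False)
    iu = np.triu_indices(n, 1)
    d = D[iu]
    inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv.sum() * 2.0 / (n * (n - 1)))


# ---------------------------------------------------------------------------
# degree-preserving null ensemble
# ---------------------------------------------------------------------------

def rewire_preserving_degree(W: np.ndarray, rng: np.random.Generator,
                             swaps_per_edge: float = 10.0) -> np.ndarray:
    """Degree-preserving double-edge-swap rewiring, weights carried with edges.

    Two edges (a, b) and (c, d) are replaced by (a, d) and (c, b) when that
    creates no self-loop or duplicate edge; each surviving edge keeps its
    original weight. The binary degree sequence is preserved exactly. If no
    valid swap can be found within the attempt budget (e.g. a complete
    graph), the partial (possibly identity) rewiring is returned and logged.
    """
    n = W.shape[0]
    iu = np.triu_indices(n, 1)
    present = W[iu] > 0
    u = iu[0][present].astype(np.int64)
    v = iu[1][present].astype(np.int64)
    w = W[iu][present].copy()
    m = u.size
    if m < 2:
        return W.copy()

    def key(a, b):
        return (a * n + b) if a < b else (b * n + a)

    edge_set = {key(a, b) for a, b in zip(u, v)}
    target = int(round(swaps_per_edge * m))
    max_attempts = max(100, 100 * target)
    swaps = attempts = 0
    # draw randomness in blocks; the loop itself is branch-heavy python
    block = max(256, 2 * target)
    ii = jj = cc = None
    pos = block
    while swaps < target and attempts < max_attempts:
        if pos >= block:
            ii = rng.integers(m, size=block)
            jj = rng.integers(m, size=block)
            cc = rng.random(block) < 0.5
            pos = 0
        i, j, flip = ii[pos], jj[pos], cc[pos]
        pos += 1
        attempts += 1
        if i == j:
            continue
        a, b = u[i], v[i]
        c, d = u[j], v[j]
        if flip:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        k1, k2 = key(a, d), key(c, b)
        if k1 in edge_set or k2 in edge_set or k1 == k2:
            continue
        edge_set.discard(key(a, b))
        edge_set.discard(key(c, d))
        edge_set.add(k1)
        edge_set.add(k2)
        u[i], v[i] = min(a, d), max(a, d)
        u[j], v[j] = min(c, b), max(c, b)
        swaps += 1
    if swaps < target:
        log.debug("rewiring stopped at %d/%d swaps after %d attempts",
                  swaps, target, attempts)

    Wn = np.zeros_like(W)
    Wn[u, v] = w
    Wn[v, u] = w
    return Wn


@dataclass
class NullEnsemble:
    """Raw clustering/efficiency values over degree-preserving null networks."""

    n_null: int
    seed: int
    swaps_per_edge: float
    clustering: np.ndarray = field(repr=False)
    efficiency: np.ndarray = field(repr=False)

    @property
    def mean_clustering(self) -> float:
        return float(self.clustering.mean())

    @property
    def mean_efficiency(self) -> float:
        return float(self.efficiency.mean())


def make_null_ensemble(c, n_null: int = 100, seed: int = 0,
                       swaps_per_edge: float = 10.0) -> NullEnsemble:
    """Build the null ensemble for a connectome (>= 4 edges required)."""
    W = _as_weights(c)
    if int((np.triu(W, 1) > 0).sum()) < 4:
        raise ValueError("need at least four edges to build a null ensemble")
    rng = np.random.default_rng(seed)
    cl = np.empty(n_null)
    ef = np.empty(n_null)
    for k in range(n_null):
        Wn = rewire_preserving_degree(W, rng, swaps_per_edge)
        cl[k] = weighted_clustering(Wn)
        ef[k] = weighted_global_efficiency(Wn)
    return NullEnsemble(n_null=n_null, seed=seed, swaps_per_edge=swaps_per_edge,
                        clustering=cl, efficiency=ef)


def normalized_measures(c, ensemble: NullEnsemble) -> tuple[float, float]:
    """(gamma, e_global): observed clustering/efficiency over the null means."""
    mc, me = ensemble.mean_clustering, ensemble.mean_efficiency
    if mc == 0 or me == 0:
        raise ValueError("null-ensemble mean is zero; normalized measure undefined")
    return (weighted_clustering(c) / mc, weighted_global_efficiency(c) / me)


@dataclass
class GraphMeasures:
    overall: float
    nu: float
    gamma: float
    e_global: float
    sparsity: float


def graph_measures(c: Connectome, mask, n_null: int = 100, seed: int = 0,
                   swaps_per_edge: float = 10.0) -> GraphMeasures:
    """All four global measures for one individual connectome.

    Overall connectivity is computed on the unmasked connectome; nu, gamma
    and e_global on the group-mask-restricted network, with an independent
    seeded null ensemble per call.
    """
    from .connectome import apply_group_mask

    overall = overall_connectivity(c)
    masked = apply_group_mask(c, mask)
    ens = make_null_ensemble(masked, n_null=n_null, seed=seed,
                             swaps_per_edge=swaps_per_edge)
    gamma, e_glob = normalized_measures(masked, ens)
    return GraphMeasures(overall=overall,
                         nu=average_node_degree(masked),
                         gamma=gamma, e_global=e_glob,
                         sparsity=mask.sparsity)
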