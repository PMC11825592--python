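"""Node centrality at each density, integrated across the sweep.

Two centrality metrics are computed on the binarized thresholded networks:

* node degree — the number of connections a parcel has;
* betweenness centrality (BC) — for node v, the sum over unordered node
  pairs {s, t} (s, t != v) of sigma_st(v) / sigma_st, where sigma_st is the
  number of shortest s-t paths and sigma_st(v) those passing through v.
  Computed with Brandes' dependency-accumulation algorithm on the unweighted
  graph; pairs with no connecting path contribute zero; values are left
  unnormalized (raw fractional pair counts), since group comparisons at a
  fixed node count are invariant to the normalization constant.

Per subject, each metric yields a (densities x nodes) profile which is then
summed across the density sweep ("area under the curve") to obtain a single
threshold-independent value per node.

Proportional thresholds are nested (the edge set at a lower density is a
subset of the edge set at a higher density, given the deterministic
tie-break), so profiles are computed from a single descending edge sort with
edges added incrementally; this is exactly equivalent to thresholding each
density independently and is cross-checked against that path in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .processing import (
    ProcessedNetwork,
    ThresholdedNetwork,
    sorted_edges,
    sweep_densities,
    target_edge_count,
)

METRICS = ("degree", "betweenness")


@dataclass(frozen=True)
class CentralityProfile:
    """Per-density, per-node values of one metric for one subject."""

    metric_name: str
    values: np.ndarray  # (n_densities, n_nodes)
    densities: tuple[int, ...]  # integer percents, strictly increasing
    labels: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.densities), len(self.labels)):
            raise ValueError("profile shape does not match densities x labels")
        if len(self.densities) == 0:
            raise ValueError("empty density sweep")
        if np.any(np.diff(self.densities) <= 0):
            raise ValueError("densities must be strictly increasing")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class IntegratedCentrality:
    """One density-integrated (summed) metric value per node."""

    metric_name: str
    values: np.ndarray  # (n_nodes,)
    labels: tuple[str, ...]

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])


def node_degree(network: ThresholdedNetwork) -> np.ndarray:
    """Number of edges incident to each node."""
    return np.asarray(network.adjacency, dtype=np.int64).sum(axis=1)


def _brandes(adjacency: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness on an undirected unweighted graph.

    Level-synchronous Brandes: per source, a BFS records path counts sigma
    and level sets; dependencies delta are then accumulated backwards,
    restricting edges to consecutive BFS levels. Each unordered pair is
    counted once (the source loop double-counts, hence the final halving).
    """
    adj = np.asarray(adjacency, dtype=bool)
    n = adj.shape[0]
    adj_f = adj.astype(float)
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, -1, dtype=np.int64)
        sigma = np.zeros(n)
        dist[s] = 0
        sigma[s] = 1.0
        frontier = np.zeros(n, dtype=bool)
        frontier[s] = True
        levels = [frontier]
        while True:
            paths_in = sigma[frontier] @ adj_f[frontier]
            newly = (paths_in > 0) & (dist < 0)
            if not newly.any():
                break
            dist[newly] = len(levels)
            sigma[newly] = paths_in[newly]
            frontier = newly
            levels.append(newly)
        delta = np.zeros(n)
        for lev in range(len(levels) - 1, 0, -1):
            w_mask = levels[lev]
            coef = np.zeros(n)
            coef[w_mask] = (1.0 + delta[w_mask]) / sigma[w_mask]
            back = adj_f @ coef
            v_mask = levels[lev - 1]
            delta[v_mask] += sigma[v_mask] * back[v_mask]
        delta[s] = 0.0
        bc += delta
    return bc / 2.0


def betweenness_centrality(network: ThresholdedNetwork) -> np.ndarray:
    """Per-node betweenness of a thresholded network (may be disconnected)."""
    return _brandes(network.adjacency)


def integrate_across_densities(profile: CentralityProfile) -> IntegratedCentrality:
    """Sum the metric over the density sweep (plain column sum, no weighting)."""
    return IntegratedCentrality(
        metric_name=profile.metric_name,
        values=profile.values.sum(axis=0),
        labels=profile.labels,
    )


def centrality_profile(
    network: ProcessedNetwork,
    metric: str,
    low: int = 20,
    high: int = 40,
    step: int = 1,
) -> CentralityProfile:
    """Metric profile over the density sweep via incremental edge addition."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    densities = sweep_densities(low, high, step)
    n = network.n_nodes
    ei, ej = sorted_edges(network.weights)
    ks = [min(target_edge_count(n, d / 100.0), len(ei)) for d in densities]
    values = np.zeros((len(densities), n))
    if metric == "degree":
        deg = np.zeros(n, dtype=np.int64)
        prev = 0
        for row, k in enumerate(ks):
            if k > prev:
                deg = deg + np.bincount(ei[prev:k], minlength=n)
                deg = deg + np.bincount(ej[prev:k], minlength=n)
                prev = k
            values[row] = deg
    else:
        adj = np.zeros((n, n), dtype=bool)
        prev = 0
        for row, k in enumerate(ks):
            if k > prev:
                adj[ei[prev:k], ej[prev:k]] = True
                adj[ej[prev:k], ei[prev:k]] = True
                prev = k
            values[row] = _brandes(adj)
    return CentralityProfile(
        metric_name=metric,
        values=values,
        densities=tuple(densities),
        labels=network.labels,
    )


def integrated_degree(
    network: ProcessedNetwork, low: int = 20, high: int = 40, step: int = 1
) -> np.ndarray:
    """Density-integrated degree per node, without building full profiles.

    Equivalent to ``integrate_across_densities(centrality_profile(...,
    'degree'))`` but avoids allocating the per-density matrix; used in
    calibration loops where only the integrated vector is needed.
    """
    densities = sweep_densities(low, high, step)
    n = network.n_nodes
    ei, ej = sorted_edges(network.weights)
    ks = [min(target_edge_count(n, d / 100.0), len(ei)) for d in densities]
    # each edge batch contributes to all remaining sweep levels
    total = np.zeros(n, dtype=np.int64)
    prev = 0
    remaining = len(ks)
    for k in ks:
        if k > prev:
            batch = np.bincount(ei[prev:k], minlength=n) + np.bincount(
                ej[prev:k], minlength=n
            )
            total += batch * remaining
            prev = k
        remaining -= 1
    return total.astype(float)


def fragmentation_flags(
    network: ProcessedNetwork, low: int = 20, high: int = 40, step: int = 1
) -> dict[int, bool]:
    """Which densities of the sweep leave the network fragmented.

    Proportional thresholds are nested, so connectivity is monotone across
    the sweep: once the graph is connected at some density it stays
    connected at every higher one. Only the leading fragmented prefix needs
    explicit component counts.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    densities = sweep_densities(low, high, step)
    n = network.n_nodes
    ei, ej = sorted_edges(network.weights)
    ks = [min(target_edge_count(n, d / 100.0), len(ei)) for d in densities]

    def connected_at(k: int) -> bool:
        graph = coo_matrix(
            (np.ones(k), (ei[:k], ej[:k])), shape=(n, n)
        )
        return connected_components(graph, directed=False)[0] == 1

    flags: dict[int, bool] = {}
    still_fragmented = True
    for d, k in zip(densities, ks):
        if still_fragmented:
            still_fragmented = not connected_at(k)
        flags[d] = still_fragmented
    return flags


@dataclass(frozen=True)
class SubjectCentrality:
    """End-to-end per-subject result: integrated metrics + diagnostics."""

    degree: IntegratedCentrality
    betweenness: IntegratedCentrality | None
    fragmented_densities: tuple[int, ...]


def subject_centrality(
    connectome,
    low: int = 20,
    high: int = 40,
    step: int = 1,
    metrics: tuple[str, ...] = METRICS,
) -> SubjectCentrality:
    """Full deterministic map: normalize -> symmetrize -> sweep -> integrate."""
    from .processing import process_connectome

    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}")
    network = process_connectome(connectome)
    frag = fragmentation_flags(network, low, high, step)
    # degree is cheap and needed by most downstream consumers: always computed
    degree = IntegratedCentrality(
        "degree", integrated_degree(network, low, high, step), network.labels
    )
    betweenness = None
    if "betweenness" in metrics:
        betweenness = integrate_across_densities(
            centrality_profile(network, "betweenness", low, high, step)
        )
    return SubjectCentrality(
        degree=degree,
        betweenness=betweenness,
        fragmented_densities=tuple(d for d, f in frag.items() if f),
    )
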