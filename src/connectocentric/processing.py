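"""Raw streamline-count matrices -> density-thresholded binary networks.

Probabilistic tractography yields an asymmetric nonnegative count matrix per
subject (entry [i, j] = streamlines seeded in region i that reached region
j) together with per-region waytotals (total streamlines propagated from
each seed region). The processing chain is:

1. row-wise normalization by the seed region's waytotal,
2. symmetrization by the arithmetic mean of the matrix and its transpose,
3. proportional thresholding to a target network density, keeping the
   strongest connections and binarizing.

Densities are handled as exact integer percents throughout the sweep to
avoid floating-point drift in the density grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def _round_half_away(x: float) -> int:
    """Round half away from zero (for nonnegative x: floor(x + 0.5))."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class ProcessedNetwork:
    """Symmetric, waytotal-normalized, zero-diagonal weighted network."""

    labels: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if len(self.labels) != w.shape[0]:
            raise ValueError("labels do not match matrix size")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class ThresholdedNetwork:
    """Binary undirected network at one proportional density.

    ``density`` is the requested edge fraction; ``achieved_density`` may be
    lower when the weighted network has fewer positive connections than the
    target edge count.
    """

    labels: tuple[str, ...]
    adjacency: np.ndarray
    density: float
    edge_count: int
    achieved_density: float = field(default=float("nan"))

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.isnan(self.achieved_density):
            n = a.shape[0]
            object.__setattr__(
                self, "achieved_density", self.edge_count / (n * (n - 1) / 2)
            )

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def normalize_by_waytotal(connectome) -> np.ndarray:
    """Divide each row of the count matrix by that region's waytotal.

    Row i holds streamline counts seeded from region i, so the waytotal of
    region i is the natural denominator turning counts into per-seed
    connection probabilities. The diagonal stays zero.
    """
    counts = np.asarray(connectome.counts, dtype=float)
    waytotals = np.asarray(connectome.waytotals, dtype=float)
    if np.any(waytotals <= 0):
        bad = connectome.labels[int(np.argmax(waytotals <= 0))]
        raise ValueError(f"non-positive waytotal for region {bad!r}")
    return counts / waytotals[:, None]


def symmetrize(weights: np.ndarray, labels: tuple[str, ...]) -> ProcessedNetwork:
    """Render a directed weight matrix undirected: (W + W.T) / 2."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    return ProcessedNetwork(labels=tuple(labels), weights=(w + w.T) / 2.0)


def process_connectome(connectome) -> ProcessedNetwork:
    """Normalization followed by symmetrization (steps 1-2)."""
    return symmetrize(normalize_by_waytotal(connectome), connectome.labels)


def sorted_edges(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positive undirected edges ordered by descending weight.

    Ties are broken deterministically by ascending (row, column) index over
    the upper triangle, so thresholding is reproducible regardless of the
    platform's sort internals.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    pos = vals > 0
    iu, ju, vals = iu[pos], ju[pos], vals[pos]
    # lexsort: last key is primary
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


def target_edge_count(n_nodes: int, density: float) -> int:
    """k = round(density * n(n-1)/2), half away from zero."""
    return _round_half_away(density * n_nodes * (n_nodes - 1) / 2.0)


def threshold_to_density(
    network: ProcessedNetwork, density: float
) -> ThresholdedNetwork:
    """Keep the k strongest undirected connections and binarize.

    k = round(density * n(n-1)/2). If fewer than k positive weights exist,
    all positive connections are kept and the achieved density is reported
    (lower than requested).
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = network.n_nodes
    k = target_edge_count(n, density)
    ei, ej = sorted_edges(network.weights)
    kept = min(k, len(ei))
    adj = np.zeros((n, n), dtype=np.int8)
    adj[ei[:kept], ej[:kept]] = 1
    adj[ej[:kept], ei[:kept]] = 1
    return ThresholdedNetwork(
        labels=network.labels,
        adjacency=adj,
        density=density,
        edge_count=kept,
        achieved_density=kept / (n * (n - 1) / 2),
    )


def density_sweep(
    network: ProcessedNetwork,
    low: int = 20,
    high: int = 40,
    step: int = 1,
) -> list[ThresholdedNetwork]:
    """Threshold at every integer-percent density in {low, low+step, .., high}."""
    for name, v in (("low", low), ("high", high), ("step", step)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer percent")
    low, high, step = int(low), int(high), int(step)
    if not (1 <= low <= high <= 100) or step < 1:
        raise ValueError("need 1 <= low <= high <= 100 and step >= 1")
    return [
        threshold_to_density(network, pct / 100.0)
        for pct in range(low, high + 1, step)
    ]


def sweep_densities(low: int = 20, high: int = 40, step: int = 1) -> list[int]:
    """The integer-percent density grid of a sweep."""
    return list(range(int(low), int(high) + 1, int(step)))


def is_fragmented(network: ThresholdedNetwork) -> bool:
    """True iff the binary graph has more than one connected component.

    Isolated nodes count as components. Fragmented graphs make path-based
    centrality degenerate, which is why the sweep's lower density bound is
    chosen high enough to avoid fragmentation in practice.
    """
    n_comp, _ = connected_components(
        csr_matrix(network.adjacency), directed=False
    )
    return int(n_comp) > 1
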