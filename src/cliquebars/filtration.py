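"""Density-indexed clique (flag) filtrations of weighted networks.

The filtration descends through the edge weights: starting from the bare
vertex set, edges enter from heaviest to lightest, ties entering together.
Each step is re-indexed by the *edge density* rho of the thresholded
subgraph — the fraction of the network's edges present — so that barcodes
from networks with different weight scales share a common [0, 1] coordinate.
The clique complex of each thresholded subgraph, truncated at triangles
(dimension 2), yields the filtration fed to persistent homology.

Because only the descending *rank* of the weights matters, the filtration is
invariant under any strictly increasing transform of the weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .network import WeightedNetwork

__all__ = [
    "ThresholdSequence",
    "FilteredSimplex",
    "DensityFiltration",
    "threshold_sequence",
    "build_density_filtration",
]


@dataclass
class ThresholdSequence:
    """Distinct edge weights in decreasing order with their densities.

    ``densities[i]`` is the fraction of the network's edges with weight
    >= ``distinct_weights[i]``; it ends at exactly 1.  Tied weights collapse
    into a single step, so densities may jump by more than ``1/|E|``.
    """

    distinct_weights: np.ndarray  # strictly decreasing, length n
    densities: np.ndarray  # nondecreasing in (0, 1], length n
    edge_counts: np.ndarray  # cumulative edge count per step

    def __post_init__(self) -> None:
        dw = np.asarray(self.distinct_weights, dtype=float)
        rho = np.asarray(self.densities, dtype=float)
        if len(dw) != len(rho):
            raise ValueError("weights and densities must align")
        if len(dw):  # empty sequences allowed for edgeless networks
            if np.any(np.diff(dw) >= 0):
                raise ValueError("distinct_weights must be strictly decreasing")
            if np.any(np.diff(rho) < 0) or rho[-1] != 1.0:
                raise ValueError("densities must be nondecreasing and end at 1")
        self.distinct_weights, self.densities = dw, rho

    @property
    def n_steps(self) -> int:
        return len(self.distinct_weights)


@dataclass(frozen=True, order=True)
class FilteredSimplex:
    """A simplex (1-3 sorted vertices) with its density appearance time."""

    appearance: float
    dim: int
    vertices: tuple[int, ...]


@dataclass
class DensityFiltration:
    """Clique filtration with density-valued appearance times, dim <= 2.

    Simplices are stored as arrays (vertices implicitly at appearance 0;
    edges and triangles with their densities) sorted by
    ``(appearance, dim, vertex tuple)`` — a valid filtration order in which
    every face precedes its cofaces.
    """

    network: WeightedNetwork
    thresholds: ThresholdSequence
    max_dim: int
    edges: np.ndarray  # (E, 2) int, filtration-sorted
    edge_appearance: np.ndarray  # (E,) float
    triangles: np.ndarray  # (T, 3) int, filtration-sorted (empty if max_dim < 2)
    triangle_appearance: np.ndarray  # (T,)
    density_cap: float | None = None

    @property
    def n_vertices(self) -> int:
        return self.network.n_nodes

    def simplices(self) -> Iterator[FilteredSimplex]:
        """Yield all simplices in filtration order (small-graph/test use)."""
        out = [FilteredSimplex(0.0, 0, (v,)) for v in range(self.n_vertices)]
        out += [
            FilteredSimplex(float(a), 1, (int(i), int(j)))
            for (i, j), a in zip(self.edges, self.edge_appearance)
        ]
        out += [
            FilteredSimplex(float(a), 2, (int(i), int(j), int(k)))
            for (i, j, k), a in zip(self.triangles, self.triangle_appearance)
        ]
        return iter(sorted(out))


def threshold_sequence(
    network: WeightedNetwork, use_absolute_weights: bool = False
) -> ThresholdSequence:
    """Distinct descending weights and the density reached at each step.

    The density denominator is the network's own edge count (``N(N-1)/2``
    for a correlation matrix, which is a complete graph).
    """
    w = network.edge_weights()
    if use_absolute_weights:
        w = np.abs(w)
    if w.size == 0:  # edgeless: empty sequence, vertices only
        return ThresholdSequence(np.empty(0), np.empty(0), np.empty(0, int))
    uniq, counts = np.unique(w, return_counts=True)  # ascending
    dw = uniq[::-1]
    cum = np.cumsum(counts[::-1])
    rho = cum / len(w)
    return ThresholdSequence(dw, rho, cum)


def _edge_densities(
    network: WeightedNetwork, thresholds: ThresholdSequence,
    use_absolute_weights: bool,
) -> np.ndarray:
    w = network.edge_weights()
    if use_absolute_weights:
        w = np.abs(w)
    # distinct weights ascending for searchsorted
    asc = thresholds.distinct_weights[::-1]
    step = len(asc) - 1 - np.searchsorted(asc, w)  # index into descending order
    return thresholds.densities[step]


def _enumerate_triangles(
    network: WeightedNetwork, edge_app_matrix: np.ndarray, cap: float | None
) -> tuple[np.ndarray, np.ndarray]:
    """All 3-cliques with appearance = max of their edges' appearances."""
    n = network.n_nodes
    adj = (
        network.mask
        if network.mask is not None
        else ~np.eye(n, dtype=bool)
    )
    tri_chunks, app_chunks = [], []
    for i in range(n - 2):
        nbrs = np.nonzero(adj[i, i + 1:])[0] + i + 1
        if len(nbrs) < 2:
            continue
        sub = np.triu(adj[np.ix_(nbrs, nbrs)], k=1)
        jj, kk = np.nonzero(sub)
        if len(jj) == 0:
            continue
        j, k = nbrs[jj], nbrs[kk]
        app = np.maximum(
            edge_app_matrix[i, j],
            np.maximum(edge_app_matrix[i, k], edge_app_matrix[j, k]),
        )
        if cap is not None:
            keep = app <= cap
            j, k, app = j[keep], k[keep], app[keep]
            if len(j) == 0:
                continue
        tri = np.empty((len(j), 3), dtype=np.int64)
        tri[:, 0] = i
        tri[:, 1] = j
        tri[:, 2] = k
        tri_chunks.append(tri)
        app_chunks.append(app)
    if not tri_chunks:
        return np.empty((0, 3), dtype=np.int64), np.empty(0)
    return np.concatenate(tri_chunks), np.concatenate(app_chunks)


def build_density_filtration(
    network: WeightedNetwork,
    max_dim: int = 2,
    density_cap: float | None = None,
    use_absolute_weights: bool = False,
) -> DensityFiltration:
    """Build the clique filtration of `network` in density coordinates.

    Parameters
    ----------
    network
        The weighted graph.
    max_dim
        1 (graph only: components) or 2 (include triangles: cycles too).
    density_cap
        If given (in (0, 1]), simplices appearing above this density are
        omitted.  This truncates the filtration: barcodes change wherever a
        feature would have died above the cap, so it is a documented
        performance escape hatch, not a default.
    use_absolute_weights
        Rank edges by |weight| instead of signed weight.  Off by default:
        negative correlations stay in, ordered by signed value, entering
        last.
    """
    if max_dim not in (1, 2):
        raise ValueError(f"max_dim must be 1 or 2, got {max_dim}")
    if density_cap is not None and not (0.0 < density_cap <= 1.0):
        raise ValueError(f"density_cap must be in (0, 1], got {density_cap}")

    thresholds = threshold_sequence(network, use_absolute_weights)
    iu, ju = network.edge_index()
    app = _edge_densities(network, thresholds, use_absolute_weights)

    if density_cap is not None:
        keep = app <= density_cap
        iu, ju, app = iu[keep], ju[keep], app[keep]

    # filtration sort: (appearance, vertex tuple)
    order = np.lexsort((ju, iu, app))
    edges = np.column_stack([iu, ju]).astype(np.int64)[order]
    app = app[order]

    if max_dim == 2:
        n = network.n_nodes
        app_m = np.zeros((n, n))
        full_iu, full_ju = network.edge_index()
        full_app = _edge_densities(network, thresholds, use_absolute_weights)
        app_m[full_iu, full_ju] = full_app
        app_m[full_ju, full_iu] = full_app
        tris, tri_app = _enumerate_triangles(network, app_m, density_cap)
        torder = np.lexsort((tris[:, 2], tris[:, 1], tris[:, 0], tri_app))
        tris, tri_app = tris[torder], tri_app[torder]
    else:
        tris = np.empty((0, 3), dtype=np.int64)
        tri_app = np.empty(0)

    return DensityFiltration(
        network=network,
        thresholds=thresholds,
        max_dim=max_dim,
        edges=edges,
        edge_appearance=app,
        triangles=tris,
        triangle_appearance=tri_app,
        density_cap=density_cap,
    )
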