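"""Independent reference implementations used only as test oracles.

Deliberately naive and separate from the package's optimized code paths:

* `dense_reduction_barcode` — textbook left-to-right persistence reduction
  over GF(2) on the full boundary matrix (dense numpy bool columns, no
  clearing, no union-find).
* `betti_numbers_at` — Betti numbers of the thresholded clique complex from
  GF(2) boundary-matrix ranks.
* `clique_complex_at` — exhaustive clique enumeration of a thresholded
  subgraph via networkx.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from cliquebars.filtration import DensityFiltration
from cliquebars.persistence import Bar, Barcode


def dense_reduction_barcode(filtration: DensityFiltration) -> Barcode:
    """Persistence by the unoptimized standard algorithm (dims 0 and 1)."""
    simplices = list(filtration.simplices())
    m = len(simplices)
    index = {s.vertices: i for i, s in enumerate(simplices)}
    cols = []
    for s in simplices:
        col = np.zeros(m, dtype=bool)
        if s.dim > 0:
            for face in itertools.combinations(s.vertices, s.dim):
                col[index[face]] = True
        cols.append(col)

    pivot_of_row: dict[int, int] = {}
    for j in range(m):
        col = cols[j]
        while col.any():
            low = int(np.nonzero(col)[0].max())
            if low not in pivot_of_row:
                pivot_of_row[low] = j
                break
            col = col ^ cols[pivot_of_row[low]]
        cols[j] = col

    bars = []
    paired_rows = pivot_of_row  # row i dies at column pivot_of_row[i]
    for i, s in enumerate(simplices):
        if cols[i].any():
            continue  # negative simplex: kills a class, births nothing
        if s.dim > 1:
            continue  # dim-2 classes out of scope
        if i in paired_rows:
            death = simplices[paired_rows[i]].appearance
            if s.appearance < death:
                bars.append(Bar(s.dim, s.appearance, death))
        else:
            bars.append(Bar(s.dim, s.appearance, math.inf))
    return Barcode(subject_id=filtration.network.subject_id, bars=bars)


def _gf2_rank(mat: np.ndarray) -> int:
    """Rank over GF(2) by plain Gaussian elimination."""
    a = (mat.astype(np.uint8) & 1).copy()
    rank = 0
    rows, colsn = a.shape
    for c in range(colsn):
        piv = None
        for r in range(rank, rows):
            if a[r, c]:
                piv = r
                break
        if piv is None:
            continue
        a[[rank, piv]] = a[[piv, rank]]
        for r in range(rows):
            if r != rank and a[r, c]:
                a[r] ^= a[rank]
        rank += 1
    return rank


def clique_complex_at(
    filtration: DensityFiltration, level: float
) -> tuple[list, list, list]:
    """Vertices, edges and triangles of the clique complex of the subgraph
    containing the edges with appearance density <= level (exhaustive)."""
    n = filtration.n_vertices
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for (i, j), rho in zip(filtration.edges, filtration.edge_appearance):
        if rho <= level:
            g.add_edge(int(i), int(j))
    edges = sorted(tuple(sorted(e)) for e in g.edges)
    triangles = sorted(
        tuple(sorted(c))
        for c in itertools.combinations(range(n), 3)
        if all(g.has_edge(a, b) for a, b in itertools.combinations(c, 2))
    )
    return list(range(n)), edges, triangles


def betti_numbers_at(
    vertices: list, edges: list, triangles: list
) -> tuple[int, int]:
    """(beta0, beta1) of a 2-dimensional simplicial complex via GF(2) ranks."""
    nv, ne, nt = len(vertices), len(edges), len(triangles)
    eindex = {e: i for i, e in enumerate(edges)}
    d1 = np.zeros((nv, ne), dtype=np.uint8)
    for j, (u, v) in enumerate(edges):
        d1[u, j] = d1[v, j] = 1
    d2 = np.zeros((ne, nt), dtype=np.uint8)
    for j, (a, b, c) in enumerate(triangles):
        for face in ((a, b), (a, c), (b, c)):
            d2[eindex[face], j] = 1
    r1 = _gf2_rank(d1) if ne else 0
    r2 = _gf2_rank(d2) if nt else 0
    beta0 = nv - r1
    beta1 = ne - r1 - r2
    return beta0, beta1


def barcode_betti_at(barcode: Barcode, dim: int, level: float) -> int:
    """Number of bars of `dim` alive at filtration value `level`."""
    return sum(
        1 for b in barcode.in_dim(dim) if b.birth <= level < b.death
    )


def random_network(rng: np.random.Generator, n: int, tie_prob: float = 0.3,
                   complete: bool = True):
    """Random weighted network, optionally sparse, with deliberate ties."""
    from cliquebars.network import WeightedNetwork

    # integer grid -> exactly representable values, so ties are bit-identical
    levels = 10 if rng.random() < tie_prob else 100  # coarse grid: more ties
    w = rng.integers(-levels, levels + 1, size=(n, n)) / levels
    w = np.triu(w, 1)
    w = w + w.T
    np.fill_diagonal(w, 0.0)
    mask = None
    if not complete:
        keep = rng.random((n, n)) < 0.7
        keep = np.triu(keep, 1)
        keep = keep | keep.T
        # keep at least one edge
        if not keep.any():
            keep[0, 1] = keep[1, 0] = True
        mask = keep
    return WeightedNetwork(w, subject_id=f"rand{n}", mask=mask)
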