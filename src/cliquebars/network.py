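"""Core domain containers: weighted networks and cohort manifests.

A subject's functional-connectivity network is a symmetric weighted graph on
the regions of interest (ROIs); the weight of an edge is the correlation
between the two regions' BOLD time series.  The diagonal (self-correlation)
is never part of the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["WeightedNetwork", "CohortManifest", "GROUP_ALIASES"]

#: Accepted spellings for the two group labels (lower-cased before lookup).
GROUP_ALIASES = {
    "control": "control",
    "ctrl": "control",
    "con": "control",
    "hc": "control",
    "healthy": "control",
    "0": "control",
    "case": "case",
    "isad": "case",
    "patient": "case",
    "1": "case",
}


@dataclass
class WeightedNetwork:
    """A symmetric weighted graph with an ignored diagonal.

    Parameters
    ----------
    weights
        Symmetric ``(N, N)`` float array.  The diagonal is ignored.
    subject_id
        Identifier carried through to barcodes and result tables.
    node_labels
        Optional ROI names, length ``N``.
    mask
        Optional boolean ``(N, N)`` adjacency; ``True`` where an edge exists.
        ``None`` means the graph is complete (every off-diagonal pair is an
        edge), which is the case for correlation matrices.
    """

    weights: np.ndarray
    subject_id: str = ""
    node_labels: list[str] | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        n = w.shape[0]
        if n < 2:
            raise ValueError(f"network needs at least 2 nodes, got {n}")
        off = ~np.eye(n, dtype=bool)
        if not np.all(np.isfinite(w[off])):
            raise ValueError("non-finite off-diagonal weight")
        asym = np.abs(w - w.T).max()
        if asym > 1e-12:
            raise ValueError(
                f"weight matrix asymmetric by {asym:.3g} (> 1e-12); "
                "pass symmetrize=True to the loader if this is rounding noise"
            )
        w = (w + w.T) / 2.0  # kill sub-tolerance asymmetry exactly
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.node_labels is not None and len(self.node_labels) != n:
            raise ValueError("node_labels length does not match matrix size")
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != (n, n):
                raise ValueError("mask shape does not match weights")
            if not np.array_equal(m, m.T):
                raise ValueError("mask must be symmetric")
            self.mask = m & off

    # -- basic graph views -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the edges (upper triangle, i < j)."""
        n = self.n_nodes
        iu, ju = np.triu_indices(n, k=1)
        if self.mask is not None:
            keep = self.mask[iu, ju]
            iu, ju = iu[keep], ju[keep]
        return iu, ju

    def edge_weights(self) -> np.ndarray:
        iu, ju = self.edge_index()
        return self.weights[iu, ju]

    @property
    def n_edges(self) -> int:
        return len(self.edge_weights())

    @property
    def delta_max(self) -> float:
        """Largest off-diagonal weight."""
        w = self.edge_weights()
        if w.size == 0:
            raise ValueError("edgeless network has no weights")
        return float(w.max())

    @property
    def delta_min(self) -> float:
        """Smallest off-diagonal weight."""
        w = self.edge_weights()
        if w.size == 0:
            raise ValueError("edgeless network has no weights")
        return float(w.min())

    @classmethod
    def from_edges(
        cls, n: int, edges: dict[tuple[int, int], float], subject_id: str = ""
    ) -> "WeightedNetwork":
        """Build a (possibly non-complete) network from an edge dict."""
        w = np.zeros((n, n))
        m = np.zeros((n, n), dtype=bool)
        for (i, j), v in edges.items():
            w[i, j] = w[j, i] = v
            m[i, j] = m[j, i] = True
        return cls(w, subject_id=subject_id, mask=m)


@dataclass
class CohortManifest:
    """Validated cohort table: subject_id, group, sex, age, matrix_path.

    Group labels are normalised to ``{"control", "case"}``; sex is coded
    0 = male, 1 = female; age is in years.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject_id", "group", "sex", "age", "matrix_path")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        ids = df["subject_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate subject_id: {dupes}")
        groups = []
        for sid, g in zip(ids, df["group"]):
            key = str(g).strip().lower()
            if key not in GROUP_ALIASES:
                raise ValueError(f"unknown group label {g!r} for subject {sid}")
            groups.append(GROUP_ALIASES[key])
        sexes = []
        for sid, s in zip(ids, df["sex"]):
            key = str(s).strip().lower()
            if key in ("0", "m", "male"):
                sexes.append(0)
            elif key in ("1", "f", "female"):
                sexes.append(1)
            else:
                raise ValueError(f"unparseable sex {s!r} for subject {sid}")
        try:
            ages = pd.to_numeric(df["age"], errors="raise").astype(float)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unparseable age in manifest: {exc}") from exc
        out = pd.DataFrame(
            {
                "subject_id": ids.to_numpy(),
                "group": groups,
                "sex": sexes,
                "age": ages.to_numpy(),
                "matrix_path": df["matrix_path"].astype(str).to_numpy(),
            }
        )
        self.table = out.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_control(self) -> int:
        return int((self.table["group"] == "control").sum())

    @property
    def n_case(self) -> int:
        return int((self.table["group"] == "case").sum())

    def check_group_sizes(self, minimum: int = 2) -> None:
        """Group-level statistics need at least `minimum` subjects per group."""
        if self.n_control < minimum or self.n_case < minimum:
            raise ValueError(
                f"need at least {minimum} subjects per group, have "
                f"{self.n_control} control / {self.n_case} case"
            )
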