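"""Readers and writers for the pipeline's text formats.

All formats are plain delimited text so that results stay diff-able and
portable: correlation matrices (square numeric, optional label header),
cohort manifests (subject_id,group,sex,age,matrix_path), barcodes
(dim,birth,death with ``inf`` for essential classes) and entropy tables.
Delimiters are auto-detected among comma/tab/whitespace on read; output is
always comma-separated.
"""

from __future__ import annotations

import csv
import io as _io
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .network import CohortManifest, WeightedNetwork
from .persistence import Bar, Barcode

__all__ = [
    "load_correlation_matrix",
    "write_correlation_matrix",
    "load_manifest",
    "write_manifest",
    "write_barcode",
    "read_barcode",
    "write_entropy_table",
]


def _sniff_delimiter(sample: str) -> str | None:
    """Return ',', '\\t' or None (meaning: any whitespace)."""
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t ").delimiter
    except csv.Error:
        return None


def _tokenize(line: str, delim: str | None) -> list[str]:
    if delim is None or delim == " ":
        return line.split()
    return [t.strip() for t in line.split(delim)]


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def load_correlation_matrix(
    path: str | Path,
    symmetrize: bool = False,
    subject_id: str | None = None,
    check_range: bool = True,
) -> WeightedNetwork:
    """Read a square correlation matrix from delimited text.

    Parameters
    ----------
    path
        Delimited numeric text, N rows by N columns; an optional single
        header row supplies node labels.
    symmetrize
        If True, the matrix is averaged with its transpose.  If False,
        asymmetry beyond 1e-12 is an error.
    check_range
        Require off-diagonal entries in [-1, 1] (correlation input).

    Returns
    -------
    WeightedNetwork
        The diagonal is discarded.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    delim = _sniff_delimiter(lines[0])
    first = _tokenize(lines[0], delim)
    labels: list[str] | None = None
    if not all(_is_number(t) for t in first):
        labels = first
        lines = lines[1:]
    rows = []
    for ln in lines:
        toks = _tokenize(ln, delim)
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric entry ({exc})") from exc
    ncols = {len(r) for r in rows}
    if len(ncols) != 1 or len(rows) != ncols.pop():
        raise ValueError(
            f"{path}: not a square matrix ({len(rows)} rows, "
            f"widths {sorted({len(r) for r in rows})})"
        )
    w = np.array(rows, dtype=float)
    n = w.shape[0]
    if n < 2:
        raise ValueError(f"{path}: matrix must be at least 2x2")
    off = ~np.eye(n, dtype=bool)
    if not np.all(np.isfinite(w[off])):
        raise ValueError(f"{path}: NaN or Inf off-diagonal entry")
    if symmetrize:
        w = (w + w.T) / 2.0
    if check_range:
        lo, hi = w[off].min(), w[off].max()
        if lo < -1.0 - 1e-12 or hi > 1.0 + 1e-12:
            raise ValueError(
                f"{path}: off-diagonal entries outside [-1, 1] "
                f"(min {lo:.4g}, max {hi:.4g}); not a correlation matrix"
            )
    sid = subject_id if subject_id is not None else path.stem
    return WeightedNetwork(w, subject_id=sid, node_labels=labels)


def write_correlation_matrix(network: WeightedNetwork, path: str | Path) -> None:
    """Write the weight matrix (unit diagonal restored) as CSV."""
    w = network.weights.copy()
    np.fill_diagonal(w, 1.0)
    buf = _io.StringIO()
    if network.node_labels is not None:
        buf.write(",".join(network.node_labels) + "\n")
    for row in w:
        buf.write(",".join(f"{v:.17g}" for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


def load_manifest(path: str | Path, resolve_paths: bool = True) -> CohortManifest:
    """Read and validate a cohort manifest.

    Columns: subject_id, group, sex, age, matrix_path.  Group labels are
    normalised (e.g. "ISAD" -> "case"); relative matrix paths are resolved
    against the manifest's own directory and must exist.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    manifest = CohortManifest(df)
    if resolve_paths:
        base = path.parent
        resolved = []
        for sid, mp in zip(manifest.table["subject_id"], manifest.table["matrix_path"]):
            p = Path(mp)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(
                    f"matrix file for subject {sid!r} not found: {p}"
                )
            resolved.append(str(p))
        manifest.table["matrix_path"] = resolved
    return manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, index=False)


def write_barcode(barcode: Barcode, path: str | Path) -> None:
    """Write a barcode as ``dim,birth,death`` rows, sorted; inf death -> "inf".

    The written file round-trips through :func:`read_barcode` exactly.
    """
    rows = sorted(
        (b.dim, b.birth, b.death if math.isfinite(b.death) else math.inf)
        for b in barcode.bars
    )
    with open(path, "w") as fh:
        fh.write("dim,birth,death\n")
        for dim, birth, death in rows:
            dtxt = "inf" if math.isinf(death) else f"{death:.17g}"
            fh.write(f"{dim},{birth:.17g},{dtxt}\n")


def read_barcode(path: str | Path, subject_id: str | None = None) -> Barcode:
    path = Path(path)
    bars = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip().lower().replace(" ", "") != "dim,birth,death":
            raise ValueError(f"{path}: unexpected barcode header {header!r}")
        for ln in fh:
            if not ln.strip():
                continue
            dim_s, birth_s, death_s = ln.strip().split(",")
            death = math.inf if death_s.strip().lower() == "inf" else float(death_s)
            bars.append(Bar(int(dim_s), float(birth_s), death))
    sid = subject_id if subject_id is not None else path.stem
    return Barcode(subject_id=sid, bars=bars)


def write_entropy_table(table: pd.DataFrame, path: str | Path) -> None:
    """Per-subject entropy table: subject_id,group,sex,age,e0,e1."""
    cols = ["subject_id", "group", "sex", "age", "e0", "e1"]
    table[cols].to_csv(path, index=False, float_format="%.12g")
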