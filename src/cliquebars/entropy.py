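"""Persistent entropy: Shannon entropy of the bar-length distribution.

Each bar [x_i, y_i) contributes a length l_i = y_i - x_i; an essential bar
(infinite death) contributes l_i = m + 1 - x_i where m is the largest
finite death in the barcode.  With p_i = l_i / L (L the total length), the
persistent entropy is e_p = -sum p_i ln p_i, in nats.  It is maximal,
ln(r), exactly when all r bars have equal length, so higher entropy means a
more uniform bar-length distribution; it is invariant under rescaling all
lengths by a common factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .persistence import Barcode

__all__ = [
    "BarLengthSet",
    "EntropyValue",
    "bar_lengths",
    "persistent_entropy",
    "barcode_entropy",
]


@dataclass
class BarLengthSet:
    """Finite bar lengths and their normalised distribution for one dim."""

    dim: int
    lengths: np.ndarray  # l_i > 0
    m: float  # largest finite death (or the fallback, see bar_lengths)
    subject_id: str = ""

    def __post_init__(self) -> None:
        l = np.asarray(self.lengths, dtype=float)
        if l.size == 0:
            raise ValueError("empty bar-length set")
        if np.any(l <= 0):
            raise ValueError("bar lengths must be positive")
        self.lengths = l

    @property
    def total(self) -> float:
        """L, the sum of all lengths."""
        return float(self.lengths.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.lengths / self.total

    @property
    def n_bars(self) -> int:
        return len(self.lengths)


@dataclass(frozen=True)
class EntropyValue:
    subject_id: str
    dim: int
    value: float  # nats, in [0, ln r]
    n_bars: int


def bar_lengths(barcode: Barcode, dim: int) -> BarLengthSet:
    """Bar lengths of `barcode` in dimension `dim`.

    Finite bars contribute y_i - x_i.  Essential bars contribute
    m + 1 - x_i with m the largest finite death; if the barcode has no
    finite death at all (edgeless or single-threshold degenerate inputs),
    m falls back to the largest birth, which keeps every length positive.

    Raises
    ------
    ValueError
        If the barcode has no bars in the requested dimension.
    """
    bars = barcode.in_dim(dim)
    if not bars:
        raise ValueError(
            f"barcode of {barcode.subject_id!r} has no bars in dim {dim}"
        )
    finite_deaths = [b.death for b in bars if b.is_finite]
    if finite_deaths:
        m = max(finite_deaths)
    else:
        m = max(b.birth for b in bars)
    lengths = np.array(
        [b.death - b.birth if b.is_finite else m + 1.0 - b.birth for b in bars]
    )
    return BarLengthSet(dim=dim, lengths=lengths, m=float(m),
                        subject_id=barcode.subject_id)


def persistent_entropy(lengths: BarLengthSet) -> EntropyValue:
    """e_p = -sum p_i ln p_i over the normalised bar-length distribution."""
    p = lengths.probabilities
    value = float(-(p * np.log(p)).sum())
    # guard against -0.0 and tiny negative rounding for degenerate p
    value = max(value, 0.0)
    return EntropyValue(
        subject_id=lengths.subject_id,
        dim=lengths.dim,
        value=value,
        n_bars=lengths.n_bars,
    )


def barcode_entropy(barcode: Barcode, dim: int) -> float:
    """Convenience: persistent entropy of `barcode` in `dim`, in nats."""
    return persistent_entropy(bar_lengths(barcode, dim)).value
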