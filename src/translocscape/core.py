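"""Core binned-matrix and segment-map containers shared by all analysis stages.

A :class:`BinnedMatrix` holds a symmetric, fixed-resolution contact matrix
together with its genome bin table and a per-bin mask.  Masked bins behave as
NA in every downstream computation but the underlying counts are retained so
that masking is idempotent and reversible.

Coordinates are 0-based, half-open (BED convention) throughout the in-memory
model; VCF-style 1-based positions appear only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_COLUMNS = ("chrom", "start", "end")


def make_bins(chrom_lengths: dict[str, int], bin_size: int) -> pd.DataFrame:
    """Build a genome-ordered bin table from chromosome lengths in bp."""
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, int(length), bin_size):
            rows.append((chrom, start, min(start + bin_size, int(length))))
    return pd.DataFrame(rows, columns=list(BIN_COLUMNS))


@dataclass
class BinnedMatrix:
    """Symmetric binned contact matrix with per-bin mask.

    Parameters
    ----------
    bins:
        Bin table with columns ``chrom``, ``start``, ``end`` in genome order.
    counts:
        ``(n, n)`` float array; NaN entries are allowed (e.g. after merging
        masked matrices).
    bin_size:
        Nominal bin width in bp (last bin of a chromosome may be shorter).
    mask:
        Boolean array, ``True`` for bins excluded from analysis.
    """

    bins: pd.DataFrame
    counts: np.ndarray
    bin_size: int
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.bins)
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {n} bins"
            )
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.counts) < 0:
                raise ValueError("contact counts must be non-negative")
        if not _symmetric(self.counts):
            raise ValueError("counts matrix must be symmetric")

    # -- accessors -----------------------------------------------------------

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        """Index range of a chromosome's bins (bins are genome-ordered)."""
        idx = np.flatnonzero(self.bins["chrom"].to_numpy() == chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in bin table")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def effective(self) -> np.ndarray:
        """Counts with masked rows/columns materialised as NaN."""
        out = self.counts.copy()
        out[self.mask, :] = np.nan
        out[:, self.mask] = np.nan
        return out

    def copy(self) -> "BinnedMatrix":
        return BinnedMatrix(
            self.bins.copy(), self.counts.copy(), self.bin_size, self.mask.copy()
        )

    def same_bins(self, other: "BinnedMatrix") -> bool:
        return self.bins.reset_index(drop=True).equals(
            other.bins.reset_index(drop=True)
        )


def _symmetric(a: np.ndarray, tol: float = 1e-8) -> bool:
    diff = a - a.T
    return bool(np.all(np.isnan(diff) | (np.abs(diff) <= tol)))


@dataclass(frozen=True)
class SegmentMap:
    """Per-chromosome breakpoint bounds defining 'up'/'down' segments.

    ``breakpoints[chrom] = (breakpoint_low, breakpoint_high)``; coordinates
    strictly below ``breakpoint_low`` are the "up" segment, strictly above
    ``breakpoint_high`` the "down" segment.  A small gap between the two
    bounds leaves breakpoint-spanning intervals unassigned.
    """

    breakpoints: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for chrom, (low, high) in self.breakpoints.items():
            if low > high:
                raise ValueError(f"{chrom}: breakpoint_low > breakpoint_high")

    def segment_of(self, chrom: str, start: int, end: int) -> str:
        """Segment label of the half-open interval [start, end).

        Returns ``"up"``, ``"down"``, ``"excluded"`` (interval spans the
        breakpoint gap), or ``"whole"`` for chromosomes without a breakpoint.
        """
        if chrom not in self.breakpoints:
            return "whole"
        low, high = self.breakpoints[chrom]
        if end <= low:
            return "up"
        if start > high:
            return "down"
        return "excluded"

    @property
    def chromosomes(self) -> list[str]:
        return list(self.breakpoints)
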