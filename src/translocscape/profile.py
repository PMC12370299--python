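"""Viewpoint profiling: 4C binning, arm profiles, insulation, breakpoints.

4C fragment counts are filtered around the viewpoint and binned over a
target region; Tiled-C-style matrices over captured regions support
arm-wide interaction profiles (normalised to 100%), diamond insulation
scores and their differences, re-scaling to a common sequencing depth, and
breakpoint calling from the drop in cross-partner contact frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_EXCLUSION_BP = 10_000
DEFAULT_4C_BIN = 250_000
DEFAULT_INSULATION_WINDOW = 5


@dataclass
class ViewpointProfile:
    """Binned interaction counts of one viewpoint over a target region."""

    viewpoint: tuple[str, int]
    region_chrom: str
    region_start: int
    bin_size: int
    counts: np.ndarray
    normalized: bool = False

    def bin_starts(self) -> np.ndarray:
        return self.region_start + np.arange(len(self.counts)) * self.bin_size


@dataclass
class Region:
    chrom: str
    start: int
    n_bins: int


@dataclass
class TiledMatrix:
    """Symmetric binned matrix over one or two captured regions.

    With two regions the matrix is a concatenation (region 0 bins first);
    the junction between them is the putative translocation breakpoint.
    """

    counts: np.ndarray
    bin_size: int
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.counts.shape[0]
        if self.counts.shape != (n, n):
            raise ValueError("matrix must be square")
        if not np.allclose(self.counts, self.counts.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if np.nanmin(self.counts) < 0:
            raise ValueError("counts must be non-negative")
        if not self.regions:
            self.regions = [Region("region0", 0, n)]
        if sum(r.n_bins for r in self.regions) != n:
            raise ValueError("region bins do not sum to matrix size")

    def region_slice(self, index: int) -> slice:
        off = sum(r.n_bins for r in self.regions[:index])
        return slice(off, off + self.regions[index].n_bins)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass
class InsulationTrack:
    """Per-bin insulation values; NaN where the diamond does not fit."""

    values: np.ndarray
    window_bins: int
    bin_size: int = 0


# ---------------------------------------------------------------------------
# 4C
# ---------------------------------------------------------------------------


def filter_and_bin_4c(
    fragments: pd.DataFrame,
    viewpoint: tuple[str, int],
    exclusion_bp: int = DEFAULT_EXCLUSION_BP,
    bin_size: int = DEFAULT_4C_BIN,
    region_chrom: str | None = None,
    region_start: int = 0,
    region_end: int | None = None,
) -> ViewpointProfile:
    """Remove near-viewpoint fragments and sum the rest into fixed bins.

    ``fragments`` has columns ``chrom``, ``pos``, ``count``.  Fragments on
    the viewpoint chromosome strictly closer than ``exclusion_bp`` to the
    viewpoint are discarded; remaining fragments on ``region_chrom``
    (default: viewpoint chromosome) from ``region_start`` onward are summed
    per ``bin_size`` window.
    """
    if exclusion_bp < 0:
        raise ValueError("exclusion_bp must be >= 0")
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    vp_chrom, vp_pos = viewpoint
    region_chrom = region_chrom or vp_chrom
    frags = fragments.copy()
    near = (frags["chrom"] == vp_chrom) & (
        (frags["pos"] - vp_pos).abs() < exclusion_bp
    )
    frags = frags[~near]
    frags = frags[
        (frags["chrom"] == region_chrom) & (frags["pos"] >= region_start)
    ]
    if region_end is not None:
        frags = frags[frags["pos"] < region_end]
    if frags.empty:
        counts = np.zeros(0 if region_end is None else
                          int(np.ceil((region_end - region_start) / bin_size)))
    else:
        idx = ((frags["pos"] - region_start) // bin_size).astype(int)
        n_bins = (
            int(np.ceil((region_end - region_start) / bin_size))
            if region_end is not None
            else int(idx.max()) + 1
        )
        counts = np.bincount(idx, weights=frags["count"], minlength=n_bins).astype(
            float
        )
    return ViewpointProfile(
        viewpoint=viewpoint,
        region_chrom=region_chrom,
        region_start=region_start,
        bin_size=bin_size,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# arm profiles and ratios
# ---------------------------------------------------------------------------


def _profile_counts(
    obj: ViewpointProfile | TiledMatrix,
    source_region: tuple[int, int] | None,
) -> tuple[np.ndarray, int, int]:
    """Per-bin counts toward the target axis, plus (bin_size, axis_start)."""
    if isinstance(obj, ViewpointProfile):
        return obj.counts.astype(float), obj.bin_size, obj.region_start
    if source_region is None:
        raise ValueError("source_region is required for a TiledMatrix")
    region = obj.regions[0]
    lo = max((source_region[0] - region.start) // obj.bin_size, 0)
    hi = min(
        int(np.ceil((source_region[1] - region.start) / obj.bin_size)),
        region.n_bins,
    )
    if hi <= lo:
        raise ValueError("source_region does not overlap the matrix")
    counts = np.nansum(obj.counts[lo:hi, :], axis=0)
    return counts, obj.bin_size, region.start


def arm_interaction_profile(
    obj: ViewpointProfile | TiledMatrix,
    target_start: int,
    window_bp: int = DEFAULT_4C_BIN,
    source_region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Percentage of interactions per window along the target arm.

    Interactions from ``source_region`` (required for matrices; implicit
    for a viewpoint profile) toward positions >= ``target_start`` are
    re-binned into ``window_bp`` windows and scaled so the target-arm
    total is 100%.
    """
    counts, bin_size, axis_start = _profile_counts(obj, source_region)
    if window_bp % bin_size:
        raise ValueError("window_bp must be a multiple of the bin size")
    starts = axis_start + np.arange(len(counts)) * bin_size
    keep = starts >= target_start
    counts, starts = counts[keep], starts[keep]
    total = counts.sum()
    if total <= 0:
        raise ValueError("no interactions toward the target arm")
    win_idx = (starts - target_start) // window_bp
    sums = np.bincount(win_idx, weights=counts)
    out = pd.DataFrame(
        {
            "window_start": target_start + np.arange(len(sums)) * window_bp,
            "percent": 100.0 * sums / total,
        }
    )
    return out


def region_ratio(
    profile: ViewpointProfile,
    region_a: tuple[int, int],
    region_b: tuple[int, int],
) -> float:
    """Ratio of summed interactions in region A over region B.

    Bins are attributed to a region when their start lies in the half-open
    region interval.
    """
    starts = profile.bin_starts()

    def region_sum(region: tuple[int, int]) -> float:
        sel = (starts >= region[0]) & (starts < region[1])
        return float(profile.counts[sel].sum())

    b = region_sum(region_b)
    if b <= 0:
        raise ValueError("region_b has no interactions")
    return region_sum(region_a) / b


# ---------------------------------------------------------------------------
# insulation
# ---------------------------------------------------------------------------


def insulation_score(
    m: TiledMatrix | np.ndarray,
    window_bins: int = DEFAULT_INSULATION_WINDOW,
) -> InsulationTrack:
    """Diamond insulation score per bin boundary.

    For each bin ``b`` with a full window on both sides, the mean count in
    the diamond ``[b-w, b) x [b, b+w)`` is computed and reported as
    log2(diamond mean / mean of all diamond means); a uniform matrix thus
    scores exactly zero everywhere, and contact depletion across a
    boundary yields negative values.
    """
    counts = m.counts if isinstance(m, TiledMatrix) else np.asarray(m, float)
    n = counts.shape[0]
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    if n <= 2 * window_bins:
        raise ValueError("window exceeds matrix size")
    diamonds = np.full(n, np.nan)
    for b in range(window_bins, n - window_bins + 1):
        block = counts[b - window_bins : b, b : b + window_bins]
        diamonds[b] = np.nanmean(block)
    valid = np.isfinite(diamonds)
    norm = np.nanmean(diamonds[valid])
    values = np.full(n, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[valid] = np.log2(diamonds[valid] / norm)
    return InsulationTrack(
        values=values,
        window_bins=window_bins,
        bin_size=m.bin_size if isinstance(m, TiledMatrix) else 0,
    )


def insulation_difference(
    t: InsulationTrack,
    control: InsulationTrack,
    sign: str = "sample_minus_control",
) -> np.ndarray:
    """Per-bin insulation difference; NA where either track is undefined.

    The default sign convention reports sample - control, so negative
    values indicate stronger insulation (lower score) in the sample; pass
    ``sign="control_minus_sample"`` for the opposite convention.
    """
    if len(t.values) != len(control.values) or t.window_bins != control.window_bins:
        raise ValueError("tracks must share bins and window size")
    diff = t.values - control.values
    if sign == "control_minus_sample":
        diff = -diff
    elif sign != "sample_minus_control":
        raise ValueError(f"unknown sign convention {sign!r}")
    return diff


def scale_to_common_depth(
    ms: list[TiledMatrix],
    shared_region: tuple[int, int] | None = None,
) -> list[TiledMatrix]:
    """Scale matrices so their shared-region totals match the minimum.

    ``shared_region`` is a bin-index interval applied to every matrix
    (whole matrix when omitted).
    """
    totals = []
    for m in ms:
        sel = slice(*shared_region) if shared_region else slice(None)
        total = np.nansum(m.counts[sel, sel])
        if total <= 0:
            raise ValueError("matrix with zero total in shared region")
        totals.append(total)
    target = min(totals)
    return [
        TiledMatrix(m.counts * (target / t), m.bin_size, list(m.regions))
        for m, t in zip(ms, totals)
    ]


# ---------------------------------------------------------------------------
# breakpoint detection
# ---------------------------------------------------------------------------


@dataclass
class BreakpointCall:
    detected: bool
    boundary: int | None  # index of the first downstream bin
    ratio: float


def detect_breakpoint(
    m: TiledMatrix | np.ndarray,
    min_ratio: float = 2.0,
    epsilon: float = 1.0,
) -> BreakpointCall:
    """Locate the contact drop-off along the cross-partner axis.

    For a two-region matrix, each bin of region 0 is summarised by its
    total contact count to region 1; a plain array is taken as that
    per-bin cross-count vector directly.  Every boundary ``k`` (1..n-1)
    is scored as mean(counts[:k]) / (mean(counts[k:]) + epsilon) and the
    maximising boundary returned; when no boundary reaches ``min_ratio``
    the drop is flagged as undetected.
    """
    if isinstance(m, TiledMatrix):
        if len(m.regions) < 2:
            raise ValueError("matrix must span two regions")
        a, b = m.region_slice(0), m.region_slice(1)
        cross = np.nansum(m.counts[a, b], axis=1)
    else:
        cross = np.asarray(m, dtype=float)
    n = len(cross)
    if n < 2:
        raise ValueError("need at least two bins")
    best_k, best_ratio = None, -np.inf
    for k in range(1, n):
        ratio = cross[:k].mean() / (cross[k:].mean() + epsilon)
        if ratio > best_ratio:
            best_k, best_ratio = k, float(ratio)
    detected = best_ratio >= min_ratio
    return BreakpointCall(
        detected=detected, boundary=best_k if detected else None, ratio=best_ratio
    )
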