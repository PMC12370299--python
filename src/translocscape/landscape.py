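"""Interchromosomal interaction-frequency landscape.

Implements the bulk Hi-C comparison between a translocated tumor entity and
two reference groups: masking of low-coverage 1 Mb bins, per-sample depth
normalization, median merging across samples, per-square-Mb chromosome-pair
interaction frequencies, log2 fold changes between entities, selection of
commonly extreme pairs, a chi-square enrichment test for the translocation
partners, and assignment of bins to breakpoint-defined segments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .core import BinnedMatrix, SegmentMap

DEFAULT_MIN_TOTAL = 60_000
DEFAULT_TARGET = 150_000_000
DEFAULT_TOP_FRACTION = 0.10


def mask_low_coverage_bins(
    m: BinnedMatrix, min_total: float = DEFAULT_MIN_TOTAL
) -> BinnedMatrix:
    """Mask bins whose genome-wide row total falls below ``min_total``.

    The row total includes cis contacts, so telomeric/centromeric-like bins
    with globally poor coverage are flagged.  Totals are computed on the
    stored counts (NaN-safe), which makes the operation idempotent.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    out = m.copy()
    totals = np.nansum(out.counts, axis=1)
    out.mask = out.mask | (totals < min_total)
    return out


def normalize_total(
    m: BinnedMatrix, target: float = DEFAULT_TARGET
) -> BinnedMatrix:
    """Scale the matrix so the unmasked total interaction count is ``target``.

    The total counts each unordered bin pair once (upper triangle including
    the diagonal) over unmasked bins.
    """
    eff = m.effective()
    iu = np.triu_indices(m.n_bins)
    total = np.nansum(eff[iu])
    if total <= 0:
        raise ValueError("total unmasked count must be > 0")
    out = m.copy()
    out.counts = out.counts * (target / total)
    return out


def merge_samples(ms: list[BinnedMatrix]) -> BinnedMatrix:
    """Element-wise median across samples; NA wherever any input is NA."""
    if not ms:
        raise ValueError("need at least one matrix")
    first = ms[0]
    for other in ms[1:]:
        if not first.same_bins(other):
            raise ValueError("bin tables differ between samples")
    stack = np.stack([m.effective() for m in ms])
    merged = np.median(stack, axis=0)  # NaN propagates (conservative policy)
    mask = np.zeros(first.n_bins, dtype=bool)
    for m in ms:
        mask |= m.mask
    out = first.copy()
    out.counts = merged
    out.mask = mask
    return out


@dataclass
class ChromPairFreq:
    """Symmetric per-chromosome-pair interaction frequency (counts / Mb^2)."""

    table: pd.DataFrame  # square, chrom x chrom, NaN diagonal

    @property
    def chromosomes(self) -> list[str]:
        return list(self.table.index)

    def value(self, a: str, b: str) -> float:
        return float(self.table.loc[a, b])

    def pairs(self) -> list[tuple[str, str]]:
        c = self.chromosomes
        return [(a, b) for i, a in enumerate(c) for b in c[i + 1:]]


def pair_frequency(
    m: BinnedMatrix,
    exclude_pairs: set[tuple[str, str]] | None = None,
) -> ChromPairFreq:
    """Trans interaction frequency per chromosome pair, scaled per Mb^2.

    The sum of unmasked trans counts between two chromosomes is divided by
    the product of their total bin numbers.  Pairs listed in
    ``exclude_pairs`` (orderless) are set to NA.
    """
    excluded = {frozenset(p) for p in (exclude_pairs or set())}
    chroms = m.chromosomes
    eff = m.effective()
    table = pd.DataFrame(np.nan, index=chroms, columns=chroms, dtype=float)
    for a, b in itertools.combinations(chroms, 2):
        if frozenset((a, b)) in excluded:
            continue
        sa, sb = m.chrom_slice(a), m.chrom_slice(b)
        block = eff[sa, sb]
        n_a = sa.stop - sa.start
        n_b = sb.stop - sb.start
        freq = np.nansum(block) / (n_a * n_b)
        table.loc[a, b] = table.loc[b, a] = freq
    return ChromPairFreq(table)


def log2fc_pairs(a: ChromPairFreq, b: ChromPairFreq) -> pd.DataFrame:
    """log2(a / b) per chromosome pair; NA where undefined.

    Entries are NA when either frequency is NA or when either is zero (a
    zero numerator would otherwise produce an unbounded, rank-dominating
    value).
    """
    if list(a.table.index) != list(b.table.index):
        raise ValueError("chromosome sets differ")
    av, bv = a.table.to_numpy(), b.table.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(av / bv)
    fc[(bv == 0) | (av == 0)] = np.nan
    return pd.DataFrame(fc, index=a.table.index, columns=a.table.columns)


def common_extreme_pairs(
    fc1: pd.DataFrame,
    fc2: pd.DataFrame,
    q: float = DEFAULT_TOP_FRACTION,
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Pairs in the common top-q (and bottom-q) tail of both fold changes.

    Thresholds are the (1-q)/q quantiles of each table's defined pair
    values; membership uses strict inequality, so ties at the threshold are
    excluded and a constant table selects nothing.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if list(fc1.index) != list(fc2.index):
        raise ValueError("chromosome sets differ")
    chroms = list(fc1.index)
    pairs = [(a, b) for i, a in enumerate(chroms) for b in chroms[i + 1:]]

    def tail_sets(fc: pd.DataFrame):
        vals = np.array([fc.loc[a, b] for a, b in pairs], dtype=float)
        ok = np.isfinite(vals)
        if not ok.any():
            return set(), set()
        hi = np.quantile(vals[ok], 1 - q)
        lo = np.quantile(vals[ok], q)
        up = {p for p, v, o in zip(pairs, vals, ok) if o and v > hi}
        down = {p for p, v, o in zip(pairs, vals, ok) if o and v < lo}
        return up, down

    up1, down1 = tail_sets(fc1)
    up2, down2 = tail_sets(fc2)
    return up1 & up2, down1 & down2


def enrichment_test(
    selected: set[tuple[str, str]],
    universe: set[tuple[str, str]],
    focal_chroms: set[str],
    yates: bool = False,
) -> tuple[float, float]:
    """Fold enrichment of focal-chromosome pairs among selected pairs.

    ``fold`` is the fraction of selected pairs involving any focal
    chromosome divided by the same fraction in the universe; the p-value
    comes from a 2x2 chi-square (selected vs not x focal vs not), without
    continuity correction by default.
    """
    if not selected <= universe:
        raise ValueError("selected must be a subset of universe")
    if not universe:
        raise ValueError("universe is empty")

    def is_focal(pair: tuple[str, str]) -> bool:
        return bool(set(pair) & focal_chroms)

    uni_focal = sum(is_focal(p) for p in universe)
    if uni_focal == 0:
        raise ValueError("no focal pairs in universe")
    sel_focal = sum(is_focal(p) for p in selected)
    n_sel, n_uni = len(selected), len(universe)
    if n_sel == 0:
        raise ValueError("selected set is empty")
    fold = (sel_focal / n_sel) / (uni_focal / n_uni)
    rest = universe - selected
    table = np.array(
        [
            [sel_focal, n_sel - sel_focal],
            [sum(is_focal(p) for p in rest), len(rest) - sum(is_focal(p) for p in rest)],
        ]
    )
    if table.min() == 0 and (table.sum(axis=0) == 0).any():
        return fold, float("nan")
    _, p, _, _ = chi2_contingency(table, correction=yates)
    return fold, float(p)


def segment_of(chrom: str, start: int, end: int, sm: SegmentMap) -> str:
    """Segment label of a bin relative to the breakpoint map."""
    return sm.segment_of(chrom, start, end)


def top_partner_pair(fc: pd.DataFrame) -> tuple[str, str]:
    """Chromosome pair with the maximum log2 fold change (NA ignored)."""
    chroms = list(fc.index)
    best, best_val = None, -np.inf
    for i, a in enumerate(chroms):
        for b in chroms[i + 1:]:
            v = fc.loc[a, b]
            if np.isfinite(v) and v > best_val:
                best, best_val = (a, b), float(v)
    if best is None:
        raise ValueError("all fold changes undefined")
    return best
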