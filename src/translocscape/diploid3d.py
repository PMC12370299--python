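"""Diploid matrix deconvolution and bead-model geometry.

Bulk Hi-C matrices average the two homologues of every chromosome.  For
3D modeling the matrices are split into allele-level matrices: in a normal
genome, cis contacts are halved between alleles ``a``/``b`` and trans
contacts quartered over the four allele combinations.  In a translocated
tumor, the single remaining wild-type homologue of each partner chromosome
is assigned the contact counts observed in the normal reference, the
derivative allele receives the remainder (clamped at zero), and trans
contacts among the partner chromosomes and their derivatives are set NA.

Geometry utilities compute center-of-mass radial positions, pairwise bin
distances and bin-to-breakpoint distance profiles on bead models, and
compartment-score aggregation / eigenvector selection support the A/B
annotation of the models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .core import BinnedMatrix, SegmentMap
from .synthgen import BeadModel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# deconvolution
# ---------------------------------------------------------------------------


def _allele_bins(bins: pd.DataFrame, labels: dict[str, tuple[str, str]]) -> pd.DataFrame:
    rows = []
    for chrom, grp in bins.groupby("chrom", sort=False):
        for suffix in labels[chrom]:
            for _, r in grp.iterrows():
                rows.append((f"{chrom}_{suffix}", r["start"], r["end"]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def deconvolute(
    m: BinnedMatrix,
    mode: str = "normal",
    normal_ref: BinnedMatrix | None = None,
    sm: SegmentMap | None = None,
) -> BinnedMatrix:
    """Split a bulk matrix into an allele-level (diploid) matrix.

    ``mode="normal"``: every chromosome becomes alleles ``_a``/``_b``; cis
    counts are divided by two per allele, trans counts by four per allele
    combination (totals are conserved exactly).

    ``mode="tumor"``: chromosomes with a breakpoint in ``sm`` become
    ``_wt``/``_der``; the wild-type allele receives the ``normal_ref``
    counts, the derivative the (clamped) sample excess, and all trans
    entries among the partner chromosomes and their derivatives are NA.
    """
    if mode not in ("normal", "tumor"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "tumor":
        if normal_ref is None or sm is None:
            raise ValueError("tumor mode requires normal_ref and sm")
        if not m.same_bins(normal_ref):
            raise ValueError("sample and normal_ref bin tables differ")
    partners = set(sm.chromosomes) if (mode == "tumor" and sm) else set()

    labels = {
        c: (("wt", "der") if c in partners else ("a", "b"))
        for c in m.chromosomes
    }
    out_bins = _allele_bins(m.bins, labels)
    n_out = len(out_bins)
    out = np.full((n_out, n_out), np.nan)

    # index ranges of each allele block in the output
    spans: dict[str, slice] = {}
    cursor = 0
    for chrom in m.chromosomes:
        n = (m.chrom_slice(chrom).stop - m.chrom_slice(chrom).start)
        for suffix in labels[chrom]:
            spans[f"{chrom}_{suffix}"] = slice(cursor, cursor + n)
            cursor += n

    eff = m.effective()
    ref_eff = normal_ref.effective() if normal_ref is not None else None
    n_clamped = 0

    for ci, chrom_i in enumerate(m.chromosomes):
        si = m.chrom_slice(chrom_i)
        # cis blocks
        cis = eff[si, si]
        if chrom_i in partners:
            assert ref_eff is not None
            ref_cis = ref_eff[si, si]
            der = cis - ref_cis
            n_clamped += int(np.nansum(der < 0))
            der = np.clip(der, 0, None)
            out[spans[f"{chrom_i}_wt"], spans[f"{chrom_i}_wt"]] = ref_cis
            out[spans[f"{chrom_i}_der"], spans[f"{chrom_i}_der"]] = der
        else:
            for suffix in labels[chrom_i]:
                out[spans[f"{chrom_i}_{suffix}"], spans[f"{chrom_i}_{suffix}"]] = cis / 2.0
        # trans blocks
        for chrom_j in m.chromosomes[ci + 1:]:
            sj = m.chrom_slice(chrom_j)
            trans = eff[si, sj]
            both_partner = chrom_i in partners and chrom_j in partners
            if both_partner:
                continue  # stays NA among partners/derivatives
            if chrom_i in partners or chrom_j in partners:
                assert ref_eff is not None
                p, o = (chrom_i, chrom_j) if chrom_i in partners else (chrom_j, chrom_i)
                ref_trans = ref_eff[si, sj]
                der = trans - ref_trans
                n_clamped += int(np.nansum(der < 0))
                der = np.clip(der, 0, None)
                for o_suffix in labels[o]:
                    for p_suffix, vals in (("wt", ref_trans), ("der", der)):
                        block = vals / 2.0
                        a = spans[f"{chrom_i}_{p_suffix if chrom_i in partners else o_suffix}"]
                        b = spans[f"{chrom_j}_{p_suffix if chrom_j in partners else o_suffix}"]
                        out[a, b] = block
                        out[np.ix_(range(b.start, b.stop), range(a.start, a.stop))] = block.T
            else:
                for suf_i in labels[chrom_i]:
                    for suf_j in labels[chrom_j]:
                        a, b = spans[f"{chrom_i}_{suf_i}"], spans[f"{chrom_j}_{suf_j}"]
                        out[a, b] = trans / 4.0
                        out[np.ix_(range(b.start, b.stop), range(a.start, a.stop))] = (trans / 4.0).T
    if n_clamped:
        logger.info("deconvolute: clamped %d negative derivative entries", n_clamped)
    return BinnedMatrix(out_bins, out, m.bin_size)


# ---------------------------------------------------------------------------
# bead-model geometry
# ---------------------------------------------------------------------------


def radial_shift_percent(shift: float, radius: float = 5.0) -> float:
    """Radial displacement as a percentage of the nuclear radius.

    E.g. an 0.86-unit inward shift in a 5-unit nucleus covers 17.2% of the
    radial distance.  Reported to one decimal.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    return round(100.0 * shift / radius, 1)


def radial_position(model: BeadModel, chrom_label: str) -> float:
    """Distance of a chromosome's center of mass from the nuclear center."""
    coords = model.coords(chrom_label)
    return float(np.linalg.norm(coords.mean(axis=0)))


def pairwise_bin_distances(
    model: BeadModel, chrom_a: str, chrom_b: str, log1p: bool = False
) -> np.ndarray:
    """Euclidean distance between every Mb-bin pair of two chromosomes."""
    d = cdist(model.coords(chrom_a), model.coords(chrom_b))
    return np.log1p(d) if log1p else d


def distance_to_breakpoint_profile(
    models: list[BeadModel],
    target_chrom: str,
    breakpoint_bin: int,
    anchor_chrom: str | None = None,
    compartments: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-bin distance distribution to the breakpoint bead across models.

    For every Mb bin of ``target_chrom``, the Euclidean distance to bead
    ``breakpoint_bin`` of ``anchor_chrom`` (default: the target chromosome
    itself) is collected across models and summarised as median and
    quartiles.  With ``compartments`` (bin -> "A"/"B") an extra column
    labels each bin.
    """
    anchor_chrom = anchor_chrom or target_chrom
    per_bin: dict[int, list[float]] = {}
    for model in models:
        target = model.coords(target_chrom)
        anchor = model.coords(anchor_chrom)
        if not 0 <= breakpoint_bin < len(anchor):
            raise IndexError("breakpoint_bin outside anchor chromosome")
        bp = anchor[breakpoint_bin]
        d = np.linalg.norm(target - bp, axis=1)
        for b, v in enumerate(d):
            per_bin.setdefault(b, []).append(float(v))
    rows = []
    for b in sorted(per_bin):
        vals = np.array(per_bin[b])
        rows.append(
            (
                b,
                float(np.median(vals)),
                float(np.quantile(vals, 0.25)),
                float(np.quantile(vals, 0.75)),
            )
        )
    out = pd.DataFrame(rows, columns=["bin", "median", "q1", "q3"])
    if compartments is not None:
        out["compartment"] = out["bin"].map(compartments)
    return out


# ---------------------------------------------------------------------------
# compartment aggregation and eigenvector selection
# ---------------------------------------------------------------------------


def _label(score: float) -> str:
    if np.isnan(score):
        return "NA"
    if score > 0:
        return "A"
    if score < 0:
        return "B"
    return "undetermined"


def aggregate_compartments(
    samples: list[pd.DataFrame],
    mb_size: int = 1_000_000,
) -> pd.DataFrame:
    """Aggregate 100-kb compartment scores to one labelled Mb-bin track.

    Each sample is a DataFrame with columns ``chrom``, ``start``, ``score``
    at 100-kb resolution.  Per sample, each Mb bin's score is the median of
    its ten 100-kb scores; the per-type score is the median across samples;
    labels are A (positive), B (negative) or "undetermined" (exactly zero).
    """
    if not samples:
        raise ValueError("need at least one sample")
    per_sample = []
    for df in samples:
        tmp = df.copy()
        tmp["mb_start"] = (tmp["start"] // mb_size) * mb_size
        med = tmp.groupby(["chrom", "mb_start"], sort=False)["score"].median()
        per_sample.append(med)
    merged = pd.concat(per_sample, axis=1)
    score = merged.median(axis=1)
    out = score.rename("score").reset_index()
    out.columns = ["chrom", "start", "score"]
    out["label"] = out["score"].map(_label)
    return out


@dataclass
class EigenSelection:
    manual: bool
    index: int | None = None
    vector: np.ndarray | None = None
    correlation: float | None = None


def select_eigenvector(
    eigs: list[tuple[np.ndarray, float]],
    gc_track: np.ndarray,
    min_corr: float = 0.6,
    similar_corr: float = 0.05,
    variance_ratio: float = 1.5,
) -> EigenSelection:
    """Pick the compartment eigenvector by GC correlation; orient positive.

    The eigenvector with the highest absolute Pearson correlation to GC
    content is selected when that correlation reaches ``min_corr`` and the
    choice is unambiguous.  When another candidate is within
    ``similar_corr`` of the best absolute correlation and the ratio of
    their explained-variance fractions is below ``variance_ratio``, the
    call is flagged for manual inspection, as is a best correlation below
    ``min_corr``.
    """
    if not eigs:
        raise ValueError("need at least one eigenvector")
    gc = np.asarray(gc_track, dtype=float)
    corrs = []
    for vec, _ in eigs:
        v = np.asarray(vec, dtype=float)
        if np.std(v) == 0 or np.std(gc) == 0:
            corrs.append(0.0)
        else:
            corrs.append(float(pearsonr(v, gc)[0]))
    abs_corrs = np.abs(corrs)
    best = int(np.argmax(abs_corrs))
    if abs_corrs[best] < min_corr:
        return EigenSelection(manual=True)
    for i, (vec, var) in enumerate(eigs):
        if i == best:
            continue
        close = abs_corrs[best] - abs_corrs[i] <= similar_corr
        vb, vi = eigs[best][1], var
        ratio = max(vb, vi) / max(min(vb, vi), 1e-12)
        if close and ratio < variance_ratio:
            return EigenSelection(manual=True)
    vec = np.asarray(eigs[best][0], dtype=float)
    if corrs[best] < 0:
        vec = -vec
    return EigenSelection(
        manual=False, index=best, vector=vec, correlation=abs(corrs[best])
    )
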