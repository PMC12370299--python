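"""Allele-specific Hi-C read classification.

Heterozygous SNPs are consolidated from three evidence sources (SNP array
replicates, pooled Hi-C genotype calls, and sorted-chromosome genotype
comparison), assigned a derivative-specific allele from sorted-derivative
genotypes, and used to classify Hi-C read pairs as wild-type or derivative.
Segment-resolved interaction counts then feed a 2x2 chi-square test for a
shift of derivative contacts toward short chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .core import SegmentMap
from .synthgen import HetSnp, ReadPair

logger = logging.getLogger(__name__)

DEFAULT_MIN_GQ = 20.0

#: genotype call records: DataFrame with columns chrom, pos, ref, alt,
#: gt ("het" | "hom_ref" | "hom_alt"), quality.
GT_COLUMNS = ("chrom", "pos", "ref", "alt", "gt", "quality")


def _key(df: pd.DataFrame) -> pd.Index:
    return pd.MultiIndex.from_frame(df[["chrom", "pos"]])


def consolidate_het_snps(
    array_calls: list[pd.DataFrame],
    hic_calls: pd.DataFrame | None,
    sort_calls: tuple[pd.DataFrame, pd.DataFrame] | None,
    min_gq: float = DEFAULT_MIN_GQ,
) -> list[HetSnp]:
    """Union of heterozygous SNPs supported by any evidence source.

    A position is retained when it is heterozygous in *both* SNP-array
    replicates, or heterozygous in the pooled Hi-C calls with quality >=
    ``min_gq``, or implied heterozygous by differing homozygous genotypes
    of the derivative and wild-type sorted-chromosome samples (each with
    quality >= ``min_gq``).  Positions with contradictory ref/alt between
    sources are dropped with a warning.
    """
    evidence: dict[tuple[str, int], dict] = {}

    def add(chrom: str, pos: int, ref: str, alt: str, source: str) -> bool:
        key = (chrom, int(pos))
        rec = evidence.get(key)
        if rec is None:
            evidence[key] = {"ref": ref, "alt": alt, "sources": {source}}
            return True
        if rec["ref"] != ref or rec["alt"] != alt:
            rec["conflict"] = True
            return False
        rec["sources"].add(source)
        return True

    if len(array_calls) >= 2:
        r1, r2 = array_calls[0], array_calls[1]
        het1 = r1[r1["gt"] == "het"]
        k2 = set(map(tuple, r2.loc[r2["gt"] == "het", ["chrom", "pos"]].to_numpy()))
        for row in het1.itertuples(index=False):
            if (row.chrom, row.pos) in k2:
                add(row.chrom, row.pos, row.ref, row.alt, "array")

    if hic_calls is not None:
        keep = hic_calls[(hic_calls["gt"] == "het") & (hic_calls["quality"] >= min_gq)]
        for row in keep.itertuples(index=False):
            add(row.chrom, row.pos, row.ref, row.alt, "hic")

    if sort_calls is not None:
        der, wt = sort_calls
        merged = der.merge(
            wt, on=["chrom", "pos"], suffixes=("_der", "_wt"), how="inner"
        )
        ok = (
            (merged["quality_der"] >= min_gq)
            & (merged["quality_wt"] >= min_gq)
            & merged["gt_der"].isin(["hom_ref", "hom_alt"])
            & merged["gt_wt"].isin(["hom_ref", "hom_alt"])
            & (merged["gt_der"] != merged["gt_wt"])
        )
        for row in merged[ok].itertuples(index=False):
            add(row.chrom, row.pos, row.ref_der, row.alt_der, "sort")

    snps = []
    for (chrom, pos), rec in sorted(evidence.items()):
        if rec.get("conflict"):
            logger.warning(
                "dropping SNP %s:%d with contradictory ref/alt between sources",
                chrom, pos,
            )
            continue
        snps.append(
            HetSnp(
                chrom=chrom,
                pos=pos,
                ref_base=rec["ref"],
                alt_base=rec["alt"],
                sources=tuple(sorted(rec["sources"])),
            )
        )
    return snps


def assign_derivative_alleles(
    snps: list[HetSnp],
    derivative_genotypes: pd.DataFrame,
    wildtype_genotypes: pd.DataFrame | None = None,
    min_gq: float = DEFAULT_MIN_GQ,
) -> list[HetSnp]:
    """Set ``derivative_allele`` from sorted-derivative genotype calls.

    A heterozygous site whose derivative genotype is homozygous forces the
    derivative allele; a missing or heterozygous derivative genotype leaves
    the SNP unassigned.  The wild-type genotypes, when given, must not
    contradict the forced assignment (contradictions leave the SNP
    unassigned with a warning).
    """
    der = derivative_genotypes.set_index(["chrom", "pos"])
    wt = (
        wildtype_genotypes.set_index(["chrom", "pos"])
        if wildtype_genotypes is not None
        else None
    )
    out = []
    for snp in snps:
        key = (snp.chrom, snp.pos)
        allele = None
        if key in der.index:
            rec = der.loc[key]
            if rec["quality"] >= min_gq and rec["gt"] in ("hom_ref", "hom_alt"):
                allele = "ref" if rec["gt"] == "hom_ref" else "alt"
        if allele is not None and wt is not None and key in wt.index:
            wrec = wt.loc[key]
            wt_allele = {"hom_ref": "ref", "hom_alt": "alt"}.get(wrec["gt"])
            if wt_allele == allele and wrec["quality"] >= min_gq:
                logger.warning(
                    "SNP %s:%d: wild-type genotype matches derivative; unassigned",
                    snp.chrom, snp.pos,
                )
                allele = None
        out.append(replace(snp, derivative_allele=allele))
    return out


def _snp_index(snps: list[HetSnp]) -> dict[tuple[str, int], HetSnp]:
    return {(s.chrom, s.pos): s for s in snps}


def classify_read(
    pair: ReadPair, snps: list[HetSnp] | dict[tuple[str, int], HetSnp]
) -> str:
    """Classify a read pair as wildtype / derivative / none / conflict.

    Each covered SNP with an assigned derivative allele casts one vote:
    a base matching the derivative allele votes "derivative", a base
    matching the other allele votes "wildtype", any other base is treated
    as no evidence.  Unanimous votes decide; disagreeing votes yield
    "conflict"; no votes yield "none".
    """
    index = snps if isinstance(snps, dict) else _snp_index(snps)
    votes = set()
    for mate in (pair.mate1, pair.mate2):
        if mate.snp_pos is None or mate.base is None:
            continue
        snp = index.get((mate.chrom, mate.snp_pos))
        if snp is None or snp.derivative_allele is None:
            continue
        if mate.base == snp.derivative_base:
            votes.add("derivative")
        elif mate.base == snp.wildtype_base:
            votes.add("wildtype")
    if not votes:
        return "none"
    if len(votes) > 1:
        return "conflict"
    return votes.pop()


@dataclass
class AlleleCounts:
    """Interaction counts keyed by (source segment, allele, target chrom)."""

    table: pd.DataFrame  # columns: segment, allele, target_chrom, count
    qc: dict[str, int]  # classification tallies (none / conflict / informative)

    def count(self, segment: str, allele: str, target: str) -> int:
        t = self.table
        sel = t[
            (t["segment"] == segment)
            & (t["allele"] == allele)
            & (t["target_chrom"] == target)
        ]
        return int(sel["count"].sum())

    def total(self) -> int:
        return int(self.table["count"].sum())


def allele_interaction_counts(
    pairs: list[ReadPair],
    snps: list[HetSnp],
    sm: SegmentMap,
    drop_partner_cis: bool = False,
) -> AlleleCounts:
    """Tally allele-resolved interactions from breakpoint segments.

    Each informative (wildtype/derivative) pair contributes one count per
    mate that falls in a mapped segment, keyed by that mate's segment
    label (e.g. ``chr11_up``), the pair's allele, and the chromosome of the
    other mate.  Pairs classified "none" or "conflict" are skipped and
    tallied in the QC summary.  With ``drop_partner_cis`` the
    translocation-based contacts between the two mapped chromosomes are
    removed.
    """
    index = _snp_index(snps)
    partner_chroms = set(sm.chromosomes)
    counts: dict[tuple[str, str, str], int] = {}
    qc = {"wildtype": 0, "derivative": 0, "none": 0, "conflict": 0}
    for pair in pairs:
        allele = classify_read(pair, index)
        qc[allele] += 1
        if allele not in ("wildtype", "derivative"):
            continue
        if drop_partner_cis and {pair.mate1.chrom, pair.mate2.chrom} <= partner_chroms:
            continue
        for mate, other in (
            (pair.mate1, pair.mate2),
            (pair.mate2, pair.mate1),
        ):
            seg = sm.segment_of(mate.chrom, mate.pos, mate.pos + 1)
            if seg in ("up", "down"):
                key = (f"{mate.chrom}_{seg}", allele, other.chrom)
                counts[key] = counts.get(key, 0) + 1
    table = pd.DataFrame(
        [(s, a, t, c) for (s, a, t), c in sorted(counts.items())],
        columns=["segment", "allele", "target_chrom", "count"],
    )
    return AlleleCounts(table=table, qc=qc)


def short_chrom_fraction_test(
    ac: AlleleCounts,
    segment: str,
    short_chroms: set[str],
) -> tuple[float, float, float]:
    """Fraction of each allele's trans contacts targeting short chromosomes.

    Returns ``(frac_wildtype, frac_derivative, chi2_p)``; the p-value is a
    2x2 chi-square (allele x short/long target) without continuity
    correction.  Contacts whose target is the segment's own chromosome are
    excluded as cis.
    """
    own_chrom = segment.rsplit("_", 1)[0]
    t = ac.table
    sel = t[(t["segment"] == segment) & (t["target_chrom"] != own_chrom)]
    cells = np.zeros((2, 2), dtype=float)  # rows: wt, der; cols: short, long
    for row in sel.itertuples(index=False):
        i = 0 if row.allele == "wildtype" else 1
        j = 0 if row.target_chrom in short_chroms else 1
        cells[i, j] += row.count
    if cells.sum(axis=1).min() == 0:
        raise ValueError("both alleles need nonzero trans totals")
    frac_wt = cells[0, 0] / cells[0].sum()
    frac_der = cells[1, 0] / cells[1].sum()
    if (cells.sum(axis=0) == 0).any():
        return frac_wt, frac_der, 1.0
    _, p, _, _ = chi2_contingency(cells, correction=False)
    return frac_wt, frac_der, float(p)
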