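"""Rule-based single-cell classification for translocation mixtures.

Cells from a mixed population (a minority carrying the translocation) are
QC-filtered, classified by CCND1 expression, and — where full-length
allele-resolved data is available — phased to parental haplotypes using
imprinted marker genes, so that translocated cells can be called toward
the maternal or paternal allele and pseudo-bulk allelic ratios computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthgen import CellData

CCND1 = "CCND1"

# Droplet-based QC bounds: removal is strict, so cells exactly at a printed
# limit are kept.
MITO_MAX = 20.0
GENES_MIN, GENES_MAX = 500, 6000
READS_MIN, READS_MAX = 1000, 30000
MAPPED_MIN = 50_000

MIN_ALLELE_READS_CCND1 = 5
MIN_READS_POOL = 10
PHASE_BIAS = 0.90


def qc_filter_droplet(
    cells: CellData,
    mito_max: float = MITO_MAX,
    genes_min: int = GENES_MIN,
    genes_max: int = GENES_MAX,
    reads_min: int = READS_MIN,
    reads_max: int = READS_MAX,
) -> CellData:
    """Remove droplet cells failing mitochondrial / gene / read bounds.

    Cells with mito > 20%, genes detected < 500 or > 6000, or reads
    < 1000 or > 30000 are removed; bounds are exclusive as printed, so a
    cell exactly at a limit survives.
    """
    obs = cells.obs
    keep = (
        (obs["pct_mito"] <= mito_max)
        & (obs["n_genes_detected"] >= genes_min)
        & (obs["n_genes_detected"] <= genes_max)
        & (obs["total_reads"] >= reads_min)
        & (obs["total_reads"] <= reads_max)
    )
    if "is_doublet" in obs.columns:
        keep &= ~obs["is_doublet"].astype(bool)
    return cells.subset(obs.index[keep])


def qc_filter_fulllength(
    cells: CellData, min_mapped: int = MAPPED_MIN
) -> CellData:
    """Keep full-length cells with mapped reads >= min_mapped."""
    keep = cells.obs["mapped_reads"] >= min_mapped
    return cells.subset(cells.obs.index[keep])


def classify_ccnd1(cells: CellData, gene: str = CCND1) -> pd.Series:
    """CCND1 status per cell: positive iff at least one transcript."""
    if gene not in cells.counts.columns:
        raise KeyError(f"gene {gene!r} absent from count matrix")
    return (cells.counts[gene] >= 1).rename("ccnd1_positive")


@dataclass(frozen=True)
class HaplotypePhase:
    """Bijective haplotype-to-parent mapping with per-marker evidence."""

    mapping: dict[str, str]  # {"A": parent, "B": parent}
    evidence: pd.DataFrame  # marker, expressed_parent, reads_a, reads_b

    def parent_of(self, haplotype: str) -> str:
        return self.mapping[haplotype]

    def haplotype_of(self, parent: str) -> str:
        inv = {v: k for k, v in self.mapping.items()}
        return inv[parent]


def phase_haplotypes(
    non_tx_cells: CellData,
    imprinted_markers: list[tuple[str, str]],
    min_reads: int = MIN_READS_POOL,
    bias: float = PHASE_BIAS,
) -> HaplotypePhase:
    """Anchor haplotypes A/B to parents via imprinted marker expression.

    For each imprinted marker ``(gene, expressed_parent)``, allele reads
    are pooled across non-translocated cells; the haplotype carrying at
    least ``bias`` of the marker's reads is assigned that parent.  Markers
    with fewer than ``min_reads`` pooled reads are dropped from evidence;
    all remaining markers must agree on a bijective mapping, otherwise a
    phase-conflict error is raised.
    """
    rows = []
    proposals = set()
    for gene, parent in imprinted_markers:
        if gene not in non_tx_cells.allele_a.columns:
            continue
        reads_a = int(non_tx_cells.allele_a[gene].sum())
        reads_b = int(non_tx_cells.allele_b[gene].sum())
        total = reads_a + reads_b
        if total < min_reads:
            continue
        if reads_a / total >= bias:
            hap = "A"
        elif reads_b / total >= bias:
            hap = "B"
        else:
            raise ValueError(
                f"marker {gene}: allelic bias below {bias:.0%}, cannot phase"
            )
        rows.append((gene, parent, reads_a, reads_b))
        proposals.add((hap, parent))
    if not rows:
        raise ValueError("no imprinted marker with sufficient reads")
    parents = {p for _, p in proposals}
    haps = {h for h, _ in proposals}
    by_hap: dict[str, set[str]] = {}
    for h, p in proposals:
        by_hap.setdefault(h, set()).add(p)
    if any(len(ps) > 1 for ps in by_hap.values()) or (
        len(parents) == 2 and len(haps) == 1
    ):
        raise ValueError("phase conflict: imprinted markers disagree")
    # complete the bijection from whichever side is anchored
    mapping: dict[str, str] = {h: next(iter(ps)) for h, ps in by_hap.items()}
    other_h = ({"A", "B"} - set(mapping)).pop() if len(mapping) == 1 else None
    if other_h is not None:
        other_p = ({"maternal", "paternal"} - set(mapping.values())).pop()
        mapping[other_h] = other_p
    evidence = pd.DataFrame(
        rows, columns=["marker", "expressed_parent", "reads_a", "reads_b"]
    )
    return HaplotypePhase(mapping=mapping, evidence=evidence)


def call_translocated_cells(
    cells: CellData,
    phase: HaplotypePhase,
    gene: str = CCND1,
    min_reads: int = MIN_ALLELE_READS_CCND1,
) -> pd.Series:
    """Label cells non_tx / tx_maternal / tx_paternal / unclassified.

    Cells without any CCND1 transcript are non-translocated.  Cells with
    at least ``min_reads`` allele-specific CCND1 reads on exactly one
    haplotype and zero on the other are called translocated toward that
    haplotype's parent; anything else is unclassified.
    """
    counts = cells.counts[gene]
    a = cells.allele_a[gene]
    b = cells.allele_b[gene]
    labels = pd.Series("unclassified", index=cells.obs.index, name="tx_label")
    labels[counts == 0] = "non_tx"
    only_a = (a >= min_reads) & (b == 0) & (counts > 0)
    only_b = (b >= min_reads) & (a == 0) & (counts > 0)
    labels[only_a] = f"tx_{phase.parent_of('A')}"
    labels[only_b] = f"tx_{phase.parent_of('B')}"
    return labels


def pseudobulk_allelic_ratio(
    cells: CellData,
    labels: pd.Series,
    phase: HaplotypePhase,
    genes: list[str] | None = None,
    min_reads_control: int = MIN_READS_POOL,
    min_reads_pool: int = MIN_READS_POOL,
) -> pd.DataFrame:
    """Pooled maternal/paternal transcript percentages per gene.

    Genes are reported when they have at least ``min_reads_control``
    allele-specific reads in the non-translocated pool and at least
    ``min_reads_pool`` in one of the translocated pools.  Percentages are
    computed per pool; a pool with zero reads for an included gene gets NA
    with a warning.
    """
    gene_list = genes if genes is not None else list(cells.counts.columns)
    mat_hap = phase.haplotype_of("maternal")
    pools = {
        "non_tx": labels == "non_tx",
        "tx_maternal": labels == "tx_maternal",
        "tx_paternal": labels == "tx_paternal",
    }
    rows = []
    for gene in gene_list:
        a = cells.allele_a[gene]
        b = cells.allele_b[gene]
        maternal = a if mat_hap == "A" else b
        paternal = b if mat_hap == "A" else a
        ctrl_total = int((maternal + paternal)[pools["non_tx"]].sum())
        tx_totals = {
            p: int((maternal + paternal)[pools[p]].sum())
            for p in ("tx_maternal", "tx_paternal")
        }
        if ctrl_total < min_reads_control or max(tx_totals.values()) < min_reads_pool:
            continue
        rec: dict[str, object] = {"gene_id": gene}
        for pool_name, sel in pools.items():
            m = int(maternal[sel].sum())
            p = int(paternal[sel].sum())
            if m + p == 0:
                warnings.warn(f"gene {gene}: pool {pool_name} has no allele reads")
                rec[f"{pool_name}_pct_maternal"] = np.nan
                rec[f"{pool_name}_pct_paternal"] = np.nan
            else:
                rec[f"{pool_name}_pct_maternal"] = 100.0 * m / (m + p)
                rec[f"{pool_name}_pct_paternal"] = 100.0 * p / (m + p)
        rows.append(rec)
    return pd.DataFrame(rows)
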