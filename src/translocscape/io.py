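"""Plain-text I/O for every exchange format of the pipeline.

Matrices travel as sparse triplet TSV (upper triangle) plus a BED bin
table; SNPs as minimal VCF (read back through pysam); read pairs, gene and
cell tables as TSV; bead models as CMM marker XML with a sidecar bin
table; profiles and tracks as BEDGRAPH.  BED intervals are 0-based
half-open, VCF positions 1-based.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .core import BinnedMatrix
from .synthgen import BeadModel, GeneRecord, HetSnp, Mate, ReadPair


# ---------------------------------------------------------------------------
# binned matrices: triplet TSV + BED bin table
# ---------------------------------------------------------------------------


def write_matrix(m: BinnedMatrix, triplet_path: str | Path, bins_path: str | Path) -> None:
    """Write upper-triangle nonzero entries and the bin table."""
    bins = m.bins.copy()
    bins["mask"] = m.mask.astype(int)
    bins.to_csv(bins_path, sep="\t", header=False, index=False)
    iu = np.triu_indices(m.n_bins)
    vals = m.counts[iu]
    keep = ~np.isnan(vals) & (vals != 0)
    df = pd.DataFrame(
        {"bin1": iu[0][keep], "bin2": iu[1][keep], "count": vals[keep]}
    )
    df.to_csv(triplet_path, sep="\t", header=False, index=False)


def read_matrix(
    triplet_path: str | Path, bins_path: str | Path, bin_size: int
) -> BinnedMatrix:
    bins = pd.read_csv(
        bins_path, sep="\t", header=None,
        names=["chrom", "start", "end", "mask"],
    )
    mask = bins.pop("mask").astype(bool).to_numpy()
    n = len(bins)
    counts = np.zeros((n, n))
    trip = pd.read_csv(
        triplet_path, sep="\t", header=None, names=["bin1", "bin2", "count"]
    )
    i = trip["bin1"].to_numpy(int)
    j = trip["bin2"].to_numpy(int)
    v = trip["count"].to_numpy(float)
    counts[i, j] = v
    counts[j, i] = v
    return BinnedMatrix(bins, counts, bin_size, mask)


# ---------------------------------------------------------------------------
# SNPs: minimal VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DER,Number=1,Type=String,Description="Derivative allele (ref/alt)">
##INFO=<ID=SRC,Number=.,Type=String,Description="Evidence sources">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_snps_vcf(snps: list[HetSnp], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for k, s in enumerate(snps):
            info = []
            if s.derivative_allele is not None:
                info.append(f"DER={s.derivative_allele}")
            if s.sources:
                info.append("SRC=" + ",".join(s.sources))
            fh.write(
                f"{s.chrom}\t{s.pos}\tsnp{k}\t{s.ref_base}\t{s.alt_base}"
                f"\t{s.quality:g}\t.\t{';'.join(info) or '.'}\n"
            )


def read_snps_vcf(path: str | Path) -> list[HetSnp]:
    snps = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            der = info.get("DER")
            src = info.get("SRC", ())
            if isinstance(src, str):
                src = (src,)
            snps.append(
                HetSnp(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_base=rec.ref,
                    alt_base=rec.alts[0],
                    derivative_allele=der,
                    quality=float(rec.qual) if rec.qual is not None else 0.0,
                    sources=tuple(src),
                )
            )
    return snps


# ---------------------------------------------------------------------------
# read pairs: TSV
# ---------------------------------------------------------------------------

READS_COLUMNS = [
    "pair_id", "chrom1", "pos1", "snp_pos1", "base1",
    "chrom2", "pos2", "snp_pos2", "base2",
]


def write_read_pairs(pairs: list[ReadPair], path: str | Path) -> None:
    rows = []
    for p in pairs:
        rows.append(
            (
                p.pair_id,
                p.mate1.chrom, p.mate1.pos,
                p.mate1.snp_pos if p.mate1.snp_pos is not None else ".",
                p.mate1.base or ".",
                p.mate2.chrom, p.mate2.pos,
                p.mate2.snp_pos if p.mate2.snp_pos is not None else ".",
                p.mate2.base or ".",
            )
        )
    pd.DataFrame(rows, columns=READS_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_read_pairs(path: str | Path) -> list[ReadPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(
            ReadPair(
                pair_id=row.pair_id,
                mate1=Mate(
                    row.chrom1, int(row.pos1),
                    None if row.snp_pos1 == "." else int(row.snp_pos1),
                    None if row.base1 == "." else row.base1,
                ),
                mate2=Mate(
                    row.chrom2, int(row.pos2),
                    None if row.snp_pos2 == "." else int(row.snp_pos2),
                    None if row.base2 == "." else row.base2,
                ),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# bead models: CMM marker XML + sidecar bin table
# ---------------------------------------------------------------------------


def write_cmm(
    model: BeadModel,
    cmm_path: str | Path,
    sidecar_path: str | Path | None = None,
    colors: dict[str, tuple[float, float, float]] | None = None,
    name: str = "model",
) -> None:
    """Write a CMM marker file; bead order defines the bin mapping.

    The sidecar TSV (bead id, chrom, bin) is required for reading the
    model back; CMM itself carries only coordinates and colors.
    """
    root = ET.Element("marker_set", name=name)
    rows = []
    for k, row in enumerate(model.beads.itertuples(index=False), start=1):
        r, g, b = (colors or {}).get(row.chrom, (0.7, 0.7, 0.7))
        ET.SubElement(
            root, "marker", id=str(k),
            x=f"{row.x:.6f}", y=f"{row.y:.6f}", z=f"{row.z:.6f}",
            r=f"{r:.3f}", g=f"{g:.3f}", b=f"{b:.3f}", radius="0.3",
        )
        rows.append((k, row.chrom, row.bin))
    for k in range(1, len(rows)):
        if rows[k][1] == rows[k - 1][1]:
            ET.SubElement(
                root, "link", id1=str(rows[k - 1][0]), id2=str(rows[k][0]),
                r="0.7", g="0.7", b="0.7", radius="0.1",
            )
    ET.ElementTree(root).write(cmm_path, xml_declaration=True, encoding="unicode")
    if sidecar_path is not None:
        pd.DataFrame(rows, columns=["bead_id", "chrom", "bin"]).to_csv(
            sidecar_path, sep="\t", index=False
        )


def read_cmm(
    cmm_path: str | Path, sidecar_path: str | Path, radius: float = 5.0
) -> BeadModel:
    tree = ET.parse(cmm_path)
    coords = {}
    for marker in tree.getroot().iter("marker"):
        coords[int(marker.get("id"))] = (
            float(marker.get("x")), float(marker.get("y")), float(marker.get("z"))
        )
    sidecar = pd.read_csv(sidecar_path, sep="\t")
    rows = []
    for row in sidecar.itertuples(index=False):
        if row.bead_id not in coords:
            raise ValueError(f"bead {row.bead_id} missing from CMM file")
        rows.append((row.chrom, row.bin, *coords[row.bead_id]))
    return BeadModel(
        beads=pd.DataFrame(rows, columns=["chrom", "bin", "x", "y", "z"]),
        radius=radius,
    )


def recolor_cmm(
    cmm_path: str | Path,
    sidecar_path: str | Path,
    out_path: str | Path,
    colors: dict[str, tuple[float, float, float]],
    keep_only: set[str] | None = None,
) -> None:
    """Recolor beads by chromosome, optionally filtering to selected ones."""
    tree = ET.parse(cmm_path)
    root = tree.getroot()
    sidecar = pd.read_csv(sidecar_path, sep="\t").set_index("bead_id")
    drop = []
    kept_ids = set()
    for marker in root.iter("marker"):
        bead_id = int(marker.get("id"))
        chrom = sidecar.loc[bead_id, "chrom"]
        if keep_only is not None and chrom not in keep_only:
            drop.append(marker)
            continue
        kept_ids.add(bead_id)
        if chrom in colors:
            r, g, b = colors[chrom]
            marker.set("r", f"{r:.3f}")
            marker.set("g", f"{g:.3f}")
            marker.set("b", f"{b:.3f}")
    for marker in drop:
        root.remove(marker)
    for link in list(root.iter("link")):
        if int(link.get("id1")) not in kept_ids or int(link.get("id2")) not in kept_ids:
            root.remove(link)
    tree.write(out_path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# bedgraph, genes, cells
# ---------------------------------------------------------------------------


def write_bedgraph(
    df: pd.DataFrame, path: str | Path, value_col: str = "value"
) -> None:
    df[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )


def write_genes(genes: list[GeneRecord], path: str | Path) -> None:
    rows = [
        (
            g.gene_id, g.chrom, g.tss, g.strand, g.bin_index,
            g.log2fc, g.fdr, int(g.protein_coding), int(g.promoter_active),
            g.imprinted_parent or ".",
        )
        for g in genes
    ]
    pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "tss", "strand", "bin_index",
            "log2fc", "fdr", "protein_coding", "promoter_active",
            "imprinted_parent",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
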