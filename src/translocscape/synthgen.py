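"""Synthetic toy diploid genome with a reciprocal translocation.

This module generates every input the analysis stages consume, with known
ground truth: binned Hi-C-like contact matrices for a "normal" and a "tumor"
cell population, phased heterozygous SNPs and SNP-tagged read pairs, 3D bead
models with a configured derivative radial shift, and a cell mixture in which
a fixed fraction of cells carries the translocation and upregulates genes in
configured bins.

The contact model is deliberately simple: cis contacts follow a power-law
distance decay, trans contacts scale inversely with the difference in mean
radial position of the two chromosome territories, and counts are Poisson
draws around those means.  The reciprocal translocation adds derivative-cis
contacts across the junction to the tumor matrix; a single ultra-long-range
cis loop (present in both conditions, as such loops pre-exist in normal
cells) multiplies the decay expectation at its anchor pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BinnedMatrix, SegmentMap, make_bins

MB = 1_000_000
BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Parameters of the toy genome and of every simulated assay.

    Chromosomes are named ``chr1`` .. ``chrN`` with lengths in Mb.  The
    default genome (20/15/10/8 Mb) keeps every downstream stage at desk
    scale.  ``translocation`` is ``(chromA, bpA, chromB, bpB)`` in bp;
    derivative 1 is chromA-up joined to chromB-down, derivative 2 the
    reciprocal product.
    """

    chrom_lengths_mb: tuple[int, ...] = (20, 15, 10, 8)
    bin_size: int = MB
    translocation: tuple[str, int, str, int] | None = None
    #: (genome bin index, genome bin index, boost factor >= 1); cis loop.
    loop: tuple[int, int, float] | None = None
    #: mean radial position per chromosome in [0, 1]; default derived from
    #: length (longer chromosomes sit closer to the periphery).
    radial_model: dict[str, float] | None = None
    cis_decay_exponent: float = 1.0
    cis_scale: float = 300.0
    trans_scale: float = 3.0
    #: heterozygous SNPs per Mb on the translocation partners.
    snp_density: float = 5.0
    n_read_pairs: int = 10_000
    seq_error_rate: float = 0.0
    #: probability that a trans read from the wild-type / derivative allele
    #: targets a short chromosome; the gap emulates the inward shift of the
    #: derivative territory.
    wt_short_frac: float = 0.40
    der_short_frac: float = 0.60
    tx_cell_fraction: float = 0.11
    #: genome bin index -> within-cell fold change in translocated cells.
    fc_spec: dict[int, float] = field(default_factory=dict)
    n_cells: int = 1000
    genes_per_mb: float = 5.0
    base_expression: float = 4.0
    #: fraction of a gene's reads that carry an allele-informative SNP.
    allele_informative_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tx_cell_fraction <= 1.0:
            raise ValueError("tx_cell_fraction must be in [0, 1]")
        if any(fc < 0 for fc in self.fc_spec.values()):
            raise ValueError("fold changes must be >= 0")
        if self.translocation is not None:
            ca, bpa, cb, bpb = self.translocation
            lengths = self.chrom_lengths()
            for chrom, bp in ((ca, bpa), (cb, bpb)):
                if chrom not in lengths:
                    raise ValueError(f"translocation chromosome {chrom!r} unknown")
                if not 0 < bp < lengths[chrom]:
                    raise ValueError(
                        f"breakpoint {bp} not strictly inside {chrom}"
                    )
        if self.loop is not None:
            a, b, boost = self.loop
            n = sum(self.chrom_lengths_mb) * MB // self.bin_size
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError("loop anchors outside genome")
            if boost < 1.0:
                raise ValueError("loop boost must be >= 1")

    # -- derived genome structure -------------------------------------------

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths_mb))]

    def chrom_lengths(self) -> dict[str, int]:
        return {
            name: length * MB
            for name, length in zip(self.chrom_names(), self.chrom_lengths_mb)
        }

    def bins(self) -> pd.DataFrame:
        return make_bins(self.chrom_lengths(), self.bin_size)

    def radial_positions(self) -> dict[str, float]:
        """Mean radial position of each territory (0 = center, 1 = lamina)."""
        if self.radial_model is not None:
            return dict(self.radial_model)
        lengths = np.array(self.chrom_lengths_mb, dtype=float)
        lo, hi = lengths.min(), lengths.max()
        span = hi - lo if hi > lo else 1.0
        radial = 0.30 + 0.50 * (lengths - lo) / span
        return dict(zip(self.chrom_names(), radial))

    def short_chroms(self) -> set[str]:
        """Shorter half of the non-partner chromosomes (trans targets)."""
        partners = (
            {self.translocation[0], self.translocation[2]}
            if self.translocation
            else set()
        )
        order = sorted(
            (c for c in self.chrom_names() if c not in partners),
            key=lambda c: self.chrom_lengths()[c],
        )
        return set(order[: max(len(order) // 2, 1)]) if order else set()

    def segment_map(self) -> SegmentMap:
        """Breakpoint map for the two translocation partners (1 kb gap)."""
        if self.translocation is None:
            return SegmentMap({})
        ca, bpa, cb, bpb = self.translocation
        return SegmentMap({ca: (bpa, bpa + 1000), cb: (bpb, bpb + 1000)})


@dataclass
class GroundTruth:
    """True labels of a simulated dataset; fields are filled per assay."""

    partner_pair: tuple[str, str] | None = None
    loop_anchors: tuple[int, int] | None = None
    loop_boost: float | None = None
    radial: dict[str, float] | None = None
    derivative_shift: float | None = None
    read_allele: pd.Series | None = None  # pair_id -> wildtype / derivative
    enriched_bins: tuple[int, ...] | None = None
    tx_cells: pd.Series | None = None  # cell_id -> bool
    tx_parent: pd.Series | None = None  # cell_id -> maternal / paternal / none
    phase: dict[str, str] | None = None  # haplotype A/B -> parent


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((cfg.seed * 1_000_003 + salt) % 2**31)


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------


def expected_cis(cfg: SimConfig, separation_bins: int) -> float:
    """Closed-form cis decay expectation at a given bin separation."""
    return cfg.cis_scale * (separation_bins + 1) ** (-cfg.cis_decay_exponent)


def contact_means(cfg: SimConfig) -> np.ndarray:
    """Expected contact matrix of the normal (non-translocated) genome."""
    bins = cfg.bins()
    n = len(bins)
    chroms = bins["chrom"].to_numpy()
    radial = cfg.radial_positions()
    mean = np.empty((n, n), dtype=float)
    idx_in_chrom = bins.groupby("chrom", sort=False).cumcount().to_numpy()
    for i in range(n):
        for j in range(i, n):
            if chroms[i] == chroms[j]:
                m = expected_cis(cfg, abs(int(idx_in_chrom[j] - idx_in_chrom[i])))
            else:
                dr = abs(radial[chroms[i]] - radial[chroms[j]])
                m = cfg.trans_scale / (0.1 + dr)
            mean[i, j] = mean[j, i] = m
    if cfg.loop is not None:
        a, b, boost = cfg.loop
        if chroms[a] != chroms[b]:
            raise ValueError("loop anchors must lie on one chromosome")
        mean[a, b] *= boost
        mean[b, a] = mean[a, b]
    return mean


def derivative_extra_means(cfg: SimConfig) -> np.ndarray:
    """Derivative-cis contact expectations added by the translocation.

    Bins that become linearly adjacent on a derivative chromosome gain
    decay-model contacts at their derivative separation; one of the two
    homologues is translocated, so the added expectation is half the
    cis-scale decay.
    """
    bins = cfg.bins()
    n = len(bins)
    extra = np.zeros((n, n), dtype=float)
    if cfg.translocation is None:
        return extra
    ca, bpa, cb, bpb = cfg.translocation
    starts = bins["start"].to_numpy()
    chroms = bins["chrom"].to_numpy()
    idx_in_chrom = bins.groupby("chrom", sort=False).cumcount().to_numpy()

    def der_pairs(c_up: str, bp_up: int, c_down: str, bp_down: int) -> None:
        up = np.flatnonzero((chroms == c_up) & (starts < bp_up))
        down = np.flatnonzero((chroms == c_down) & (starts >= bp_down))
        if up.size == 0 or down.size == 0:
            return
        n_up = up.size
        for k, i in enumerate(up):
            for m, j in enumerate(down):
                # derivative coordinates: up bins 0..n_up-1, down bins follow
                sep = (n_up - 1 - k) + 1 + m
                val = 0.5 * expected_cis(cfg, sep)
                extra[i, j] += val
                extra[j, i] += val

    der_pairs(ca, bpa, cb, bpb)  # derivative 1: chrA up + chrB down
    der_pairs(cb, bpb, ca, bpa)  # derivative 2: chrB up + chrA down
    return extra


def _poisson_symmetric(
    rng: np.random.Generator, mean: np.ndarray
) -> np.ndarray:
    n = mean.shape[0]
    iu = np.triu_indices(n)
    draws = rng.poisson(mean[iu]).astype(float)
    out = np.zeros_like(mean)
    out[iu] = draws
    out.T[iu] = draws
    return out


def simulate_contacts(
    cfg: SimConfig,
) -> tuple[BinnedMatrix, BinnedMatrix, GroundTruth]:
    """Simulate normal and tumor contact matrices with known structure."""
    rng = _rng(cfg, 1)
    bins = cfg.bins()
    base = contact_means(cfg)
    normal = _poisson_symmetric(rng, base)
    tumor = _poisson_symmetric(rng, base + derivative_extra_means(cfg))
    truth = GroundTruth(
        partner_pair=(
            (cfg.translocation[0], cfg.translocation[2])
            if cfg.translocation
            else None
        ),
        loop_anchors=cfg.loop[:2] if cfg.loop else None,
        loop_boost=cfg.loop[2] if cfg.loop else None,
        radial=cfg.radial_positions(),
    )
    return (
        BinnedMatrix(bins.copy(), normal, cfg.bin_size),
        BinnedMatrix(bins.copy(), tumor, cfg.bin_size),
        truth,
    )


# ---------------------------------------------------------------------------
# SNPs and allele-tagged read pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HetSnp:
    """Phased heterozygous SNP with a derivative-allele assignment."""

    chrom: str
    pos: int  # 1-based (VCF convention)
    ref_base: str
    alt_base: str
    derivative_allele: str | None = None  # "ref" | "alt" | None
    quality: float = 99.0
    sources: tuple[str, ...] = ()

    @property
    def derivative_base(self) -> str | None:
        if self.derivative_allele is None:
            return None
        return self.ref_base if self.derivative_allele == "ref" else self.alt_base

    @property
    def wildtype_base(self) -> str | None:
        if self.derivative_allele is None:
            return None
        return self.alt_base if self.derivative_allele == "ref" else self.ref_base


@dataclass(frozen=True)
class Mate:
    chrom: str
    pos: int
    snp_pos: int | None = None  # 1-based position of the covered SNP
    base: str | None = None


@dataclass(frozen=True)
class ReadPair:
    pair_id: str
    mate1: Mate
    mate2: Mate


def simulate_allelic_reads(
    cfg: SimConfig,
) -> tuple[list[HetSnp], list[ReadPair], GroundTruth]:
    """Simulate phased SNPs and trans read pairs tagged by true allele.

    Read pairs anchor their first mate at a SNP in the "up" segment of the
    first translocation partner; the second mate targets another chromosome,
    with derivative-allele reads biased toward short chromosomes
    (``der_short_frac`` vs ``wt_short_frac``) to emulate the inward shift of
    the derivative territory.  With ``seq_error_rate`` > 0 the recorded base
    is flipped to the other allele's base.
    """
    if cfg.translocation is None:
        raise ValueError("simulate_allelic_reads requires a translocation")
    rng = _rng(cfg, 2)
    ca, bpa, cb, bpb = cfg.translocation
    lengths = cfg.chrom_lengths()

    snps: list[HetSnp] = []
    for chrom, bp in ((ca, bpa), (cb, bpb)):
        n_snps = int(round(cfg.snp_density * lengths[chrom] / MB))
        if n_snps == 0:
            continue
        pos = np.sort(
            rng.choice(np.arange(1, lengths[chrom] + 1), n_snps, replace=False)
        )
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            snps.append(
                HetSnp(
                    chrom=chrom,
                    pos=int(p),
                    ref_base=str(BASES[ref]),
                    alt_base=str(BASES[alt]),
                    derivative_allele=str(rng.choice(["ref", "alt"])),
                    sources=("synthetic",),
                )
            )

    up_snps = [s for s in snps if s.chrom == ca and s.pos <= bpa]
    pairs: list[ReadPair] = []
    labels: dict[str, str] = {}
    if cfg.snp_density > 0 and up_snps:
        short = sorted(cfg.short_chroms())
        lng = sorted(set(cfg.chrom_names()) - set(short) - {ca, cb})
        alleles = rng.random(cfg.n_read_pairs) < 0.5
        for k in range(cfg.n_read_pairs):
            allele = "derivative" if alleles[k] else "wildtype"
            snp = up_snps[int(rng.integers(len(up_snps)))]
            true_base = (
                snp.derivative_base if allele == "derivative" else snp.wildtype_base
            )
            base = true_base
            if cfg.seq_error_rate > 0 and rng.random() < cfg.seq_error_rate:
                base = (
                    snp.wildtype_base
                    if allele == "derivative"
                    else snp.derivative_base
                )
            p_short = (
                cfg.der_short_frac if allele == "derivative" else cfg.wt_short_frac
            )
            pool = short if (short and rng.random() < p_short) else (lng or short)
            target = pool[int(rng.integers(len(pool)))]
            tpos = int(rng.integers(1, lengths[target] + 1))
            pid = f"pair{k:06d}"
            pairs.append(
                ReadPair(
                    pair_id=pid,
                    mate1=Mate(ca, snp.pos, snp_pos=snp.pos, base=base),
                    mate2=Mate(target, tpos),
                )
            )
            labels[pid] = allele

    truth = GroundTruth(
        partner_pair=(ca, cb),
        read_allele=pd.Series(labels, dtype=object),
    )
    return snps, pairs, truth


# ---------------------------------------------------------------------------
# bead models
# ---------------------------------------------------------------------------


@dataclass
class BeadModel:
    """Allele-level 3D bead coordinates inside a spherical nucleus.

    ``beads`` has one row per Mb bin of each allele-level chromosome with
    columns ``chrom`` (allele label, e.g. ``chr1_a`` or ``der1``), ``bin``
    (Mb index along that chromosome) and ``x``/``y``/``z`` in length units.
    """

    beads: pd.DataFrame
    radius: float = 5.0

    def coords(self, chrom_label: str) -> np.ndarray:
        sel = self.beads[self.beads["chrom"] == chrom_label]
        if sel.empty:
            raise KeyError(f"no beads for {chrom_label!r}")
        return sel[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.beads["chrom"]))


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _place_chromosome(
    rng: np.random.Generator,
    n_beads: int,
    radial_frac: float,
    radius: float,
    step: float = 0.35,
    radial_sd: float = 0.03,
) -> np.ndarray:
    """Random-walk territory whose center of mass sits at radial_frac * R."""
    r = float(np.clip(radial_frac + rng.normal(0.0, radial_sd), 0.02, 0.95))
    center = _random_unit(rng) * r * radius
    walk = np.cumsum(rng.normal(scale=step, size=(n_beads, 3)), axis=0)
    walk -= walk.mean(axis=0)  # COM exactly at `center`
    beads = center + walk
    # shrink deviations if any bead pokes outside the nucleus
    norms = np.linalg.norm(beads, axis=1)
    if norms.max() > radius:
        margin = radius - np.linalg.norm(center)
        extent = np.linalg.norm(walk, axis=1).max()
        if extent > 0 and margin > 0:
            walk *= 0.95 * margin / extent
            beads = center + walk
    return beads


def simulate_bead_models(
    cfg: SimConfig,
    n_models: int,
    derivative_shift: float = 0.0,
    radius: float = 5.0,
) -> list[BeadModel]:
    """Simulate diploid bead models; derivatives are shifted radially.

    Each wild-type chromosome contributes alleles ``_a`` and ``_b`` at its
    configured mean radial position.  With a translocation, the ``_b``
    alleles of the two partners are replaced by derivatives ``der1`` and
    ``der2`` whose centers of mass are displaced by ``derivative_shift``
    (in units of the nuclear radius) relative to their wild-type partner
    of origin (chrA for der1, chrB for der2).  If a cis loop is configured,
    its two anchor beads are co-localised.
    """
    rng = _rng(cfg, 3)
    radial = cfg.radial_positions()
    lengths_mb = {
        c: length // MB for c, length in cfg.chrom_lengths().items()
    }
    bins = cfg.bins().reset_index()
    loop_local: tuple[str, int, int] | None = None
    if cfg.loop is not None:
        a, b, _ = cfg.loop
        ca = bins.loc[a, "chrom"]
        if bins.loc[b, "chrom"] != ca:
            raise ValueError("loop anchors must lie on one chromosome")
        first = bins[bins["chrom"] == ca].index[0]
        loop_local = (str(ca), int(a - first), int(b - first))

    tx = cfg.translocation
    models = []
    for _ in range(n_models):
        rows = []

        def add(label: str, n_beads: int, radial_frac: float, origin: str) -> None:
            coords = _place_chromosome(rng, n_beads, radial_frac, radius)
            if loop_local is not None and origin == loop_local[0]:
                i, j = loop_local[1], loop_local[2]
                if i < n_beads and j < n_beads:
                    coords[j] = coords[i] + rng.normal(scale=0.05, size=3)
            for b_idx in range(n_beads):
                rows.append((label, b_idx, *coords[b_idx]))

        for chrom, n_mb in lengths_mb.items():
            add(f"{chrom}_a", n_mb, radial[chrom], chrom)
            is_partner = tx is not None and chrom in (tx[0], tx[2])
            if not is_partner:
                add(f"{chrom}_b", n_mb, radial[chrom], chrom)
        if tx is not None:
            ca, bpa, cb, bpb = tx
            n_der1 = bpa // MB + (lengths_mb[cb] - bpb // MB)
            n_der2 = bpb // MB + (lengths_mb[ca] - bpa // MB)
            add("der1", max(n_der1, 1), radial[ca] + derivative_shift, ca)
            add("der2", max(n_der2, 1), radial[cb] + derivative_shift, cb)
        models.append(
            BeadModel(
                beads=pd.DataFrame(rows, columns=["chrom", "bin", "x", "y", "z"]),
                radius=radius,
            )
        )
    return models


# ---------------------------------------------------------------------------
# expression: genes and cells
# ---------------------------------------------------------------------------


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    bin_index: int  # genome bin index at cfg.bin_size
    log2fc: float
    fdr: float
    protein_coding: bool = True
    promoter_active: bool = False
    imprinted_parent: str | None = None  # "maternal" | "paternal" | None


@dataclass
class CellData:
    """DataFrame-backed container of a simulated single-cell experiment.

    ``obs`` carries per-cell QC metrics and ground-truth-free metadata;
    ``counts`` is cells x genes; ``allele_a``/``allele_b`` are the
    allele-resolved read counts on haplotypes A and B (same shape).
    """

    obs: pd.DataFrame
    counts: pd.DataFrame
    allele_a: pd.DataFrame
    allele_b: pd.DataFrame

    def subset(self, cell_ids: pd.Index | list[str]) -> "CellData":
        return CellData(
            self.obs.loc[cell_ids].copy(),
            self.counts.loc[cell_ids].copy(),
            self.allele_a.loc[cell_ids].copy(),
            self.allele_b.loc[cell_ids].copy(),
        )

    @property
    def n_cells(self) -> int:
        return len(self.obs)


def simulate_expression(
    cfg: SimConfig,
) -> tuple[list[GeneRecord], CellData, GroundTruth]:
    """Simulate genes and a translocated/non-translocated cell mixture.

    Translocated cells (fraction ``tx_cell_fraction``) express CCND1
    (guaranteed >= 1 transcript and >= 5 allele reads, all on the
    translocated haplotype) and upregulate genes in ``fc_spec`` bins by the
    configured fold change, with the extra reads in cis on the translocated
    haplotype.  Two imprinted marker genes are expressed monoallelically
    from the paternal and maternal haplotype respectively, anchoring the
    haplotype-to-parent phase.
    """
    rng = _rng(cfg, 4)
    bins = cfg.bins()
    n_bins = len(bins)
    lengths = cfg.chrom_lengths()
    tx = cfg.translocation
    ca = tx[0] if tx else cfg.chrom_names()[0]
    bpa = tx[1] if tx else lengths[ca] // 2

    # haplotype -> parent mapping for this toy individual
    a_is_maternal = bool(rng.integers(2))
    phase = {
        "A": "maternal" if a_is_maternal else "paternal",
        "B": "paternal" if a_is_maternal else "maternal",
    }

    # -- genes --------------------------------------------------------------
    genes: list[GeneRecord] = []
    total_mb = sum(cfg.chrom_lengths_mb)
    n_genes = int(round(cfg.genes_per_mb * total_mb))
    chrom_arr = bins["chrom"].to_numpy()
    start_arr = bins["start"].to_numpy()
    gpos = np.sort(rng.integers(0, total_mb * MB, size=n_genes))
    # map linear genome coordinate to (chrom, local position)
    offsets = np.cumsum([0] + [lengths[c] for c in cfg.chrom_names()])
    for k, g in enumerate(gpos):
        ci = int(np.searchsorted(offsets, g, side="right") - 1)
        chrom = cfg.chrom_names()[ci]
        local = int(g - offsets[ci])
        bin_index = int(
            np.flatnonzero(
                (chrom_arr == chrom) & (start_arr <= local)
            )[-1]
        )
        genes.append(
            GeneRecord(
                gene_id=f"gene{k:04d}",
                chrom=chrom,
                tss=local,
                strand="+" if rng.random() < 0.5 else "-",
                bin_index=bin_index,
                log2fc=0.0,
                fdr=1.0,
            )
        )
    # CCND1 sits just downstream of the breakpoint on partner A's "down" side
    ccnd1_bin = int(
        np.flatnonzero((chrom_arr == ca) & (start_arr <= min(bpa, lengths[ca] - 1)))[-1]
    )
    genes.append(
        GeneRecord("CCND1", ca, min(bpa + 1000, lengths[ca] - 1), "+",
                   ccnd1_bin, 0.0, 1.0)
    )
    # imprinted markers on a non-partner chromosome
    other = [c for c in cfg.chrom_names() if tx is None or c not in (tx[0], tx[2])]
    imprint_chrom = other[-1] if other else ca
    for name, parent, frac in (
        ("IMPR_PAT", "paternal", 0.25),
        ("IMPR_MAT", "maternal", 0.75),
    ):
        pos = int(lengths[imprint_chrom] * frac)
        bi = int(
            np.flatnonzero((chrom_arr == imprint_chrom) & (start_arr <= pos))[-1]
        )
        genes.append(
            GeneRecord(name, imprint_chrom, pos, "+", bi, 0.0, 1.0,
                       imprinted_parent=parent)
        )

    gene_ids = [g.gene_id for g in genes]
    enriched = tuple(sorted(cfg.fc_spec))
    for b in enriched:
        if not 0 <= b < n_bins:
            raise ValueError(f"fc_spec bin {b} outside genome")

    # -- cells --------------------------------------------------------------
    n_cells = cfg.n_cells
    cell_ids = [f"cell{k:04d}" for k in range(n_cells)]
    is_tx = rng.random(n_cells) < cfg.tx_cell_fraction
    tx_parent = np.where(
        is_tx, np.where(rng.random(n_cells) < 0.5, "maternal", "paternal"), "none"
    )

    base_mean = np.full(len(genes), cfg.base_expression)
    # imprinted markers and CCND1 handled separately
    special = {g.gene_id: i for i, g in enumerate(genes)
               if g.gene_id in ("CCND1", "IMPR_PAT", "IMPR_MAT")}
    base_mean[special["CCND1"]] = 0.0

    mean_matrix = np.tile(base_mean, (n_cells, 1))
    for b, fc in cfg.fc_spec.items():
        cols = [i for i, g in enumerate(genes)
                if g.bin_index == b and g.gene_id not in special]
        for c in cols:
            mean_matrix[is_tx, c] *= fc
    counts = rng.poisson(mean_matrix).astype(int)
    # CCND1: expressed only in translocated cells, guaranteed detectable
    ccnd1_col = special["CCND1"]
    counts[:, ccnd1_col] = 0
    counts[is_tx, ccnd1_col] = 8 + rng.poisson(4, size=int(is_tx.sum()))

    # -- allele-resolved reads ---------------------------------------------
    informative = rng.binomial(counts, cfg.allele_informative_frac)
    hap_a = rng.binomial(informative, 0.5)
    # extra upregulation reads act in cis on the translocated haplotype
    for b, fc in cfg.fc_spec.items():
        if fc <= 1.0:
            continue
        cols = [i for i, g in enumerate(genes)
                if g.bin_index == b and g.gene_id not in special]
        for c in cols:
            extra = np.clip(
                counts[:, c] - rng.poisson(base_mean[c], size=n_cells), 0, None
            )
            extra_inf = rng.binomial(
                np.where(is_tx, extra, 0), cfg.allele_informative_frac
            )
            tx_on_a = (tx_parent == phase["A"])
            base_inf = np.clip(informative[:, c] - extra_inf, 0, None)
            hap_a[:, c] = rng.binomial(base_inf, 0.5) + np.where(
                tx_on_a, extra_inf, 0
            )
            informative[:, c] = base_inf + extra_inf
    # CCND1 allele reads: all on the translocated haplotype
    informative[:, ccnd1_col] = counts[:, ccnd1_col]
    hap_a[:, ccnd1_col] = np.where(
        tx_parent == phase["A"], counts[:, ccnd1_col], 0
    )
    # imprinted markers: monoallelic on their parent haplotype
    for name, parent in (("IMPR_PAT", "paternal"), ("IMPR_MAT", "maternal")):
        c = special[name]
        informative[:, c] = counts[:, c]
        hap_a[:, c] = counts[:, c] if phase["A"] == parent else 0
    hap_b = informative - hap_a

    # -- QC metrics (all cells healthy by construction) ----------------------
    total_reads = counts.sum(axis=1) * 10 + 5000
    obs = pd.DataFrame(
        {
            "pct_mito": rng.uniform(1.0, 15.0, n_cells).round(2),
            "n_genes_detected": np.clip((counts > 0).sum(axis=1) + 600, 500, 6000),
            "total_reads": np.clip(total_reads, 1000, 30000),
            "mapped_reads": np.maximum(total_reads * 8, 60_000),
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )

    cells = CellData(
        obs=obs,
        counts=pd.DataFrame(counts, index=obs.index, columns=gene_ids),
        allele_a=pd.DataFrame(hap_a, index=obs.index, columns=gene_ids),
        allele_b=pd.DataFrame(hap_b, index=obs.index, columns=gene_ids),
    )

    # gene-level DE-style summary: honest pseudo-bulk mixture fold change
    pop_mean = counts.mean(axis=0)
    ctrl = counts[~is_tx].mean(axis=0) if (~is_tx).any() else pop_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(np.where(ctrl > 0, pop_mean / np.where(ctrl > 0, ctrl, 1), np.nan))
    for i, g in enumerate(genes):
        g.log2fc = float(lfc[i]) if np.isfinite(lfc[i]) else 0.0
        in_enriched = g.bin_index in cfg.fc_spec and g.gene_id not in special
        g.fdr = float(rng.uniform(0.0, 0.09)) if in_enriched else float(
            rng.uniform(0.1, 1.0)
        )

    truth = GroundTruth(
        partner_pair=(tx[0], tx[2]) if tx else None,
        enriched_bins=enriched,
        tx_cells=pd.Series(is_tx, index=obs.index),
        tx_parent=pd.Series(tx_parent, index=obs.index),
        phase=phase,
    )
    return genes, cells, truth
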