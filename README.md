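# translocscape

Reciprocal translocations such as the t(11;14) of mantle cell lymphoma do more
than fuse an enhancer to an oncogene: by changing the length, gene density and
GC content of the two derivative chromosomes they reorganise the
interchromosomal 3D landscape (derivative territories shift radially within
the nucleus), and by inserting a strong enhancer into pre-existing
ultra-long-range cis interactions they can enhance the expression of genes
across an entire chromosome arm, in a regulon-like fashion.

`translocscape` is a tested, reusable implementation of the computational
analyses needed to characterise this behaviour, aimed at genomicists working
with Hi-C, 4C/Tiled-C, bead-model and single-cell RNA-seq data from
translocated samples.  Every stage also runs on a fully synthetic toy diploid
genome with known ground truth, so the whole pipeline is testable without any
external data.

## What it computes

- **Interchromosomal landscape** (`translocscape.landscape`) — per-sample
  masking of low-coverage bins (row total < 60 000), depth normalisation to a
  fixed total (150 M), median merging across samples, trans interaction
  frequency per chromosome pair *f(i, j) = Σ counts / (nᵢ · nⱼ)* (counts per
  Mb²), log₂ fold changes between entities, common top-*q* extreme pairs, and
  a 2×2 chi-square enrichment test of translocation-partner involvement.
- **Allele-specific Hi-C** (`translocscape.allele_hic`) — consolidation of
  heterozygous SNPs from array replicates, pooled Hi-C calls and
  sorted-chromosome genotypes (GQ ≥ 20), derivative-allele assignment,
  read-pair classification (wildtype / derivative / none / conflict) and a
  chi-square test for the shift of derivative contacts toward short
  chromosomes.
- **Diploid deconvolution and 3D geometry** (`translocscape.diploid3d`) —
  allele-level matrix splitting (cis/2, trans/4; in tumors the wild-type
  homologue keeps the normal-reference counts and the derivative the clamped
  excess), center-of-mass radial positions ‖x̄‖₂ of bead-model territories,
  pairwise bin distances, bin-to-breakpoint distance profiles, compartment
  score aggregation (median of ten 100-kb scores per Mb) and GC-correlation
  eigenvector selection.
- **Viewpoint profiling** (`translocscape.profile`) — 4C fragment filtering
  (10 kb viewpoint exclusion) and 250-kb binning, arm-wide interaction
  profiles normalised to 100%, diamond insulation scores
  log₂(diamond mean / global diamond mean), common-depth rescaling, and
  breakpoint calling from the cross-partner contact drop-off.
- **Gene-level statistics** (`translocscape.regulon`) — upregulated-gene
  selection rules, the two-population mixture model
  *FC_pop = f · FC_tx + (1 − f)*, permutation enrichment of upregulated genes
  per 3-Mb bin with p = (#{random > observed} + 1)/n, fold-change–distance
  correlations, promoter-activity flags (±1500 bp of the TSS) and the
  allele→cell fraction conversion 2·AF for heterozygous translocations.
- **Single-cell classification** (`translocscape.allele_sc`) — droplet and
  full-length QC filters, CCND1 status (≥1 transcript), imprinting-based
  haplotype phasing, translocated-cell calling (≥5 allele reads on one
  haplotype, 0 on the other) and pseudo-bulk allelic ratios.
- **Synthetic data** (`translocscape.synthgen`) — the toy diploid genome:
  power-law cis decay, radial-territory trans model, derivative-junction
  contacts, one ultra-long-range loop, SNP-tagged reads, bead models with a
  configured radial shift, and a translocated-cell mixture with bin-localised
  upregulation.

## Worked example

```python
import numpy as np
from translocscape import landscape as L
from translocscape import allele_hic as AH
from translocscape import diploid3d as D3
from translocscape.synthgen import (
    SimConfig, simulate_contacts, simulate_allelic_reads, simulate_bead_models,
)

cfg = SimConfig(
    translocation=("chr1", 12_000_000, "chr2", 6_000_000),
    loop=(2, 14, 5.0),   # ultra-long-range cis loop, 5x over decay
    seed=1,
)

normal, tumor, truth = simulate_contacts(cfg)
fn = L.pair_frequency(L.normalize_total(normal, 1_000_000))
ft = L.pair_frequency(L.normalize_total(tumor, 1_000_000))
fc = L.log2fc_pairs(ft, fn)
print("top interchromosomal log2FC pair:", L.top_partner_pair(fc))
print("log2FC(chr1, chr2) = %.2f" % fc.loc["chr1", "chr2"])

snps, pairs, _ = simulate_allelic_reads(cfg)
ac = AH.allele_interaction_counts(pairs, snps, cfg.segment_map())
fw, fd, p = AH.short_chrom_fraction_test(ac, "chr1_up", cfg.short_chroms())
print("short-chromosome fraction: wildtype %.3f vs derivative %.3f "
      "(chi2 p = %.2e)" % (fw, fd, p))

models = simulate_bead_models(cfg, 100, derivative_shift=-0.17)
diffs = [D3.radial_position(m, "der1") - D3.radial_position(m, "chr1_a")
         for m in models]
print("mean radial shift of der1: %.2f units (%.1f%% of R)"
      % (np.mean(diffs), D3.radial_shift_percent(np.mean(diffs), 5.0)))
```

prints

```
top interchromosomal log2FC pair: ('chr1', 'chr2')
log2FC(chr1, chr2) = 0.90
short-chromosome fraction: wildtype 0.395 vs derivative 0.593 (chi2 p = 2.01e-87)
mean radial shift of der1: -0.83 units (-16.5% of R)
```

The tumor matrix's strongest interchromosomal gain identifies the configured
translocation partners; the derivative allele of the chr1 "up" segment
contacts short chromosomes about 1.5× more often than its wild-type
counterpart (a proxy for its inward nuclear shift); and over 100 bead models
the derivative territory recovers the configured inward displacement of 17%
of the nuclear radius.

## Command line

The same stages are available as subcommands of the `translocscape` console
script — `simulate`, `landscape`, `allele-hic`, `diploid3d`, `profile`,
`regulon`, `allele-sc` — each writing plain-text outputs plus a JSON manifest
with parameters, seed and output checksums.  An end-to-end synthetic demo:

```bash
translocscape simulate --outdir demo --seed 5
translocscape landscape --case demo/tumor --control demo/normal \
    --min-total 0 --target 1000000 --outdir demo/landscape
translocscape allele-hic --snps demo/snps.vcf --reads demo/read_pairs.tsv \
    --segments demo/segments.yaml --segment chr1_up --short-chroms chr4 \
    --outdir demo/allele-hic
```

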