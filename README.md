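# spotsnv

Spot-resolved somatic SNV analysis for spatial transcriptomics.

Spatial transcriptomics reads carry more than expression: reads overlapping a
somatic variant locus place that mutation at a capture spot. `spotsnv`
turns spot-level SNV evidence (a Mutect2-style somatic VCF plus a per-read
evidence table) into spatially interpretable mutation statistics for tumor
sections:

* **Effective SNVs** — unique-read counting with UMI deduplication on
  (barcode, UMI, locus), then a support filter: an SNV is *effective* if it is
  backed by ≥ 20 unique reads and observed in ≥ 5 spots.
* **Normalized mutation burden** — per spot *i* with SNV count *sᵢ* and total
  mRNA UMI *U*: `Norm SNVᵢ = ln(sᵢ / U + 1)`, removing the dependence of
  apparent burden on sequencing depth.
* **SNV groups** — SNVs pooled into 100-kb genomic windows (`chrom@index`,
  index = pos // 100000); the spot × window matrix *M* is smoothed with
  Gaussian k-NN weights `W_ij = exp(−D_ij² / 2α²)` as `M_w = W·M`; the
  window–window spatial correlation `W_corr = M_wᵀ·M_w` (computed on each
  window's top-50% spots, cosine-normalized) feeds a directed graph whose
  Leiden communities (resolution ≈ 5) are spatially coordinated *SNV groups*.
* **Margin decay** — for each tumor-margin spot, the mean distance to its
  k = 5 nearest tumor spots; an OLS fit of ln(burden) on ln(distance) gives
  the decay exponent and R² (squared Pearson r).
* **Moran's I** — global spatial autocorrelation
  `I = (n/S₀)·Σ w_ij z_i z_j / Σ z_i²` for SNVs and SNV groups.
* **Neoantigen candidates** — for each exonic nonsynonymous SNV, the 15-aa
  flanks around the substituted residue are translated from the transcript
  CDS; every 8–15-mer covering the mutation is enumerated and filtered
  against all 8–15-mers of the normal proteome plus user-supplied healthy
  ligand lists; known-epitope membership is annotated, not filtered.
* **Synthetic data** — a fully manifested generator (tumor-disk/margin/normal
  lattice, lognormal depth, planted SNV groups, subclones, power-law margin
  decay, duplicate-laden read evidence, toy genome + GTF + CDS) so the whole
  pipeline runs and is testable offline.

The package is aimed at computational biologists analyzing Stereo-seq,
Visium or Slide-seq tumor sections who want mutation-level spatial structure
without re-sequencing DNA.

## Worked example

```sh
python examples/02_snv_groups.py
```

prints (seed 0):

```
310 effective SNVs -> 210 windows (labels like chr1@100)
Leiden at resolution 5: 44 SNV groups
adjusted Rand index vs 4 planted groups: 1.000
group 0: Moran's I 0.734 vs member median 0.296
group 1: Moran's I 0.580 vs member median 0.262
```

310 of 315 planted SNVs pass the effective filter (the 5 low-support decoys
are dropped); the four planted spatial groups are recovered exactly
(ARI = 1.0), and each group's pooled, UMI-normalized score is spatially far
more coherent (Moran's I ≈ 0.6–0.7) than its median member window (≈ 0.3) —
pooling a group averages out per-window Poisson noise.

The other examples cover effective-SNV calling and burden
(`01_effective_snvs.py`), margin distance decay (`03_margin_decay.py`; the
clean n=1000 simulation recovers a planted exponent −0.8 as slope −0.805,
R² 0.881), and mutant-peptide enumeration (`04_neoantigens.py`; an interior
substitution yields exactly 92 peptides, and a planted G12D-style change is
annotated as `G12D`).

## Command line

A thin CLI mirrors the library:

```sh
spotsnv simulate work/ --seed 2        # synthetic section + toy genome
spotsnv all work/ --seed 2             # matrix -> effective -> groups ->
                                          # margins -> neoantigen
```

Outputs are plain text (MTX bundles, TSV tables, FASTA, JSON summary); the
configuration used is saved beside them. Individual stages (`matrix`,
`effective`, `windows`, `margins`, `neoantigen`) run on an existing work
directory.

## Layout

```
src/spotsnv/
  io.py          readers/writers, evidence -> matrix, spot binning
  annotate.py    minimal GTF/CDS functional annotator
  effective.py   effective filter, binarize, normalize, differential SNVs
  windows.py     100-kb windows, smoothing, correlation, Leiden groups
  spatial.py     Moran's I, margin decay, signatures, correlations
  neoantigen.py  mutant-peptide contexts, enumeration, exclusion, export
  synthetic.py   manifested generators (section, margin decay, toy genome)
  pipeline.py    file-level stages; cli.py — the command line
```
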