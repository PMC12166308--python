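# Methods

## Scope and model

`spotsnv` quantifies somatic single-nucleotide variants in their tissue
context. The package assumes variant *calling* has already happened (a
Mutect2-style somatic VCF is consumed, records carrying any of the failure
tags `weak_evidence`, `germline`, `strand_bias`, `slippage`, `contamination`,
`panel_of_normals` are excluded, multiallelic records are split) and that the
caller's per-read evidence can be expressed as a TSV of
(read_id, barcode, UMI, chrom, pos, allele) rows. Alignment, base
recalibration and the caller's internals are out of scope, as are HLA typing
and binding-affinity prediction downstream of the exported peptides.

### Unique-read counting

Reads are deduplicated on the key (barcode, UMI, chrom, pos). Including the
locus in the key prevents collapsing two distinct variant loci that happen to
share a UMI in the same spot. After dedup, a read increments the
(spot, SNV) count only if its allele equals the SNV's alternative base;
reads matching the reference or a third base are discarded rather than
counted as reference, since a miscalled third base carries no evidence either
way. On lattice platforms, spots can be aggregated into `bin_size` ×
`bin_size` blocks (bin id = floor(coord / bin_size); counts and UMI are
summed, region labels carried by majority).

### Effective SNVs

An SNV is retained iff its total unique-read support is ≥ `min_unique_reads`
(default 20) **and** it occurs in ≥ `min_spots` spots (default 5). The filter
is idempotent and order-preserving. Both thresholds trade sensitivity against
the high per-spot error rate of transcriptome-derived variant calls.

### Normalization

The binary occurrence layer is divided by each spot's total mRNA UMI and
log-transformed: `ln(s/U + 1)`. The denominator is per-spot (not global):
depth varies by an order of magnitude across a section and is regionally
structured, so a global denominator would leave depth-driven artifacts in
the burden map. Natural log is used; the choice of base only rescales and
every monotone comparison is base-invariant. Normalization of raw (unbinarized)
counts is available by passing the raw layer. A spot with SNV signal but zero
total UMI is an error, not a silent zero.

### SNV windows and groups

SNVs are pooled into 100-kb windows, `index = pos // window_size` with
1-based positions, labeled `chrom@index`. Raw unique-read counts (not the
normalized layer) feed the window matrix: co-occurrence in space is the
signal of interest and depth affects all windows of a spot equally.

Smoothing: `M_w = W · M` with Gaussian k-NN weights
`W_ij = exp(−D_ij²/2α²)` for j among i's k nearest neighbors
(union-symmetrized) and `W_ii = 1`. α defaults to the section's mean k-NN
distance — the natural length scale of the array — and k defaults to 6
(first-ring neighbors on a square lattice, with the diagonal reached through
symmetrization). W is applied unnormalized by default; a row-normalized
variant (which leaves spatially constant columns unchanged) is a flag.

Correlation: each window is masked to the spots at or above the median
(`top_fraction` = 0.5) of its nonzero smoothed values — including zeros would
make the quantile degenerate for sparse windows — and the masked columns are
cosine-normalized before the product `W_corr = M̂_wᵀ·M̂_w`. The
normalization matters: raw dot products scale with each window's absolute
counts, so high-count windows would dominate every downstream weight
regardless of how well their spatial patterns actually match; the cosine
score is a genuine pattern correlation in [0, 1]. The unnormalized product
is available via `normalize=False`.

Graph: per window, the top 50% of positively correlated partners are kept
(ties at the cutoff included, which keeps the graph symmetric when rows are
identical). Edge weight is the correlation refined by a Gaussian decay of
the row-normalized score distance r = 1 − score/max_score:
`weight = score · exp(−r²/2·decay_alpha²)`, `decay_alpha` = 0.5. Carrying
the correlation magnitude in the weight is essential: a rank-decay-only
weight floors every kept edge at e^(−2) ≈ 0.135, which makes the graph
effectively dense and uniform, and community detection then collapses (see
*Numerical choices*).

Groups: Leiden on the union-symmetrized weighted graph
(RB-configuration quality, resolution 5.0, seeded), with groups relabeled
0..G−1 by decreasing internal weight. Group scores are
`ln(Σ_{w∈g} M[spot,w] / U_spot + 1)`. A window's *representative gene* is
the unique gene hit by its SNVs, or, among several candidates, the gene whose
expression correlates best (Pearson, across spots) with the window's count
vector; all-intergenic windows have none.

### Spatial statistics

Moran's I is computed directly:
`I = (n/S₀)·Σ_ij w_ij z_i z_j / Σ z_i²`, self-weights excluded, error on
constant input. It is exact against an O(n²) double loop, gives −1 on a rook
checkerboard, and its permutation-null mean is −1/(n−1). The Gaussian k-NN
weights are reused (with zeroed diagonal) as the default weight scheme.

Margin decay: for each margin-labeled spot, the mean Euclidean distance to
its k = 5 nearest tumor spots (KD-tree); OLS of ln(burden) on ln(distance);
spots with zero burden or distance are dropped and counted. R² is the
squared Pearson correlation, reported with slope and intercept. Binarization
saturates multi-read signal and any distance-flat background adds a floor
inside the log, so a full-section fit is attenuated toward zero relative to
the generating exponent; the clean per-spot simulation quantifies estimator
accuracy separately from those biological/technical floors.

Signature scores use the standard expression-binned control scheme (bin
genes by mean expression into 25 bins, sample 50 controls per signature gene,
score = mean(set) − mean(controls)), implemented directly so sparse matrices
and seeding behave uniformly; it tracks Scanpy's `score_genes` on planted
shifts. Burden–pathway association and the per-SNV tumor-region test are
plain Pearson and chi-square contingency wrappers.

### Differential SNVs

One-vs-rest Wilcoxon rank-sum on normalized values per group, log2 fold
change of group means with a 1e-9 pseudocount, Benjamini–Hochberg adjusted
p-values reported alongside. Defaults are lfc ≥ 1 and p < 0.5; the latter is
the screening threshold this method was published with and is deliberately
permissive — 0.05 is the conventional confirmatory choice, and the parameter
is exposed rather than silently changed. Constant SNVs report p = 1,
lfc = 0.

### Neoantigen candidates

For each nonsynonymous SNV the transcript CDS is translated (trimmed to the
longest whole-codon frame if needed, stopped at the first stop); the context
is 15 residues on each flank of the substituted position (31 aa interior;
clipped at protein bounds), with the alternative residue substituted at the
center. "15 surrounding" is read as per-flank: with 7 per side, centered
15-mers would be impossible, contradicting the 8–15 window range. Stopgain
substitutions truncate the context and yield no peptides through the
standard path. Enumeration produces every k-mer (8 ≤ k ≤ 15) covering the
center — exactly Σk = 92 for a full context — deduplicated by sequence with
offsets recorded. Exclusion is exact string membership against all 8–15-mers
of the reference proteome (translated CDS FASTA) plus optional
healthy-ligand lists; known-epitope lists only annotate. Database peptide
lists are consumed as local one-per-line text files; nothing is bundled or
downloaded.

## Synthetic data: what it emulates, and what it does not

`generate_section` (defaults: 50×50 lattice, seed-deterministic) plants:

* geometry — tumor disk (r ≤ 0.20 m), margin annulus (≤ 0.36 m), normal
  background; per-spot depth lognormal (σ = 0.5, ~10× spread), tumor 1.5×;
* four SNV groups × 25 windows × 2 SNVs on chr1, each group sharing a
  Gaussian spatial field (σ = 0.08 m) centered radially at 0.52 m — outside
  the margin annulus so group signal does not masquerade as margin decay —
  with Poisson rate 0.8 per SNV at the blob center over a 0.01 background;
* 30 margin SNVs on chr2, rate 0.2·(d/median d)^β confined to margin spots
  (β = −0.8 by default);
* two tumor subclones (20 SNVs each on chr5/chr6, rate 0.35) occupying the
  left and right halves of the tumor disk — the planted differential-SNV
  truth, and two further spatially coherent window communities;
* 40 depth-linked, spatially unstructured noise SNVs on chr3 and 5
  low-support SNVs on chr4 (expected ~2 reads) that must fail the effective
  filter;
* read evidence with a 30% PCR-duplicate rate and ~10% reference-supporting
  reads, exercising dedup and allele matching;
* an expression matrix with one gene tracking each group field, a
  tumor-enriched gene, and flat background genes.

`generate_toy_genome` builds two-exon genes on alternating strands with
planted variants covering every annotation class, including a
GGT→GAT codon-12 change (G12D), a third-position synonymous change, a
minus-strand R5H, and a protein-position-40 change whose context yields the
full 92-peptide sweep; expected regions, amino-acid changes and mutant
contexts are computed from the generator's own layout and stored in the
manifest.

What the generator does **not** emulate: 3′ capture bias (real poly(T)
platforms see mostly 3′-proximal SNVs), expression-dependent dropout beyond
a global depth link, doublets/segmentation error, CNV-driven allelic
imbalance, or realistic error profiles. Passing tests therefore demonstrate
the correctness and statistical behavior of the *method* under its stated
model, not calling performance on real tissue.

## Numerical choices

* Positions 1-based (VCF convention) throughout; intervals 1-based closed.
* The graph community structure obeys a sharp resolution bound: for a
  balanced g-community weighted graph, RB-modularity at resolution γ retains
  communities only if γ < g (the penalty/weight ratio is exactly γ/g). A
  desk-scale section must therefore carry more than five comparable
  spatially coherent window communities for the default resolution 5 to be
  meaningful — the default section has seven (4 groups, margin ring, 2
  subclones). On real sections with thousands of windows the bound is far
  from binding.
* Ties at the top-fraction cutoff are kept (symmetry under identical rows);
  Leiden is seeded and groups are relabeled deterministically by internal
  weight, so reruns are bit-identical.
* Quantile masking uses each window's nonzero smoothed values; windows with
  <2 nonzero spots correlate with nothing.
* The margin fit drops (and counts) zero-burden/zero-distance spots rather
  than adding a pseudocount inside the log.
* Degenerate inputs raise typed errors (constant feature for Moran's I,
  zero-UMI spot with signal, missing region labels) instead of returning
  NaN.

## Known limitations

* The annotator is deliberately minimal: one CDS per transcript, a fixed
  2-bp splice window, no multi-transcript reconciliation or splice-distance
  rules; a ref-mismatch yields exonic region with no effect call.
* Windows are fixed-width and genome-coordinate-aligned; no sliding overlap.
* The resolution bound above means very small sections (few windows) can
  over-fragment at resolution 5; lower the resolution or pool sections.
* Differential testing is one-vs-rest rank-sum only; no covariates, no
  spatial autocorrelation correction of p-values.
* Peptide exclusion is exact-match; near-identical self peptides (one
  substitution elsewhere) are not excluded, matching the published procedure.
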