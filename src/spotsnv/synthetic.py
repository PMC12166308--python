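"""Synthetic section and toy-genome generators with ground-truth
manifests.

The section generator emulates the data regimes of a tumor section
profiled by a spatial platform: an m x m spot lattice with a disk-shaped
tumor core, an annular margin and normal background; per-spot mRNA depth
varying over roughly an order of magnitude (lognormal); SNV counts drawn
Poisson with expression/depth-linked baselines; spatially coherent
planted SNV groups (Gaussian-blob fields shared by member windows);
margin SNVs whose rate decays as a power of the distance to the tumor
boundary; and a handful of low-support SNVs that must fail the
effective filter.  A per-read evidence table with a controllable
duplicate rate exercises UMI deduplication.

The toy-genome generator emits a small multi-gene genome (FASTA), its
annotation (GTF), CDS sequences and a planted variant list whose
expected regions, amino-acid changes and mutant-peptide contexts are
recorded in the manifest.  Everything is deterministic under a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import KDTree

from .io import write_expression_matrix
from .types import SNVCallSet, SNVRecord, SpotTable

DEFAULT_LATTICE = 50
DEFAULT_N_GROUPS = 4
DEFAULT_WINDOWS_PER_GROUP = 25
DEFAULT_SNVS_PER_WINDOW = 2
DEFAULT_BETA = -0.8
DEFAULT_DUPLICATE_RATE = 0.3

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# --------------------------------------------------------------------
# section generator
# --------------------------------------------------------------------

@dataclass
class SyntheticSection:
    spots: SpotTable
    snvs: SNVCallSet
    evidence: pd.DataFrame
    expression: sp.csr_matrix
    gene_names: List[str]
    truth: dict


def _region_labels(m: int) -> Tuple[np.ndarray, np.ndarray]:
    """Lattice coordinates and region labels: tumor disk (r <= 0.2 m),
    margin annulus (0.2 m < r <= 0.36 m), normal elsewhere."""
    xs, ys = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    center = (m - 1) / 2.0
    r = np.hypot(coords[:, 0] - center, coords[:, 1] - center)
    region = np.full(coords.shape[0], "normal", dtype=object)
    region[r <= 0.36 * m] = "margin"
    region[r <= 0.20 * m] = "tumor"
    return coords, region


def generate_section(
    m: int = DEFAULT_LATTICE,
    n_groups: int = DEFAULT_N_GROUPS,
    windows_per_group: int = DEFAULT_WINDOWS_PER_GROUP,
    snvs_per_window: int = DEFAULT_SNVS_PER_WINDOW,
    n_margin_snvs: int = 30,
    n_subclone_snvs: int = 20,
    n_noise_snvs: int = 40,
    n_rare_snvs: int = 5,
    beta: float = DEFAULT_BETA,
    duplicate_rate: float = DEFAULT_DUPLICATE_RATE,
    seed: int = 0,
) -> SyntheticSection:
    """Generate one synthetic section with a full ground-truth manifest.

    Planted structure:

    * ``n_groups`` SNV groups of ``windows_per_group`` 100-kb windows on
      chr1, each group sharing a Gaussian spatial field centered in one
      corner of the section (rate 0.8 per SNV at the blob center,
      background 0.01);
    * ``n_margin_snvs`` SNVs on chr2, one window each, expressed only in
      margin spots with Poisson rate 0.2 x (d / median d)^beta where d
      is the mean distance to the 5 nearest tumor spots;
    * two tumor subclones of ``n_subclone_snvs`` SNVs each (chr5/chr6),
      enriched in the left and right halves of the tumor disk — the
      planted differential-SNV fixture;
    * ``n_noise_snvs`` depth- and expression-linked diffuse SNVs on
      chr3 (spatially unstructured);
    * ``n_rare_snvs`` low-support SNVs on chr4 (expected total support
      ~2 reads) that must fail the effective filter.
    """
    rng = np.random.default_rng(seed)
    coords, region = _region_labels(m)
    n = coords.shape[0]
    center = (m - 1) / 2.0

    # per-spot depth: lognormal, ~1 order of magnitude spread; tumor 1.5x
    umi = rng.lognormal(mean=np.log(2000.0), sigma=0.5, size=n)
    umi = umi * np.where(region == "tumor", 1.5, 1.0)
    umi = np.maximum(1, np.round(umi)).astype(int)
    depth_factor = umi / umi.mean()

    spots = SpotTable(
        pd.DataFrame(
            {
                "barcode": [f"s{x:03d}_{y:03d}" for x, y in coords.astype(int)],
                "x": coords[:, 0].astype(int),
                "y": coords[:, 1].astype(int),
                "total_umi": umi,
                "region": region,
            }
        )
    )

    # group spatial fields: Gaussian blobs toward the section corners,
    # radially outside the margin annulus
    angles = 2 * np.pi * (np.arange(n_groups) + 0.5) / n_groups
    blob_centers = np.column_stack(
        [center + 0.52 * m * np.cos(angles),
         center + 0.52 * m * np.sin(angles)]
    )
    sigma_blob = 0.08 * m
    fields = np.stack(
        [
            np.exp(
                -((coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2)
                / (2 * sigma_blob**2)
            )
            for cx, cy in blob_centers
        ]
    )  # n_groups x n

    # margin distance (mean to 5 nearest tumor spots)
    tumor_xy = coords[region == "tumor"]
    margin_mask = region == "margin"
    d_margin, _ = KDTree(tumor_xy).query(coords[margin_mask], k=5)
    d_margin = d_margin.mean(axis=1)
    d_med = float(np.median(d_margin))

    records: List[SNVRecord] = []
    rates: List[np.ndarray] = []
    group_windows: Dict[str, int] = {}
    margin_ids: List[str] = []
    noise_ids: List[str] = []
    rare_ids: List[str] = []

    refalt = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]

    for g in range(n_groups):
        for w in range(windows_per_group):
            widx = 100 + g * windows_per_group + w
            group_windows[f"chr1@{widx}"] = g
            for s in range(snvs_per_window):
                pos = widx * 100_000 + 1_000 + s * 997
                ref, alt = refalt[(g + w + s) % 4]
                records.append(SNVRecord(chrom="chr1", pos=pos, ref=ref, alt=alt))
                rates.append(0.8 * fields[g] + 0.01)

    margin_rate = np.zeros(n)
    margin_rate[margin_mask] = 0.2 * (d_margin / d_med) ** beta
    for i in range(n_margin_snvs):
        pos = i * 100_000 + 5_000
        ref, alt = refalt[i % 4]
        rec = SNVRecord(chrom="chr2", pos=pos, ref=ref, alt=alt)
        records.append(rec)
        margin_ids.append(rec.snv_id)
        rates.append(margin_rate.copy())

    # two spatial tumor subclones: left / right half of the tumor disk
    subclone_ids: Dict[str, List[str]] = {"A": [], "B": []}
    tumor_mask = region == "tumor"
    half = {
        "A": tumor_mask & (coords[:, 0] <= center),
        "B": tumor_mask & (coords[:, 0] > center),
    }
    for label, chrom in (("A", "chr5"), ("B", "chr6")):
        field_sc = half[label].astype(float)
        for i in range(n_subclone_snvs):
            pos = i * 100_000 + 3_000
            ref, alt = refalt[(i + 3) % 4]
            rec = SNVRecord(chrom=chrom, pos=pos, ref=ref, alt=alt)
            records.append(rec)
            subclone_ids[label].append(rec.snv_id)
            rates.append(0.35 * field_sc + 0.005)

    # expression-linked diffuse noise: per-SNV lognormal baseline times depth
    for i in range(n_noise_snvs):
        pos = i * 100_000 + 7_000
        ref, alt = refalt[(i + 1) % 4]
        rec = SNVRecord(chrom="chr3", pos=pos, ref=ref, alt=alt)
        records.append(rec)
        noise_ids.append(rec.snv_id)
        base = rng.lognormal(mean=np.log(0.04), sigma=0.4)
        rates.append(base * depth_factor)

    for i in range(n_rare_snvs):
        pos = i * 100_000 + 9_000
        ref, alt = refalt[(i + 2) % 4]
        rec = SNVRecord(chrom="chr4", pos=pos, ref=ref, alt=alt)
        records.append(rec)
        rare_ids.append(rec.snv_id)
        rates.append(np.full(n, 2.0 / n))

    snvs = SNVCallSet(records)
    counts = np.column_stack([rng.poisson(r) for r in rates])

    evidence = _synthesize_evidence(counts, spots, snvs, duplicate_rate, rng)

    # expression: one gene tracking each group field, plus flat background
    gene_names = [f"GENE_G{g}" for g in range(n_groups)]
    gene_rates = [0.5 + 5.0 * fields[g] for g in range(n_groups)]
    tumor_field = (region == "tumor").astype(float)
    gene_names.append("SIG_TUMOR")
    gene_rates.append(0.5 + 4.0 * tumor_field)
    for b in range(15):
        gene_names.append(f"BG{b:02d}")
        gene_rates.append(np.full(n, float(rng.lognormal(np.log(1.0), 0.4))))
    expression = sp.csr_matrix(
        np.column_stack([rng.poisson(r * depth_factor) for r in gene_rates])
    )

    truth = {
        "m": m,
        "seed": seed,
        "beta": beta,
        "n_groups": n_groups,
        "group_windows": group_windows,
        "group_snv_ids": [
            r.snv_id for r in records if r.chrom == "chr1"
        ],
        "margin_snv_ids": margin_ids,
        "subclone_snv_ids": subclone_ids,
        "noise_snv_ids": noise_ids,
        "rare_snv_ids": rare_ids,
        "duplicate_rate": duplicate_rate,
    }
    return SyntheticSection(
        spots=spots, snvs=snvs, evidence=evidence,
        expression=expression, gene_names=gene_names, truth=truth,
    )


def _synthesize_evidence(
    counts: np.ndarray,
    spots: SpotTable,
    snvs: SNVCallSet,
    duplicate_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-read evidence rows realizing the count matrix: one unique
    (barcode, UMI) read per count, duplicated with probability
    ``duplicate_rate``; ~10% extra reference-allele reads that must not
    be counted."""
    barcodes = spots.barcodes.to_numpy()
    rows: List[tuple] = []
    read_no = 0
    spot_idx, snv_idx = np.nonzero(counts)
    for i, j in zip(spot_idx, snv_idx):
        rec = snvs[int(j)]
        for t in range(counts[i, j]):
            umi = f"u{i}_{j}_{t}"
            rows.append(
                (f"r{read_no}", barcodes[i], umi, rec.chrom, rec.pos, rec.alt)
            )
            read_no += 1
            if rng.random() < duplicate_rate:  # PCR duplicate
                rows.append(
                    (f"r{read_no}", barcodes[i], umi, rec.chrom, rec.pos, rec.alt)
                )
                read_no += 1
            if rng.random() < 0.1:  # reference-supporting read
                rows.append(
                    (
                        f"r{read_no}", barcodes[i], f"ref_{umi}",
                        rec.chrom, rec.pos, rec.ref,
                    )
                )
                read_no += 1
    return pd.DataFrame(
        rows, columns=["read_id", "barcode", "umi", "chrom", "pos", "allele"]
    )


def simulate_margin_decay(
    n: int = 1000,
    beta: float = DEFAULT_BETA,
    sigma: float = 0.2,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Margin-spot (distance, burden) pairs with a planted power-law
    decay: burden = 0.01 * d^beta * exp(N(0, sigma^2)), d uniform on
    [1, 20]."""
    rng = np.random.default_rng(seed)
    d = rng.uniform(1.0, 20.0, size=n)
    burden = 0.01 * d**beta * np.exp(rng.normal(0.0, sigma, size=n))
    return d, burden


# --------------------------------------------------------------------
# VCF / file output
# --------------------------------------------------------------------

#: decoy records carrying Mutect2 failure tags, written alongside the
#: planted SNVs so the VCF filter has something to exclude
_DECOY_TAGS = [
    "weak_evidence", "germline", "strand_bias",
    "slippage", "contamination", "panel_of_normals",
    "weak_evidence;strand_bias",
]


def write_vcf(path, snvs: SNVCallSet, decoys: bool = True) -> None:
    """Write planted SNVs as a PASS-only VCF, optionally appending decoy
    records carrying each excluded FILTER tag."""
    chroms = sorted({r.chrom for r in snvs}, key=lambda c: (len(c), c))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for tag in set(";".join(_DECOY_TAGS).split(";")):
            fh.write(f'##FILTER=<ID={tag},Description="failed">\n')
        fh.write('##FILTER=<ID=clustered_events,Description="kept">\n')
        for c in chroms + ["chr99"]:
            fh.write(f"##contig=<ID={c},length=100000000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in sorted(snvs, key=lambda r: (r.chrom, r.pos)):
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\n"
            )
        if decoys:
            for i, tag in enumerate(_DECOY_TAGS):
                fh.write(f"chr99\t{1000 + i * 10}\t.\tA\tC\t.\t{tag}\t.\n")
            # a non-excluded failure tag: must be retained by the filter
            fh.write("chr99\t2000\t.\tG\tT\t.\tclustered_events\t.\n")


def write_section(section: SyntheticSection, outdir) -> None:
    """Write a section to disk in exactly the formats the readers
    consume: spots.tsv, evidence.tsv, snvs.vcf, an MTX expression bundle
    and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    section.spots.write_tsv(outdir / "spots.tsv")
    section.evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    write_vcf(outdir / "snvs.vcf", section.snvs)
    write_expression_matrix(
        outdir / "expression", section.expression,
        list(section.spots.barcodes), section.gene_names,
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(section.truth, fh, indent=1)


# --------------------------------------------------------------------
# toy genome generator
# --------------------------------------------------------------------

@dataclass
class ToyGenome:
    genome: Dict[str, str]  # chrom -> sequence
    gtf: pd.DataFrame
    cds: Dict[str, str]  # transcript id -> CDS (transcript orientation)
    proteins: Dict[str, str]
    variants: SNVCallSet
    expected: pd.DataFrame  # per-variant truth
    truth: dict


_SAFE_CODONS = [
    "GCT", "GCC", "CGT", "AAT", "GAT", "TGT", "CAA", "GAA", "GGT", "CAT",
    "ATT", "AAA", "CTG", "ATG", "TTT", "CCT", "TCT", "ACT", "TGG", "TAT",
    "GTT", "AGC", "ACC", "CTC",
]

def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).translate())


@dataclass
class _GeneLayout:
    gene: str
    tid: str
    chrom: str
    strand: str
    start: int  # 1-based genomic start of the gene span
    utr5_len: int
    cds1_len: int
    intron_len: int
    cds_len: int
    utr3_len: int

    @property
    def total_len(self) -> int:
        return self.utr5_len + self.cds_len + self.intron_len + self.utr3_len

    def genomic_pos_of_cds_offset(self, offset: int) -> int:
        """1-based genomic position of 0-based CDS offset."""
        t = self.utr5_len + offset  # position in transcript (pre-splice
        # coordinates need the intron inserted between cds1 and cds2)
        if offset >= self.cds1_len:
            t += self.intron_len
        if self.strand == "+":
            return self.start + t
        return self.start + self.total_len - 1 - t

    def transcript_intervals(self) -> Dict[str, List[Tuple[int, int]]]:
        """1-based closed genomic intervals for utr5/cds/intron/utr3/exons."""
        # pre-mRNA order: utr5, cds1, intron, cds2, utr3
        lens = [
            ("utr5", self.utr5_len),
            ("cds1", self.cds1_len),
            ("intron", self.intron_len),
            ("cds2", self.cds_len - self.cds1_len),
            ("utr3", self.utr3_len),
        ]
        out: Dict[str, List[Tuple[int, int]]] = {}
        if self.strand == "+":
            cur = self.start
            for name, ln in lens:
                out[name] = [(cur, cur + ln - 1)]
                cur += ln
        else:
            cur = self.start + self.total_len - 1
            for name, ln in lens:
                out[name] = [(cur - ln + 1, cur)]
                cur -= ln
        exons = []
        for a in ("utr5", "cds1"):
            exons.extend(out[a])
        ex1 = (min(s for s, _ in exons), max(e for _, e in exons))
        exons = []
        for a in ("cds2", "utr3"):
            exons.extend(out[a])
        ex2 = (min(s for s, _ in exons), max(e for _, e in exons))
        out["exons"] = sorted([ex1, ex2])
        out["cds"] = sorted(out["cds1"] + out["cds2"])
        return out


def generate_toy_genome(n_genes: int = 10, seed: int = 0) -> ToyGenome:
    """A small genome of ``n_genes`` two-exon protein-coding genes on
    alternating strands, with planted variants covering every annotation
    class.

    Planted coding variants (all on the first three genes) include a
    G12D-style nonsynonymous change, a third-position synonymous change,
    a substitution at protein position 40 (whose full 31-aa context
    yields the complete 8-15-mer sweep) and a minus-strand
    nonsynonymous change; UTR5/UTR3/intronic/splicing/intergenic
    variants are planted around the first gene.
    """
    rng = np.random.default_rng(seed)
    n_codons = 60
    utr_len, intron_len, gap = 24, 60, 200

    genome_parts: List[str] = []
    gtf_rows: List[dict] = []
    cds_map: Dict[str, str] = {}
    layouts: List[_GeneLayout] = []
    cursor = 0  # 0-based length so far
    chrom = "chrT"

    for gi in range(n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        gene, tid = f"TG{gi}", f"TG{gi}.t1"
        codons = ["ATG"] + [
            _SAFE_CODONS[int(rng.integers(len(_SAFE_CODONS)))]
            for _ in range(n_codons - 1)
        ] + ["TAA"]
        if gi == 0:
            codons[11] = "GGT"  # protein position 12
        if gi == 1:
            codons[4] = "CGT"  # protein position 5, minus strand
        if gi == 2:
            codons[39] = "AAA"  # protein position 40
        cds = "".join(codons)
        utr5 = "".join(rng.choice(list("ACGT"), size=utr_len))
        utr3 = "".join(rng.choice(list("ACGT"), size=utr_len))
        intron = "GT" + "".join(rng.choice(list("ACGT"), size=intron_len - 4)) + "AG"
        cds1_len = (len(cds) // 2) // 3 * 3  # split between codons
        pre = utr5 + cds[:cds1_len] + intron + cds[cds1_len:] + utr3

        gene_start = cursor + gap + 1  # 1-based
        layout = _GeneLayout(
            gene=gene, tid=tid, chrom=chrom, strand=strand,
            start=gene_start, utr5_len=utr_len, cds1_len=cds1_len,
            intron_len=intron_len, cds_len=len(cds), utr3_len=utr_len,
        )
        genomic = pre if strand == "+" else _revcomp(pre)
        genome_parts.append("".join(rng.choice(list("ACGT"), size=gap)))
        genome_parts.append(genomic)
        cursor = gene_start + layout.total_len - 1

        iv = layout.transcript_intervals()
        attrs = (
            f'gene_id "{gene}"; transcript_id "{tid}"; gene_name "{gene}"; '
            f'gene_biotype "protein_coding";'
        )
        for s, e in iv["exons"]:
            gtf_rows.append(dict(feature="exon", start=s, end=e))
        for s, e in iv["cds"]:
            gtf_rows.append(dict(feature="CDS", start=s, end=e))
        for s, e in iv["utr5"]:
            gtf_rows.append(dict(feature="five_prime_utr", start=s, end=e))
        for s, e in iv["utr3"]:
            gtf_rows.append(dict(feature="three_prime_utr", start=s, end=e))
        for row in gtf_rows[-6:]:
            row.update(chrom=chrom, strand=strand, attrs=attrs)
        cds_map[tid] = cds
        layouts.append(layout)

    genome_parts.append("".join(rng.choice(list("ACGT"), size=gap)))
    genome = {chrom: "".join(genome_parts)}
    gtf = pd.DataFrame(gtf_rows)
    proteins = {tid: _translate(s)[:-1] for tid, s in cds_map.items()}

    # ---- planted variants with hand-derivable expectations ----
    variants: List[SNVRecord] = []
    expected_rows: List[dict] = []

    def plant_coding(layout: _GeneLayout, cds_offset: int, alt_cds_base: str, note: str):
        cds = cds_map[layout.tid]
        ref_cds = cds[cds_offset]
        pos = layout.genomic_pos_of_cds_offset(cds_offset)
        if layout.strand == "+":
            ref_g, alt_g = ref_cds, alt_cds_base
        else:
            ref_g = ref_cds.translate(_COMPLEMENT)
            alt_g = alt_cds_base.translate(_COMPLEMENT)
        ci = cds_offset // 3
        codon = cds[3 * ci: 3 * ci + 3]
        mut = codon[: cds_offset % 3] + alt_cds_base + codon[cds_offset % 3 + 1:]
        ref_aa, alt_aa = _translate(codon), _translate(mut)
        if alt_aa == ref_aa:
            effect = "synonymous"
        elif alt_aa == "*":
            effect = "stopgain"
        else:
            effect = "nonsynonymous"
        rec = SNVRecord(chrom=layout.chrom, pos=pos, ref=ref_g, alt=alt_g)
        variants.append(rec)
        protein = proteins[layout.tid]
        ctx = None
        if effect == "nonsynonymous":
            lo = max(0, ci - 15)
            hi = min(len(protein), ci + 16)
            wt = protein[lo:hi]
            ctx = wt[: ci - lo] + alt_aa + wt[ci - lo + 1:]
        expected_rows.append(
            dict(
                snv_id=rec.snv_id, note=note, region="exonic", effect=effect,
                gene=layout.gene, aa_change=f"{ref_aa}{ci + 1}{alt_aa}",
                mut_context=ctx,
                center_index=(ci - max(0, ci - 15)) if ctx else None,
            )
        )

    g0, g1, g2 = layouts[0], layouts[1], layouts[2]
    plant_coding(g0, 34, "A", "G12D-style GGT>GAT")      # codon 12 pos 2
    plant_coding(g0, 35, "C", "synonymous GGT>GGC")      # codon 12 pos 3
    plant_coding(g1, 13, "A", "minus-strand CGT>CAT R5H")  # codon 5 pos 2
    plant_coding(g2, 117, "G", "K40E full-context")       # codon 40 pos 1

    def plant_noncoding(pos: int, region: str, note: str, gene=None):
        base = genome[chrom][pos - 1]
        alt = "A" if base != "A" else "G"
        rec = SNVRecord(chrom=chrom, pos=pos, ref=base, alt=alt)
        variants.append(rec)
        expected_rows.append(
            dict(
                snv_id=rec.snv_id, note=note, region=region, effect=None,
                gene=gene, aa_change=None, mut_context=None, center_index=None,
            )
        )

    iv0 = g0.transcript_intervals()
    plant_noncoding(iv0["utr5"][0][0] + 3, "UTR5", "gene0 5'UTR", g0.gene)
    plant_noncoding(iv0["utr3"][0][0] + 3, "UTR3", "gene0 3'UTR", g0.gene)
    intron_iv = iv0["intron"][0]
    mid = (intron_iv[0] + intron_iv[1]) // 2
    plant_noncoding(mid, "intronic", "gene0 intron middle", g0.gene)
    plant_noncoding(intron_iv[0] + 1, "splicing", "gene0 donor+2", g0.gene)
    plant_noncoding(100, "intergenic", "upstream gap")

    expected = pd.DataFrame(expected_rows)
    truth = {"n_genes": n_genes, "seed": seed, "chrom": chrom}
    return ToyGenome(
        genome=genome, gtf=gtf, cds=cds_map, proteins=proteins,
        variants=SNVCallSet(variants), expected=expected, truth=truth,
    )


def write_toy_genome(toy: ToyGenome, outdir) -> None:
    """Write genome.fa, genes.gtf, cds.fa, variants.vcf and the expected
    annotation table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in toy.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(outdir / "cds.fa", "w") as fh:
        for tid, seq in toy.cds.items():
            fh.write(f">{tid}\n{seq}\n")
    with open(outdir / "genes.gtf", "w") as fh:
        for row in toy.gtf.itertuples(index=False):
            fh.write(
                f"{row.chrom}\ttoy\t{row.feature}\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{row.attrs}\n"
            )
    write_vcf(outdir / "variants.vcf", toy.variants, decoys=False)
    toy.expected.to_csv(outdir / "expected_annotation.tsv", sep="\t", index=False)
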