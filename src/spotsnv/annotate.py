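"""Minimal functional annotation of SNVs against a GTF and CDS FASTA.

Assigns each variant a genomic region by interval-overlap precedence
(exonic > UTR5/UTR3 > splicing > intronic > ncRNA > intergenic) and, for
coding variants, derives the amino-acid change from the transcript CDS
using the standard genetic code.  Minus-strand codons are read off the
reverse complement.  This is a deliberately small annotator: it handles
one CDS per transcript, a fixed 2-bp splice window, and no multi-
transcript reconciliation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .types import FormatError, SNVCallSet, SNVRecord

logger = logging.getLogger(__name__)

SPLICE_WINDOW = 2  # bp into the intron counted as splicing

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

GTF_COLUMNS = [
    "chrom", "source", "feature", "start", "end",
    "score", "strand", "frame", "attributes",
]


def _parse_attributes(s: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(s))


@dataclass
class TranscriptModel:
    transcript_id: str
    gene: str
    chrom: str
    strand: str
    coding: bool
    exons: List[Tuple[int, int]]  # 1-based closed, sorted by start
    cds: List[Tuple[int, int]]
    utr5: List[Tuple[int, int]]
    utr3: List[Tuple[int, int]]

    def cds_offset(self, pos: int) -> Optional[int]:
        """0-based offset of genomic ``pos`` within the spliced CDS, in
        transcript orientation; None if pos is outside the CDS."""
        blocks = self.cds
        hit = None
        for b in blocks:
            if b[0] <= pos <= b[1]:
                hit = b
                break
        if hit is None:
            return None
        if self.strand == "+":
            prior = sum(e - s + 1 for s, e in blocks if e < hit[0])
            return prior + (pos - hit[0])
        prior = sum(e - s + 1 for s, e in blocks if s > hit[1])
        return prior + (hit[1] - pos)


def read_gtf(path) -> List[TranscriptModel]:
    """Parse transcript models from a GTF (1-based closed intervals)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GTF_COLUMNS,
        dtype={"chrom": str},
    )
    if df.empty:
        return []
    models: Dict[str, TranscriptModel] = {}
    for row in df.itertuples(index=False):
        attrs = _parse_attributes(row.attributes)
        tid = attrs.get("transcript_id")
        if tid is None:
            continue
        gene = attrs.get("gene_name", attrs.get("gene_id", tid))
        biotype = attrs.get("gene_biotype", attrs.get("transcript_biotype", "protein_coding"))
        m = models.get(tid)
        if m is None:
            m = TranscriptModel(
                transcript_id=tid, gene=gene, chrom=row.chrom,
                strand=row.strand, coding=(biotype == "protein_coding"),
                exons=[], cds=[], utr5=[], utr3=[],
            )
            models[tid] = m
        iv = (int(row.start), int(row.end))
        feat = row.feature.lower()
        if feat == "exon":
            m.exons.append(iv)
        elif feat == "cds":
            m.cds.append(iv)
        elif feat in ("five_prime_utr", "5utr"):
            m.utr5.append(iv)
        elif feat in ("three_prime_utr", "3utr"):
            m.utr3.append(iv)
    for m in models.values():
        for lst in (m.exons, m.cds, m.utr5, m.utr3):
            lst.sort()
    return list(models.values())


def read_cds_fasta(path) -> Dict[str, str]:
    """CDS sequences keyed by transcript id, in transcript orientation."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _classify_coding(
    rec: SNVRecord, model: TranscriptModel, cds_seq: str
) -> SNVRecord:
    offset = model.cds_offset(rec.pos)
    if offset is None or offset >= len(cds_seq):
        return replace(
            rec, genomic_region="exonic", gene=model.gene,
            transcript=model.transcript_id,
        )
    ref_base = rec.ref if model.strand == "+" else rec.ref.translate(_COMPLEMENT)
    alt_base = rec.alt if model.strand == "+" else rec.alt.translate(_COMPLEMENT)
    if cds_seq[offset] != ref_base:
        logger.warning(
            "ref base mismatch at %s:%d (%s vs CDS %s of %s); effect left unset",
            rec.chrom, rec.pos, ref_base, cds_seq[offset], model.transcript_id,
        )
        return replace(
            rec, genomic_region="exonic", gene=model.gene,
            transcript=model.transcript_id, effect=None,
        )
    codon_index = offset // 3
    within = offset % 3
    codon = cds_seq[3 * codon_index: 3 * codon_index + 3]
    if len(codon) < 3:
        return replace(rec, genomic_region="exonic", gene=model.gene)
    mut_codon = codon[:within] + alt_base + codon[within + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mut_codon).translate())
    if alt_aa == ref_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "stopgain"
    elif ref_aa == "*":
        effect = "other"
    else:
        effect = "nonsynonymous"
    return replace(
        rec, genomic_region="exonic", gene=model.gene,
        transcript=model.transcript_id, effect=effect,
        aa_change=(model.gene, ref_aa, codon_index + 1, alt_aa),
    )


def _locate_in_transcript(pos: int, m: TranscriptModel) -> Optional[str]:
    """Region of pos within one transcript, or None if outside its span."""
    span = (m.exons or m.cds)
    if not span:
        return None
    tx_start, tx_end = span[0][0], span[-1][1]
    if not (tx_start <= pos <= tx_end):
        return None
    if any(s <= pos <= e for s, e in m.cds):
        return "exonic"
    if any(s <= pos <= e for s, e in m.utr5):
        return "UTR5"
    if any(s <= pos <= e for s, e in m.utr3):
        return "UTR3"
    in_exon = any(s <= pos <= e for s, e in m.exons)
    if in_exon:
        return "exonic" if m.coding else "ncRNA"
    # intronic; splicing if within SPLICE_WINDOW of an exon boundary
    for s, e in m.exons:
        if 0 < s - pos <= SPLICE_WINDOW or 0 < pos - e <= SPLICE_WINDOW:
            return "splicing"
    return "intronic" if m.coding else "ncRNA"


_PRECEDENCE = ["exonic", "UTR5", "UTR3", "splicing", "intronic", "ncRNA"]


def annotate_snvs(snvs: SNVCallSet, gtf_path, cds_path) -> SNVCallSet:
    """Annotate each SNV with a genomic region and, when exonic in a
    coding transcript, the amino-acid effect of the substitution."""
    models = read_gtf(gtf_path)
    cds_seqs = read_cds_fasta(cds_path)

    trees: Dict[str, IntervalTree] = {}
    for i, m in enumerate(models):
        span = m.exons or m.cds
        if not span:
            continue
        trees.setdefault(m.chrom, IntervalTree()).addi(
            span[0][0], span[-1][1] + 1, i
        )

    out = []
    for rec in snvs:
        tree = trees.get(rec.chrom)
        hits = sorted(iv.data for iv in tree[rec.pos]) if tree is not None else []
        if not hits:
            out.append(replace(rec, genomic_region="intergenic"))
            continue
        best_region = None
        best_model = None
        for i in hits:
            region = _locate_in_transcript(rec.pos, models[i])
            if region is None:
                continue
            if best_region is None or _PRECEDENCE.index(region) < _PRECEDENCE.index(best_region):
                best_region = region
                best_model = models[i]
        if best_region is None:
            out.append(replace(rec, genomic_region="intergenic"))
        elif best_region == "exonic" and best_model.coding and best_model.cds:
            seq = cds_seqs.get(best_model.transcript_id)
            if seq is None:
                logger.warning(
                    "no CDS sequence for %s; region only", best_model.transcript_id
                )
                out.append(replace(
                    rec, genomic_region="exonic", gene=best_model.gene,
                    transcript=best_model.transcript_id,
                ))
            else:
                out.append(_classify_coding(rec, best_model, seq))
        else:
            out.append(replace(
                rec, genomic_region=best_region, gene=best_model.gene,
                transcript=best_model.transcript_id,
            ))
    return SNVCallSet(out)
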