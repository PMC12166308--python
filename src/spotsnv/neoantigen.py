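"""Mutant-peptide construction from exonic nonsynonymous SNVs.

For each nonsynonymous substitution the translated CDS yields a
wild-type amino-acid context of up to 15 residues on each flank of the
mutated site (31 aa for an interior site).  A sliding window enumerates
every 8-15-mer covering the substituted residue; peptides that occur
anywhere in the normal proteome (all 8-15-mers of the reference CDS
translations) or in user-supplied healthy-ligand lists are excluded.
Membership in known-epitope lists is annotated but does not drop a
peptide.  Surviving candidates are exported as FASTA + TSV for external
HLA typing and binding-affinity tools.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set

import pandas as pd
from Bio.Seq import Seq

from .annotate import read_cds_fasta
from .types import MutantContext, PeptideCandidate, SNVRecord

logger = logging.getLogger(__name__)

FLANK = 15  # residues kept on each side of the mutated site
KMIN, KMAX = 8, 15


def translate_cds(cds_seq: str) -> str:
    """Translate a CDS, trimming to the longest valid frame if its
    length is not a multiple of 3, and stopping at the first stop."""
    usable = len(cds_seq) - len(cds_seq) % 3
    if usable < len(cds_seq):
        logger.warning("CDS length %d not divisible by 3; trimmed", len(cds_seq))
    prot = str(Seq(cds_seq[:usable]).translate())
    stop = prot.find("*")
    return prot if stop == -1 else prot[:stop]


def extract_context(
    snv: SNVRecord, cds_seqs: Dict[str, str], flank: int = FLANK
) -> MutantContext:
    """Amino-acid context around a nonsynonymous (or stopgain) SNV.

    The wild-type protein is translated from the transcript CDS; the
    context spans ``flank`` residues each side of the mutated position,
    clipped at the protein bounds.  Stopgain substitutions truncate the
    mutant context at the new stop and are flagged.
    """
    if snv.effect not in ("nonsynonymous", "stopgain"):
        raise ValueError(f"SNV {snv.snv_id} effect is {snv.effect!r}; need a coding change")
    if snv.aa_change is None or snv.transcript is None:
        raise ValueError(f"SNV {snv.snv_id} lacks amino-acid annotation")
    gene, ref_aa, protein_pos, alt_aa = snv.aa_change
    cds = cds_seqs.get(snv.transcript)
    if cds is None:
        raise KeyError(f"no CDS sequence for transcript {snv.transcript}")
    protein = translate_cds(cds)
    center = protein_pos - 1  # aa positions are 1-based
    if center >= len(protein) or protein[center] != ref_aa:
        raise ValueError(
            f"annotated ref residue {ref_aa}{protein_pos} disagrees with "
            f"translated CDS of {snv.transcript}"
        )
    lo = max(0, center - flank)
    hi = min(len(protein), center + flank + 1)
    wt = protein[lo:hi]
    center_index = center - lo
    truncated = False
    if alt_aa == "*":
        mut = wt[:center_index]
        truncated = True
        # a stop at the mutated site removes it and everything after;
        # keep the wt alignment by storing the truncated pair
        wt = wt[: center_index + 1]
        mut = mut + "*"  # placeholder differing at center
    else:
        mut = wt[:center_index] + alt_aa + wt[center_index + 1:]
    return MutantContext(
        snv=snv, wt_context=wt, mut_context=mut,
        center_index=center_index, truncated_by_stop=truncated,
    )


def enumerate_peptides(
    context: MutantContext, kmin: int = KMIN, kmax: int = KMAX
) -> List[PeptideCandidate]:
    """All distinct k-mers (kmin <= k <= kmax) of the mutant context
    that cover the substituted residue.

    Stop-truncated contexts yield nothing (the mutant residue is a
    stop).  Sequence-identical windows from distinct offsets collapse to
    one candidate with all offsets recorded.
    """
    if context.truncated_by_stop:
        return []
    seqs: Dict[str, List[int]] = {}
    m = context.mut_context
    c = context.center_index
    for k in range(kmin, kmax + 1):
        for start in range(max(0, c - k + 1), min(len(m) - k, c) + 1):
            seqs.setdefault(m[start:start + k], []).append(start)
    return [
        PeptideCandidate(
            sequence=s,
            snv_id=context.snv.snv_id,
            gene=context.snv.gene,
            start_offsets=offs,
        )
        for s, offs in sorted(seqs.items())
    ]


class ExclusionIndex:
    """Membership index over all 8-15-mers of a normal proteome plus
    optional healthy-ligand peptide lists."""

    def __init__(self, proteome_kmers: Set[str], ligand_peptides: Set[str]):
        self._proteome = proteome_kmers
        self._ligands = ligand_peptides

    def in_proteome(self, peptide: str) -> bool:
        return peptide in self._proteome

    def in_ligandome(self, peptide: str) -> bool:
        return peptide in self._ligands

    def __contains__(self, peptide: str) -> bool:
        return self.in_proteome(peptide) or self.in_ligandome(peptide)


def _kmers(protein: str, kmin: int, kmax: int) -> Iterable[str]:
    for k in range(kmin, kmax + 1):
        for i in range(len(protein) - k + 1):
            yield protein[i:i + k]


def read_peptide_list(path) -> Set[str]:
    """One peptide per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            pep = line.strip()
            if pep and not pep.startswith("#"):
                out.add(pep.upper())
    return out


def build_exclusion_index(
    cds_path, extra_peptide_lists: Sequence = (), kmin: int = KMIN, kmax: int = KMAX
) -> ExclusionIndex:
    """Index every 8-15-mer of the reference proteome (translated CDS
    FASTA) together with peptides from healthy-ligand lists."""
    kmers: Set[str] = set()
    for tid, cds in read_cds_fasta(cds_path).items():
        protein = translate_cds(cds)
        kmers.update(_kmers(protein, kmin, kmax))
    ligands: Set[str] = set()
    for path in extra_peptide_lists:
        ligands |= read_peptide_list(path)
    return ExclusionIndex(kmers, ligands)


def filter_candidates(
    peptides: Sequence[PeptideCandidate],
    index: ExclusionIndex,
    known_epitope_lists: Sequence = (),
) -> pd.DataFrame:
    """Drop peptides found in the normal proteome or healthy ligandome;
    annotate (without dropping) membership in known-epitope lists.

    Returns the surviving candidates sorted by gene then sequence.
    """
    known: Set[str] = set()
    for path in known_epitope_lists:
        known |= read_peptide_list(path)
    rows = []
    for pep in peptides:
        pep.in_normal_proteome = index.in_proteome(pep.sequence)
        pep.in_healthy_ligandome = index.in_ligandome(pep.sequence)
        pep.in_known_epitope_db = pep.sequence in known
        if not pep.is_candidate:
            continue
        rows.append(
            dict(
                gene=pep.gene or "",
                sequence=pep.sequence,
                snv_id=pep.snv_id,
                start_offsets=",".join(map(str, pep.start_offsets)),
                in_known_epitope_db=pep.in_known_epitope_db,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["gene", "sequence", "snv_id", "start_offsets", "in_known_epitope_db"],
    )
    return df.sort_values(["gene", "sequence"]).reset_index(drop=True)


def sharing_table(per_sample_candidates: Dict[str, Set[str]]) -> pd.DataFrame:
    """Peptide x sample boolean sharing matrix, sorted by the number of
    samples carrying each peptide (descending), then by sequence."""
    samples = list(per_sample_candidates)
    union = sorted(set().union(*per_sample_candidates.values())) if samples else []
    data = {
        s: [pep in per_sample_candidates[s] for pep in union] for s in samples
    }
    df = pd.DataFrame(data, index=pd.Index(union, name="peptide"))
    df["n_samples"] = df.sum(axis=1)
    df = df.sort_values(
        ["n_samples", "peptide"], ascending=[False, True]
    ).drop(columns="n_samples")
    return df


def export_for_hla_tools(candidates: pd.DataFrame, fasta_path, tsv_path) -> None:
    """Write surviving candidates as FASTA (headers gene|snv|offsets)
    plus the full TSV table, ready for HLA typing / affinity tools."""
    with open(fasta_path, "w") as fh:
        for i, row in candidates.iterrows():
            header = f"{row['gene']}|{row['snv_id']}|{row['start_offsets']}"
            fh.write(f">{header}\n{row['sequence']}\n")
    candidates.to_csv(tsv_path, sep="\t", index=False)


def read_exported_fasta(path) -> pd.DataFrame:
    """Parse back an exported peptide FASTA into (gene, snv_id,
    start_offsets, sequence)."""
    rows = []
    header = None
    seq_parts: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    rows.append((header, "".join(seq_parts)))
                header = line[1:]
                seq_parts = []
            else:
                seq_parts.append(line)
    if header is not None:
        rows.append((header, "".join(seq_parts)))
    out = []
    for header, seq in rows:
        gene, snv_id, offsets = header.split("|")
        out.append(
            dict(gene=gene, snv_id=snv_id, start_offsets=offsets, sequence=seq)
        )
    return pd.DataFrame(out, columns=["gene", "snv_id", "start_offsets", "sequence"])
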