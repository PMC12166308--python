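"""Readers, writers and matrix construction from raw per-read evidence.

Handles every external format the pipeline touches: somatic VCFs
(Mutect2-style FILTER column), TSV evidence tables (one row per aligned
read overlapping a candidate locus), MatrixMarket expression bundles,
and spot tables.  Matrix construction deduplicates reads on
(barcode, UMI, chrom, pos) before counting alt-supporting reads per
spot.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import (
    FormatError,
    SNVCallSet,
    SNVRecord,
    SpotSNVMatrix,
    SpotTable,
)

logger = logging.getLogger(__name__)

#: FILTER tags excluded when selecting somatic SNVs from a Mutect2 VCF.
DEFAULT_EXCLUDED_TAGS = frozenset(
    {
        "weak_evidence",
        "germline",
        "strand_bias",
        "slippage",
        "contamination",
        "panel_of_normals",
    }
)

EVIDENCE_COLUMNS = ["read_id", "barcode", "umi", "chrom", "pos", "allele"]


def read_filtered_vcf(path, excluded_tags=DEFAULT_EXCLUDED_TAGS) -> SNVCallSet:
    """Read biallelic SNVs from a VCF, dropping records whose FILTER
    carries any excluded tag.

    PASS records are always retained.  Multiallelic records are split
    and each ref/alt pair judged separately; non-SNV alleles (indels,
    symbolic) are skipped.
    """
    from cyvcf2 import VCF

    excluded_tags = frozenset(excluded_tags)
    records = []
    seen = set()
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    for var in vcf:
        filt = var.FILTER  # None means PASS in cyvcf2
        tags = frozenset() if filt is None else frozenset(filt.split(";"))
        if tags & excluded_tags:
            continue
        ref = var.REF
        if len(ref) != 1 or ref not in "ACGT":
            continue
        for alt in var.ALT:
            if len(alt) != 1 or alt not in "ACGT" or alt == ref:
                continue
            key = (var.CHROM, var.POS, ref, alt)
            if key in seen:
                continue
            seen.add(key)
            records.append(
                SNVRecord(
                    chrom=var.CHROM, pos=var.POS, ref=ref, alt=alt,
                    filter_tags=tags,
                )
            )
    vcf.close()
    return SNVCallSet(records)


def read_evidence_tsv(path) -> pd.DataFrame:
    """Read a per-read evidence table (read_id, barcode, umi, chrom,
    pos, allele)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele": str})
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"evidence table missing columns: {sorted(missing)}")
    return df


def build_spot_snv_matrix(
    evidence: pd.DataFrame, snvs: SNVCallSet, spots: SpotTable
) -> SpotSNVMatrix:
    """Build the raw spots x SNVs unique-read count matrix.

    Reads are first deduplicated on (barcode, umi, chrom, pos); each
    retained unique read whose allele equals the SNV's alt allele
    increments the count for its spot.  Reads matching the reference or
    a third base contribute nothing.  Evidence rows with barcodes absent
    from the spot table, or loci absent from the call set, are dropped
    with a logged count.
    """
    ev = evidence.copy()
    bc_index = spots.barcode_index()
    known_bc = ev["barcode"].isin(bc_index)
    n_unknown_bc = int((~known_bc).sum())
    if n_unknown_bc:
        logger.info("dropped %d evidence rows with unknown barcodes", n_unknown_bc)
    ev = ev[known_bc]

    # dedup on (barcode, umi, chrom, pos); distinct loci sharing a UMI
    # are deliberately kept apart
    ev = ev.drop_duplicates(subset=["barcode", "umi", "chrom", "pos"])

    locus_to_cols: dict = {}
    alt_of: dict = {}
    for j, rec in enumerate(snvs):
        locus_to_cols.setdefault((rec.chrom, rec.pos), []).append(j)
        alt_of[j] = rec.alt

    rows, cols = [], []
    n_unknown_locus = 0
    for bc, chrom, pos, allele in zip(
        ev["barcode"], ev["chrom"], ev["pos"], ev["allele"]
    ):
        js = locus_to_cols.get((chrom, int(pos)))
        if js is None:
            n_unknown_locus += 1
            continue
        for j in js:
            if allele == alt_of[j]:
                rows.append(bc_index[bc])
                cols.append(j)
    if n_unknown_locus:
        logger.info(
            "ignored %d evidence rows at loci not in the call set",
            n_unknown_locus,
        )
    counts = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(spots.n_spots, len(snvs)),
    ).tocsr()
    return SpotSNVMatrix(
        spots=spots, snv_ids=snvs.ids, counts=counts, layer="raw", snvs=snvs
    )


def aggregate_spot_bins(
    matrix: SpotSNVMatrix, bin_size: int
) -> Tuple[SpotSNVMatrix, SpotTable]:
    """Aggregate spots into bin_size x bin_size lattice blocks.

    New spot id is ``binX_binY`` with binX = floor(x / bin_size); counts
    and total_umi are summed within each block.  Region labels are
    carried over by majority vote within the block.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    df = matrix.spots.df
    bx = np.floor(df["x"].to_numpy() / bin_size).astype(int)
    by = np.floor(df["y"].to_numpy() / bin_size).astype(int)
    keys = pd.Series(list(zip(bx, by)))
    groups = keys.groupby(keys, sort=True).groups  # key -> row positions

    bin_keys = list(groups.keys())
    n_bins = len(bin_keys)
    assign_rows, assign_cols = [], []
    for new_i, key in enumerate(bin_keys):
        for old_i in groups[key]:
            assign_rows.append(new_i)
            assign_cols.append(old_i)
    A = sp.coo_matrix(
        (np.ones(len(assign_rows)), (assign_rows, assign_cols)),
        shape=(n_bins, matrix.n_spots),
    ).tocsr()

    new_counts = (A @ matrix.counts).astype(matrix.counts.dtype)
    new_umi = A @ df["total_umi"].to_numpy()

    regions = []
    for key in bin_keys:
        reg = df.loc[groups[key], "region"]
        regions.append(reg.mode().iloc[0])

    new_df = pd.DataFrame(
        {
            "barcode": [f"bin_{x}_{y}" for x, y in bin_keys],
            "x": [x for x, _ in bin_keys],
            "y": [y for _, y in bin_keys],
            "total_umi": new_umi.astype(df["total_umi"].dtype),
            "region": regions,
        }
    )
    new_spots = SpotTable(new_df)
    new_matrix = SpotSNVMatrix(
        spots=new_spots, snv_ids=list(matrix.snv_ids), counts=new_counts,
        layer=matrix.layer, snvs=matrix.snvs,
    )
    return new_matrix, new_spots


def read_expression_matrix(path) -> Tuple[sp.csr_matrix, list, list]:
    """Read a spots x genes MatrixMarket bundle (matrix.mtx,
    barcodes.tsv, features.tsv).

    Returns (matrix, barcodes, features) with rows = barcodes.  Raises
    :class:`FormatError` on dimension mismatch between the MTX header
    and the sidecar files.
    """
    path = Path(path)
    mtx = scipy.io.mmread(path / "matrix.mtx")
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].tolist()
    if mtx.shape[0] == 0 or mtx.shape[1] == 0:
        raise FormatError(f"empty expression matrix in {path}")
    if mtx.shape != (len(barcodes), len(features)):
        raise FormatError(
            f"MTX shape {mtx.shape} does not match {len(barcodes)} barcodes "
            f"x {len(features)} features"
        )
    return sp.csr_matrix(mtx), barcodes, features


def write_expression_matrix(path, matrix, barcodes, features) -> None:
    """Write a spots x genes sparse matrix as an MTX bundle."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(matrix))
    pd.Series(barcodes).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(features).to_csv(path / "features.tsv", sep="\t", index=False, header=False)


def align_expression_to_spots(
    matrix: sp.csr_matrix, barcodes: Sequence[str], spots: SpotTable
) -> sp.csr_matrix:
    """Reorder expression rows to match the spot table's barcode order.

    Spots with no expression row get a zero row.
    """
    bc_to_row = {b: i for i, b in enumerate(barcodes)}
    rows = []
    n_missing = 0
    zero = sp.csr_matrix((1, matrix.shape[1]))
    for bc in spots.barcodes:
        i = bc_to_row.get(bc)
        if i is None:
            n_missing += 1
            rows.append(zero)
        else:
            rows.append(matrix[i])
    if n_missing:
        logger.info("%d spots have no expression row; zero-filled", n_missing)
    return sp.vstack(rows).tocsr()
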