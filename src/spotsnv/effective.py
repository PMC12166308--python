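"""Effective-SNV filtering, binarization, UMI normalization, gene
mutation frequency and differential SNV testing.

An *effective* SNV is one supported by at least 20 unique
(deduplicated) reads in total and observed in at least 5 spots; both
thresholds are configurable.  Per-spot normalization divides the
(binary) SNV signal by the spot's total mRNA UMI before a log1p
transform, which removes most of the correlation between apparent
mutation burden and sequencing depth.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import ranksums
from statsmodels.stats.multitest import multipletests

from .types import (
    EffectiveFilterParams,
    NormalizationError,
    SNVCallSet,
    SpotSNVMatrix,
    SpotTable,
)

logger = logging.getLogger(__name__)


def filter_effective(
    matrix: SpotSNVMatrix, params: EffectiveFilterParams = EffectiveFilterParams()
) -> SpotSNVMatrix:
    """Keep SNV columns with total unique-read support >=
    ``min_unique_reads`` and nonzero presence in >= ``min_spots`` spots.

    Column order is preserved; the result may be empty.  Idempotent.
    """
    if matrix.layer != "raw":
        raise ValueError("effective filtering operates on the raw layer")
    X = matrix.counts.tocsc()
    read_support = np.asarray(X.sum(axis=0)).ravel()
    spot_support = X.getnnz(axis=0)
    keep = (read_support >= params.min_unique_reads) & (
        spot_support >= params.min_spots
    )
    logger.info(
        "effective filter: %d of %d SNVs kept (>=%d reads, >=%d spots)",
        int(keep.sum()), matrix.n_snvs,
        params.min_unique_reads, params.min_spots,
    )
    return matrix.subset_snvs(keep)


def binarize(matrix: SpotSNVMatrix) -> SpotSNVMatrix:
    """Convert counts to 0/1 occurrence per spot."""
    b = matrix.counts.copy()
    b.data = (b.data > 0).astype(np.int8)
    b.eliminate_zeros()
    return matrix.with_counts(b, layer="binary")


def normalize_snv(
    matrix: SpotSNVMatrix, spots: Optional[SpotTable] = None
) -> SpotSNVMatrix:
    """Depth-normalize per-spot SNV signal: value = ln(s / U + 1) where
    s is the spot's (binary) count for that SNV and U its total UMI.

    Zero counts map exactly to zero.  A spot carrying SNV signal but
    zero total UMI is an error (its burden would be undefined).
    """
    spots = spots or matrix.spots
    X = matrix.counts.tocoo()
    umi = spots.total_umi.astype(float)
    if X.nnz:
        zero_umi = umi[X.row] == 0
        if zero_umi.any():
            bad = spots.barcodes[X.row[zero_umi][0]]
            raise NormalizationError(
                f"spot {bad!r} has SNV signal but zero total UMI"
            )
    data = np.log1p(X.data / umi[X.row])
    out = sp.csr_matrix((data, (X.row, X.col)), shape=X.shape)
    return matrix.with_counts(out, layer="normalized")


def spot_burden(matrix: SpotSNVMatrix, spots: Optional[SpotTable] = None) -> np.ndarray:
    """Per-spot scalar mutation burden: ln(sum of SNV counts / total
    UMI + 1)."""
    spots = spots or matrix.spots
    s = np.asarray(matrix.counts.sum(axis=1)).ravel().astype(float)
    umi = spots.total_umi.astype(float)
    if np.any((umi == 0) & (s > 0)):
        bad = spots.barcodes[int(np.flatnonzero((umi == 0) & (s > 0))[0])]
        raise NormalizationError(f"spot {bad!r} has SNV signal but zero total UMI")
    with np.errstate(invalid="ignore"):
        ratio = np.where(s > 0, s / np.where(umi > 0, umi, 1.0), 0.0)
    return np.log1p(ratio)


def gene_mutation_frequency(
    snvs: SNVCallSet, matrix: SpotSNVMatrix, gene_lengths: Dict[str, int]
) -> pd.DataFrame:
    """Per-gene effective-SNV density.

    For each gene with at least one effective SNV: the number of
    distinct SNV loci annotated to it, divided by gene length (bp), plus
    the mean number of spots in which its SNVs occur.
    """
    id_to_col = {sid: j for j, sid in enumerate(matrix.snv_ids)}
    X = matrix.counts.tocsc()
    spot_occ = X.getnnz(axis=0)
    per_gene: Dict[str, List[int]] = {}
    for rec in snvs:
        if rec.gene is None or rec.snv_id not in id_to_col:
            continue
        per_gene.setdefault(rec.gene, []).append(id_to_col[rec.snv_id])
    rows = []
    for gene, cols in sorted(per_gene.items()):
        length = gene_lengths.get(gene)
        if length is None or length <= 0:
            logger.warning("no length for gene %s; skipped", gene)
            continue
        rows.append(
            dict(
                gene=gene,
                n_effective_sites=len(cols),
                gene_length=length,
                frequency=len(cols) / length,
                mean_occurrence=float(np.mean(spot_occ[cols])),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "n_effective_sites", "gene_length", "frequency", "mean_occurrence"],
    )


def differential_snvs(
    matrix: SpotSNVMatrix,
    groups: np.ndarray,
    lfc_min: float = 1.0,
    p_max: float = 0.5,
    pseudocount: float = 1e-9,
) -> pd.DataFrame:
    """One-vs-rest differential SNVs between spot groups.

    For each SNV and each group, a Wilcoxon rank-sum test on normalized
    values (group vs all other spots) and a log2 fold change of group
    means with a small pseudocount.  Rows with lfc >= ``lfc_min`` and
    p < ``p_max`` are reported with Benjamini-Hochberg adjusted p-values.

    The default ``p_max`` of 0.5 is deliberately permissive (it mirrors
    the screening threshold this method was published with); 0.05 is the
    conventional choice for confirmatory analysis.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 spots")
    X = np.asarray(matrix.counts.todense(), dtype=float)
    rows = []
    for g in labels:
        in_g = groups == g
        A, B = X[in_g], X[~in_g]
        mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
        lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
        for j, sid in enumerate(matrix.snv_ids):
            col_a, col_b = A[:, j], B[:, j]
            if np.ptp(X[:, j]) == 0:  # constant across all spots
                p, l = 1.0, 0.0
            else:
                p = float(ranksums(col_a, col_b).pvalue)
                l = float(lfc[j])
            rows.append(dict(snv=sid, group=g, log_fold_change=l, p=p))
    df = pd.DataFrame(rows)
    df["adjusted_p"] = multipletests(df["p"], method="fdr_bh")[1]
    out = df[(df["log_fold_change"] >= lfc_min) & (df["p"] < p_max)]
    return out.reset_index(drop=True)
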