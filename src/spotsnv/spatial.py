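"""Spatial statistics: Moran's I autocorrelation, tumor-margin distance
decay of mutation burden, burden-pathway correlation and gene-signature
scoring.

Moran's I for a per-spot feature z (mean-centered values) under weights
w_ij (self-weights excluded) is

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   S0 = sum_ij w_ij.

The margin-decay analysis measures, for each margin spot, the mean
Euclidean distance to its k (default 5) nearest tumor spots and fits
ln(burden) ~ ln(distance) by ordinary least squares; the slope is the
decay exponent and R^2 the squared Pearson correlation.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import KDTree
from scipy.stats import chi2_contingency, linregress, pearsonr

from .types import (
    DistanceRegression,
    LabelingError,
    MoranResult,
    SpatialWeights,
    SpotTable,
)

logger = logging.getLogger(__name__)


def morans_i(
    values: np.ndarray, weights, feature: str = ""
) -> MoranResult:
    """Global Moran's I of a per-spot feature under a spatial weight
    matrix (any scipy sparse or dense square matrix, or
    :class:`SpatialWeights`).  Self-weights are excluded.

    Raises for constant features, whose autocorrelation is undefined.
    """
    values = np.asarray(values, dtype=float)
    if isinstance(weights, SpatialWeights):
        W = weights.without_self()
    else:
        W = sp.csr_matrix(weights)
        W = W.tolil()
        W.setdiag(0.0)
        W = W.tocsr()
    n = values.size
    if W.shape != (n, n):
        raise ValueError("weight matrix shape does not match values")
    z = values - values.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I undefined for a constant feature")
    S0 = float(W.sum())
    if S0 <= 0:
        raise ValueError("weight matrix has zero total weight")
    num = float(z @ (W @ z))
    return MoranResult(feature=feature, I=(n / S0) * num / denom, n=n)


def rook_adjacency(spots: SpotTable) -> sp.csr_matrix:
    """Binary rook (4-neighbor) adjacency for integer-lattice spots."""
    coords = spots.coords.astype(int)
    index = {(int(x), int(y)): i for i, (x, y) in enumerate(coords)}
    rows, cols = [], []
    for (x, y), i in index.items():
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            j = index.get((x + dx, y + dy))
            if j is not None:
                rows.append(i)
                cols.append(j)
    n = spots.n_spots
    return sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ).tocsr()


def distance_to_tumor(spots: SpotTable, k: int = 5) -> pd.Series:
    """Mean Euclidean distance from each margin spot to its k nearest
    tumor-region spots, indexed by margin-spot barcode."""
    region = spots.region
    tumor = spots.coords[region == "tumor"]
    margin_mask = region == "margin"
    if tumor.shape[0] == 0:
        raise LabelingError("no tumor-region spots in the spot table")
    if tumor.shape[0] < k:
        raise LabelingError(
            f"only {tumor.shape[0]} tumor spots; need at least k={k}"
        )
    if not margin_mask.any():
        raise LabelingError("no margin-region spots in the spot table")
    tree = KDTree(tumor)
    dist, _ = tree.query(spots.coords[margin_mask], k=k)
    dist = np.atleast_2d(dist)
    if k == 1:
        dist = dist.reshape(-1, 1)
    return pd.Series(
        dist.mean(axis=1), index=spots.barcodes[margin_mask], name="mean_tumor_distance"
    )


def burden_distance_fit(
    burden: np.ndarray, distance: np.ndarray, k: int = 5
) -> DistanceRegression:
    """OLS fit of ln(burden) on ln(distance) over margin spots.

    Spots with zero burden or zero distance are dropped (their log is
    undefined) and counted.  R^2 is the squared Pearson correlation of
    the fitted pairs.
    """
    burden = np.asarray(burden, dtype=float)
    distance = np.asarray(distance, dtype=float)
    if burden.shape != distance.shape:
        raise ValueError("burden and distance must align")
    ok = (burden > 0) & (distance > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d spots with zero burden or distance", n_dropped)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable margin spots for the fit")
    res = linregress(np.log(distance[ok]), np.log(burden[ok]))
    return DistanceRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_margin_spots=int(ok.sum()),
        k=k,
        n_dropped=n_dropped,
    )


def slope_vs_immune(slopes: Sequence[float], immune_scores: Sequence[float]):
    """Pearson correlation (r, two-sided p) between per-section decay
    slopes and per-section immune scores."""
    slopes = np.asarray(slopes, dtype=float)
    immune = np.asarray(immune_scores, dtype=float)
    if slopes.size != immune.size:
        raise ValueError("slopes and immune scores must align")
    if slopes.size < 3:
        raise ValueError("need at least 3 sections for a correlation p-value")
    r, p = pearsonr(slopes, immune)
    return float(r), float(p)


def signature_score(
    expression,
    gene_names: Sequence[str],
    gene_set: Sequence[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Per-spot gene-signature score: mean expression of the gene set
    minus the mean of an expression-matched control set.

    Genes are binned by their average expression (``n_bins`` bins);
    ``n_ctrl`` control genes are sampled from the bin of each signature
    gene.  This is the standard single-cell scoring scheme (Scanpy's
    ``score_genes``), computed here directly so sparse inputs and seeds
    are handled uniformly.
    """
    X = sp.csr_matrix(expression, dtype=float)
    gene_names = list(gene_names)
    name_to_col = {g: j for j, g in enumerate(gene_names)}
    set_cols = [name_to_col[g] for g in gene_set if g in name_to_col]
    if not set_cols:
        raise ValueError("no gene-set genes found in the expression matrix")
    if len(set_cols) < len(gene_set):
        logger.warning(
            "%d of %d signature genes absent from the matrix",
            len(gene_set) - len(set_cols), len(gene_set),
        )
    rng = np.random.default_rng(seed)
    avg = np.asarray(X.mean(axis=0)).ravel()
    order = np.argsort(avg, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(avg))
    bins = (ranks // np.ceil(len(avg) / n_bins)).astype(int)

    ctrl_cols: set = set()
    for c in set_cols:
        pool = np.flatnonzero(bins == bins[c])
        take = min(n_ctrl, pool.size)
        ctrl_cols.update(rng.choice(pool, size=take, replace=False).tolist())
    ctrl_cols -= set(set_cols)
    if not ctrl_cols:
        return np.zeros(X.shape[0])
    ctrl = sorted(ctrl_cols)
    mean_set = np.asarray(X[:, set_cols].mean(axis=1)).ravel()
    mean_ctrl = np.asarray(X[:, ctrl].mean(axis=1)).ravel()
    return mean_set - mean_ctrl


def burden_pathway_correlation(
    burden: np.ndarray, pathway_scores: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of per-spot mutation burden with each pathway
    score column, sorted by r descending."""
    burden = np.asarray(burden, dtype=float)
    rows = []
    for col in pathway_scores.columns:
        vals = pathway_scores[col].to_numpy(dtype=float)
        if np.std(vals) == 0 or np.std(burden) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = pearsonr(burden, vals)
        rows.append(dict(pathway=col, r=r, p=p))
    return (
        pd.DataFrame(rows)
        .sort_values("r", ascending=False)
        .reset_index(drop=True)
    )


def region_association(presence: np.ndarray, region: np.ndarray):
    """Chi-square test of association between SNV presence (0/1 per
    spot) and tumor-region membership.  Returns (chi2, p)."""
    presence = np.asarray(presence).astype(bool)
    in_tumor = np.asarray(region) == "tumor"
    table = np.array(
        [
            [np.sum(presence & in_tumor), np.sum(presence & ~in_tumor)],
            [np.sum(~presence & in_tumor), np.sum(~presence & ~in_tumor)],
        ]
    )
    chi2, p, _, _ = chi2_contingency(table)
    return float(chi2), float(p)


def read_gmt(path) -> Dict[str, List[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
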