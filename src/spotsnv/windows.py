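"""100-kb genomic window aggregation, Gaussian spatial smoothing,
window-window spatial correlation, and Leiden SNV groups.

SNVs are pooled into 100-kb windows (labeled ``chrom@index`` with
index = pos // window_size) using raw unique-read counts.  The spot x
window matrix M is smoothed by a Gaussian k-NN weight matrix,
M_w = W x M with W_ij = exp(-D_ij^2 / (2 alpha^2)).  Window-window
spatial correlation is W_corr = M_w^T x M_w computed after masking each
window to the spots in its top 50% of smoothed signal.  A directed
graph keeps, per window, its top 50% most correlated partners with
Gaussian-decayed rank-normalized weights; Leiden community detection on
this graph yields SNV groups.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .types import (
    SNVCallSet,
    SpatialWeights,
    SpotSNVMatrix,
    SpotTable,
    WindowMatrix,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 100_000
DEFAULT_RESOLUTION = 5.0
DEFAULT_TOP_FRACTION = 0.5
DEFAULT_DECAY_ALPHA = 0.5


def window_label(chrom: str, pos: int, window_size: int = DEFAULT_WINDOW_SIZE) -> str:
    """``chrom@index`` label of the window containing a 1-based position."""
    return f"{chrom}@{pos // window_size}"


def window_aggregate(
    matrix: SpotSNVMatrix,
    snvs: Optional[SNVCallSet] = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> WindowMatrix:
    """Sum raw unique-read SNV counts into 100-kb genomic windows.

    Each SNV belongs to exactly one window; total counts are conserved.
    """
    snvs = snvs or matrix.snvs
    if snvs is None:
        raise ValueError("an SNVCallSet is required to place SNVs in windows")
    keys = [(rec.chrom, rec.pos // window_size) for rec in snvs]
    windows = sorted(set(keys))
    w_index = {w: j for j, w in enumerate(windows)}
    cols = np.array([w_index[k] for k in keys])
    # assignment matrix SNVs x windows
    A = sp.coo_matrix(
        (np.ones(len(keys)), (np.arange(len(keys)), cols)),
        shape=(len(keys), len(windows)),
    ).tocsr()
    M = (matrix.counts @ A).tocsr()
    return WindowMatrix(
        spots=matrix.spots, windows=windows, counts=M, window_size=window_size
    )


def mean_knn_distance(spots: SpotTable, k: int) -> float:
    """Mean distance to the k nearest neighbors over all spots; the
    default Gaussian bandwidth."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(spots.coords)
    dist, _ = nn.kneighbors(spots.coords)
    return float(dist[:, 1:].mean())


def spatial_weights(
    spots: SpotTable, k: int = 6, alpha: Optional[float] = None
) -> SpatialWeights:
    """Gaussian k-NN spatial weight matrix.

    W_ij = exp(-D_ij^2 / (2 alpha^2)) for j among i's k nearest
    neighbors (union-symmetrized) and W_ii = 1; zero elsewhere.  When
    ``alpha`` is None the section's mean k-NN distance is used.
    """
    n = spots.n_spots
    if k >= n:
        raise ValueError(f"k={k} must be < n_spots={n}")
    if alpha is None:
        alpha = mean_knn_distance(spots, k)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(spots.coords)
    dist, idx = nn.kneighbors(spots.coords)
    rows = np.repeat(np.arange(n), k + 1)
    cols = idx.ravel()
    w = np.exp(-(dist.ravel() ** 2) / (2.0 * alpha**2))
    W = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)  # union symmetrization
    W.setdiag(1.0)
    return SpatialWeights(W=W.tocsr(), k=k, alpha=float(alpha))


def smooth(
    windows: WindowMatrix, weights: SpatialWeights, row_normalize: bool = False
) -> WindowMatrix:
    """Gaussian smoothing M_w = W x M (optionally with row-normalized W)."""
    W = weights.W
    if row_normalize:
        rs = np.asarray(W.sum(axis=1)).ravel()
        W = sp.diags(1.0 / np.where(rs > 0, rs, 1.0)) @ W
    M_w = np.asarray((W @ windows.counts).todense(), dtype=float)
    return WindowMatrix(
        spots=windows.spots, windows=list(windows.windows),
        counts=windows.counts, window_size=windows.window_size, smoothed=M_w,
    )


def _mask_top_fraction(M_w: np.ndarray, top_fraction: float) -> np.ndarray:
    """Zero entries below each window's top-fraction quantile, computed
    over that window's nonzero smoothed values."""
    masked = M_w.copy()
    for j in range(M_w.shape[1]):
        col = M_w[:, j]
        nz = col[col > 0]
        if nz.size < 2:
            masked[:, j] = 0.0
            continue
        thresh = np.quantile(nz, 1.0 - top_fraction)
        masked[col < thresh, j] = 0.0
    return masked


def window_correlation(
    windows: WindowMatrix,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    normalize: bool = True,
) -> np.ndarray:
    """Window x window spatial correlation from the smoothed matrix,
    after restricting each window to the spots in its top fraction of
    smoothed signal.

    With ``normalize=True`` (default) each masked window column is
    scaled to unit norm first, so the score is a cosine similarity in
    [0, 1] and windows are comparable regardless of their absolute count
    scale; ``normalize=False`` gives the raw masked product
    M_w^T x M_w.  Windows with fewer than 2 nonzero spots get a zero
    row."""
    if windows.smoothed is None:
        raise ValueError("call smooth() before window_correlation()")
    masked = _mask_top_fraction(windows.smoothed, top_fraction)
    if normalize:
        norms = np.linalg.norm(masked, axis=0)
        masked = masked / np.where(norms > 0, norms, 1.0)
    return masked.T @ masked


def build_group_graph(
    corr: np.ndarray,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    decay_alpha: float = DEFAULT_DECAY_ALPHA,
) -> pd.DataFrame:
    """Directed weighted graph over windows from the correlation matrix.

    Per window (row), the diagonal is ignored and only the
    ``top_fraction`` highest-scoring positive partners are kept.  The
    kept correlation scores are refined by a Gaussian decay of the
    normalized score distance r = 1 - score / max_score of the row:

        weight = score * exp(-r^2 / (2 decay_alpha^2))

    so each row's top partner keeps its full correlation as weight and
    weakly correlated partners are attenuated beyond their raw score
    gap.  Returns an edge list (source, target, weight) with integer
    window indices; the graph may be asymmetric.
    """
    n = corr.shape[0]
    src, dst, wts = [], [], []
    for i in range(n):
        row = corr[i].astype(float).copy()
        row[i] = -np.inf
        pos = np.flatnonzero(row > 0)
        if pos.size == 0:
            continue
        n_keep = max(1, int(np.ceil(top_fraction * pos.size)))
        ranked = pos[np.argsort(row[pos])[::-1]]
        cutoff = row[ranked[n_keep - 1]]
        order = ranked[row[ranked] >= cutoff]  # ties at the cutoff kept
        max_score = row[order[0]]
        for j in order:
            r = 1.0 - row[j] / max_score
            w = float(row[j] * np.exp(-(r**2) / (2.0 * decay_alpha**2)))
            src.append(i)
            dst.append(int(j))
            wts.append(w)
    return pd.DataFrame({"source": src, "target": dst, "weight": wts})


def leiden_groups(
    graph: pd.DataFrame,
    n_windows: int,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on the (union-symmetrized) weighted
    window graph.

    Returns one group id per window, with groups relabeled 0..G-1 in
    decreasing order of summed within-group edge weight.  Deterministic
    given the seed.
    """
    import igraph as ig
    import leidenalg

    # symmetrize: undirected edge weight = max of the two directions
    W = sp.coo_matrix(
        (graph["weight"], (graph["source"], graph["target"])),
        shape=(n_windows, n_windows),
    ).tocsr()
    W = W.maximum(W.T).tocoo()
    mask = W.row < W.col
    edges = list(zip(W.row[mask].tolist(), W.col[mask].tolist()))
    weights = W.data[mask].tolist()
    g = ig.Graph(n=n_windows, edges=edges, directed=False)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
    )
    membership = np.asarray(part.membership)

    # rank groups by summed within-group weight
    strength: Dict[int, float] = {}
    for (a, b), w in zip(edges, weights):
        if membership[a] == membership[b]:
            strength[membership[a]] = strength.get(membership[a], 0.0) + w
    order = sorted(
        np.unique(membership),
        key=lambda gid: (-strength.get(gid, 0.0), gid),
    )
    relabel = {gid: rank for rank, gid in enumerate(order)}
    return np.array([relabel[m] for m in membership])


def group_scores(
    windows: WindowMatrix, assignment: np.ndarray, spots: Optional[SpotTable] = None
) -> pd.DataFrame:
    """Depth-normalized per-spot SNV group score:
    ln(sum of raw window counts in the group / spot total UMI + 1)."""
    spots = spots or windows.spots
    assignment = np.asarray(assignment)
    umi = spots.total_umi.astype(float)
    umi_safe = np.where(umi > 0, umi, 1.0)
    out = {}
    for g in np.unique(assignment):
        cols = np.flatnonzero(assignment == g)
        s = np.asarray(windows.counts[:, cols].sum(axis=1)).ravel().astype(float)
        out[f"group_{g}"] = np.log1p(s / umi_safe)
    return pd.DataFrame(out, index=spots.barcodes)


def representative_gene(
    window_index: int,
    windows: WindowMatrix,
    snvs: SNVCallSet,
    expression: Optional[sp.csr_matrix] = None,
    gene_names: Optional[Sequence[str]] = None,
) -> Optional[str]:
    """The single gene summarizing one window.

    Windows whose SNVs are all intergenic have no representative gene;
    a single-gene window returns that gene; with several candidate
    genes, the one whose expression correlates best (Pearson, across
    spots) with the window's count vector wins (ties broken
    lexicographically).
    """
    chrom, widx = windows.windows[window_index]
    genes = sorted(
        {
            rec.gene
            for rec in snvs
            if rec.gene is not None
            and rec.chrom == chrom
            and rec.pos // windows.window_size == widx
        }
    )
    if not genes:
        return None
    if len(genes) == 1:
        return genes[0]
    if expression is None or gene_names is None:
        logger.warning(
            "window %s@%d has %d candidate genes but no expression given; "
            "falling back to first alphabetically",
            chrom, widx, len(genes),
        )
        return genes[0]
    gene_col = {g: j for j, g in enumerate(gene_names)}
    wvec = np.asarray(windows.counts[:, window_index].todense()).ravel().astype(float)
    best: Tuple[float, str] = (-np.inf, "")
    for g in genes:
        j = gene_col.get(g)
        if j is None:
            continue
        evec = np.asarray(expression[:, j].todense()).ravel().astype(float)
        if np.std(evec) == 0 or np.std(wvec) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(evec, wvec)[0, 1])
        if r > best[0] or (r == best[0] and (best[1] == "" or g < best[1])):
            best = (r, g)
    return best[1] if best[1] else genes[0]
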