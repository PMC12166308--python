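"""End-to-end pipeline stages over a working directory.

Each stage reads the files its predecessors wrote, so stages can be run
individually or chained (`run_all`).  All outputs are plain text (TSV,
MTX, FASTA, JSON); the configuration used is saved next to them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import annotate as ann
from . import effective as eff
from . import io as sio
from . import neoantigen as neo
from . import spatial as sst
from . import windows as win
from .config import PipelineConfig
from .types import SNVCallSet, SpotSNVMatrix, SpotTable

logger = logging.getLogger(__name__)


def _write_matrix_bundle(matrix: SpotSNVMatrix, path) -> None:
    sio.write_expression_matrix(
        path, matrix.counts, list(matrix.spots.barcodes), matrix.snv_ids
    )


def _read_matrix_bundle(path, spots: SpotTable, layer: str) -> SpotSNVMatrix:
    counts, barcodes, snv_ids = sio.read_expression_matrix(path)
    if list(barcodes) != list(spots.barcodes):
        counts = sio.align_expression_to_spots(counts, barcodes, spots)
    return SpotSNVMatrix(spots=spots, snv_ids=snv_ids, counts=counts, layer=layer)


def stage_matrix(workdir, config: PipelineConfig) -> SpotSNVMatrix:
    """VCF + evidence + spots -> raw spots x SNVs unique-read matrix."""
    workdir = Path(workdir)
    spots = SpotTable.read_tsv(workdir / "spots.tsv")
    snvs = sio.read_filtered_vcf(workdir / "snvs.vcf")
    evidence = sio.read_evidence_tsv(workdir / "evidence.tsv")
    matrix = sio.build_spot_snv_matrix(evidence, snvs, spots)
    if config.bin_size > 1:
        matrix, spots = sio.aggregate_spot_bins(matrix, config.bin_size)
        spots.write_tsv(workdir / "spots_binned.tsv")
    _write_matrix_bundle(matrix, workdir / "matrix_raw")
    return matrix


def _load_spots(workdir, config: PipelineConfig) -> SpotTable:
    workdir = Path(workdir)
    binned = workdir / "spots_binned.tsv"
    if config.bin_size > 1 and binned.exists():
        return SpotTable.read_tsv(binned)
    return SpotTable.read_tsv(workdir / "spots.tsv")


def stage_effective(workdir, config: PipelineConfig) -> SpotSNVMatrix:
    """Raw matrix -> effective SNVs -> binary and normalized layers."""
    workdir = Path(workdir)
    spots = _load_spots(workdir, config)
    raw = _read_matrix_bundle(workdir / "matrix_raw", spots, "raw")
    params = eff.EffectiveFilterParams(config.min_unique_reads, config.min_spots)
    effective = eff.filter_effective(raw, params)
    _write_matrix_bundle(effective, workdir / "matrix_effective")
    binary = eff.binarize(effective)
    normalized = eff.normalize_snv(binary)
    _write_matrix_bundle(normalized, workdir / "matrix_normalized")
    burden = eff.spot_burden(binary)
    pd.DataFrame(
        {"barcode": spots.barcodes, "normalized_snv_count": burden}
    ).to_csv(workdir / "spot_burden.tsv", sep="\t", index=False)
    return effective


def stage_windows(workdir, config: PipelineConfig) -> Dict[str, object]:
    """Effective matrix -> 100-kb windows -> smoothing -> correlation ->
    graph -> Leiden groups -> group scores and Moran's I."""
    workdir = Path(workdir)
    spots = _load_spots(workdir, config)
    effective = _read_matrix_bundle(workdir / "matrix_effective", spots, "raw")
    snvs = SNVCallSet(
        [_snv_from_id(sid) for sid in effective.snv_ids]
    )
    wm = win.window_aggregate(effective, snvs, config.window_size)
    weights = win.spatial_weights(spots, k=config.knn_k, alpha=config.alpha)
    wm = win.smooth(wm, weights)
    corr = win.window_correlation(wm, config.top_fraction)
    graph = win.build_group_graph(corr, config.top_fraction, config.decay_alpha)
    labels = wm.labels
    graph_out = graph.assign(
        source=[labels[i] for i in graph["source"]],
        target=[labels[i] for i in graph["target"]],
    )
    graph_out.to_csv(workdir / "window_graph.tsv", sep="\t", index=False)
    assignment = win.leiden_groups(
        graph, wm.n_windows, resolution=config.leiden_resolution, seed=config.seed
    )
    pd.DataFrame({"window": labels, "group": assignment}).to_csv(
        workdir / "snv_groups.tsv", sep="\t", index=False
    )
    scores = win.group_scores(wm, assignment, spots)
    scores.to_csv(workdir / "group_scores.tsv", sep="\t")

    moran_rows = []
    for col in scores.columns:
        vals = scores[col].to_numpy()
        if np.ptp(vals) == 0:
            continue
        res = sst.morans_i(vals, weights, feature=col)
        moran_rows.append(dict(feature=col, morans_i=res.I, n=res.n))
    pd.DataFrame(moran_rows).to_csv(
        workdir / "group_morans_i.tsv", sep="\t", index=False
    )
    return dict(windows=wm, assignment=assignment, scores=scores, graph=graph)


def _snv_from_id(snv_id: str):
    from .types import SNVRecord

    chrom, pos, alleles = snv_id.split(":")
    ref, alt = alleles.split(">")
    return SNVRecord(chrom=chrom, pos=int(pos), ref=ref, alt=alt)


def stage_margins(workdir, config: PipelineConfig) -> dict:
    """Margin-spot distances to tumor and the log-log burden decay fit."""
    workdir = Path(workdir)
    spots = _load_spots(workdir, config)
    burden = pd.read_csv(workdir / "spot_burden.tsv", sep="\t")
    dist = sst.distance_to_tumor(spots, k=config.distance_k)
    burden = burden.set_index("barcode").loc[dist.index, "normalized_snv_count"]
    fit = sst.burden_distance_fit(
        burden.to_numpy(), dist.to_numpy(), k=config.distance_k
    )
    pd.DataFrame(
        {
            "barcode": dist.index,
            "mean_tumor_distance": dist.to_numpy(),
            "normalized_snv_count": burden.to_numpy(),
        }
    ).to_csv(workdir / "margin_distance.tsv", sep="\t", index=False)
    out = dict(
        slope=fit.slope, intercept=fit.intercept, r_squared=fit.r_squared,
        n_margin_spots=fit.n_margin_spots, k=fit.k, n_dropped=fit.n_dropped,
    )
    with open(workdir / "margin_fit.json", "w") as fh:
        json.dump(out, fh, indent=1)
    return out


def stage_neoantigen(workdir, config: PipelineConfig) -> pd.DataFrame:
    """Annotate effective SNVs against the toy annotation and export
    surviving mutant-peptide candidates."""
    workdir = Path(workdir)
    toy = workdir / "toy"
    gtf, cds = toy / "genes.gtf", toy / "cds.fa"
    if not gtf.exists():
        raise FileNotFoundError(f"no annotation at {gtf}")
    snvs = sio.read_filtered_vcf(toy / "variants.vcf")
    annotated = ann.annotate_snvs(snvs, gtf, cds)
    annotated.to_frame().to_csv(
        workdir / "annotated_snvs.tsv", sep="\t", index=False
    )
    cds_seqs = ann.read_cds_fasta(cds)
    peptides = []
    for rec in annotated:
        if rec.effect != "nonsynonymous":
            continue
        ctx = neo.extract_context(rec, cds_seqs)
        peptides.extend(neo.enumerate_peptides(ctx, config.kmin, config.kmax))
    extra = [p for p in [toy / "healthy_ligands.txt"] if p.exists()]
    known = [p for p in [toy / "known_epitopes.txt"] if p.exists()]
    index = neo.build_exclusion_index(cds, extra, config.kmin, config.kmax)
    candidates = neo.filter_candidates(peptides, index, known)
    neo.export_for_hla_tools(
        candidates, workdir / "peptides.fasta", workdir / "peptides.tsv"
    )
    return candidates


def run_all(workdir, config: Optional[PipelineConfig] = None) -> dict:
    """Run every stage in order; returns a summary dict (also written to
    summary.json)."""
    config = config or PipelineConfig()
    workdir = Path(workdir)
    config.save(workdir / "config_used.yaml")
    raw = stage_matrix(workdir, config)
    effective = stage_effective(workdir, config)
    wres = stage_windows(workdir, config)
    mres = stage_margins(workdir, config)
    summary = dict(
        n_snvs_called=raw.n_snvs,
        n_effective=effective.n_snvs,
        n_windows=wres["windows"].n_windows,
        n_groups=int(len(np.unique(wres["assignment"]))),
        margin_slope=mres["slope"],
        margin_r_squared=mres["r_squared"],
    )
    if (workdir / "toy" / "genes.gtf").exists():
        candidates = stage_neoantigen(workdir, config)
        summary["n_peptide_candidates"] = int(len(candidates))
    with open(workdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
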