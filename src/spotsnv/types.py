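"""Core data containers shared by all pipeline stages.

The pipeline operates on three central objects: a :class:`SpotTable`
(spot barcodes with lattice coordinates, per-spot total mRNA UMI and an
optional region label), an :class:`SNVCallSet` (filtered somatic variant
records with optional functional annotation), and a :class:`SpotSNVMatrix`
(sparse spots x SNVs count matrix in a raw, binary or normalized layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

REGIONS = ("tumor", "margin", "normal", "unassigned")

GENOMIC_REGIONS = (
    "exonic",
    "UTR5",
    "UTR3",
    "splicing",
    "intronic",
    "ncRNA",
    "intergenic",
    "unknown",
)

EFFECTS = ("synonymous", "nonsynonymous", "stopgain", "other")


class SpotSNVError(Exception):
    """Base class for pipeline errors."""


class FormatError(SpotSNVError):
    """Malformed or inconsistent input file."""


class NormalizationError(SpotSNVError):
    """A spot with SNV signal has zero total UMI."""


class LabelingError(SpotSNVError):
    """Region labels required by an operation are missing."""


@dataclass
class SpotTable:
    """Spot barcodes with 2-D section coordinates and per-spot depth.

    Parameters
    ----------
    df
        DataFrame with columns ``barcode``, ``x``, ``y``, ``total_umi``
        and optionally ``region`` (one of {tumor, margin, normal,
        unassigned}).  Barcodes must be unique, coordinates finite and
        ``total_umi`` nonnegative.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"barcode", "x", "y", "total_umi"}
        missing = required - set(self.df.columns)
        if missing:
            raise FormatError(f"SpotTable missing columns: {sorted(missing)}")
        if self.df["barcode"].duplicated().any():
            dup = self.df.loc[self.df["barcode"].duplicated(), "barcode"].iloc[0]
            raise FormatError(f"duplicate spot barcode: {dup!r}")
        xy = self.df[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise FormatError("spot coordinates must be finite")
        if (self.df["total_umi"] < 0).any():
            raise FormatError("total_umi must be nonnegative")
        if "region" not in self.df.columns:
            self.df = self.df.assign(region="unassigned")
        bad = set(self.df["region"].unique()) - set(REGIONS)
        if bad:
            raise FormatError(f"unknown region labels: {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    @property
    def barcodes(self) -> pd.Index:
        return pd.Index(self.df["barcode"])

    @property
    def n_spots(self) -> int:
        return len(self.df)

    @property
    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    @property
    def total_umi(self) -> np.ndarray:
        return self.df["total_umi"].to_numpy()

    @property
    def region(self) -> np.ndarray:
        return self.df["region"].to_numpy()

    def barcode_index(self) -> dict:
        return {b: i for i, b in enumerate(self.df["barcode"])}

    @classmethod
    def read_tsv(cls, path) -> "SpotTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df)

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class SNVRecord:
    """One biallelic somatic single-nucleotide variant.

    Positions are 1-based (VCF convention).  ``genomic_region`` and the
    coding-effect fields are filled by the annotator; ``effect`` is only
    meaningful for exonic records.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    filter_tags: frozenset = frozenset()
    genomic_region: str = "unknown"
    effect: Optional[str] = None
    gene: Optional[str] = None
    transcript: Optional[str] = None
    aa_change: Optional[tuple] = None  # (gene, ref_aa, protein_pos, alt_aa)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def snv_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


class SNVCallSet:
    """An ordered collection of :class:`SNVRecord` with unique ids."""

    def __init__(self, records: Sequence[SNVRecord]):
        self.records = list(records)
        ids = [r.snv_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNV records in call set")
        self._by_id = {r.snv_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SNVRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def get(self, snv_id: str) -> Optional[SNVRecord]:
        return self._by_id.get(snv_id)

    @property
    def ids(self) -> list:
        return [r.snv_id for r in self.records]

    def subset(self, ids: Sequence[str]) -> "SNVCallSet":
        return SNVCallSet([self._by_id[i] for i in ids])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            aa = None
            if r.aa_change is not None:
                g, ra, p, na = r.aa_change
                aa = f"{ra}{p}{na}"
            rows.append(
                dict(
                    snv_id=r.snv_id, chrom=r.chrom, pos=r.pos, ref=r.ref,
                    alt=r.alt, genomic_region=r.genomic_region,
                    effect=r.effect, gene=r.gene, transcript=r.transcript,
                    aa_change=aa,
                )
            )
        return pd.DataFrame(rows)


@dataclass
class SpotSNVMatrix:
    """Sparse spots x SNVs count matrix with a named layer.

    ``layer`` is one of ``raw`` (deduplicated unique-read counts),
    ``binary`` (0/1 occurrence) or ``normalized``
    (ln(count / spot UMI + 1)).
    """

    spots: SpotTable
    snv_ids: list
    counts: sp.csr_matrix
    layer: str = "raw"
    snvs: Optional[SNVCallSet] = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (self.spots.n_spots, len(self.snv_ids)):
            raise ValueError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{self.spots.n_spots} spots x {len(self.snv_ids)} SNVs"
            )
        if self.layer not in ("raw", "binary", "normalized"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        if self.layer == "binary" and self.counts.nnz:
            vals = np.unique(self.counts.data)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError("binary layer must contain only 0/1")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snvs(self) -> int:
        return self.counts.shape[1]

    def with_counts(self, counts, layer: str) -> "SpotSNVMatrix":
        return SpotSNVMatrix(
            spots=self.spots, snv_ids=list(self.snv_ids),
            counts=counts, layer=layer, snvs=self.snvs,
        )

    def subset_snvs(self, keep: np.ndarray) -> "SpotSNVMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        ids = [self.snv_ids[i] for i in idx]
        snvs = self.snvs.subset(ids) if self.snvs is not None else None
        return SpotSNVMatrix(
            spots=self.spots, snv_ids=ids,
            counts=self.counts[:, idx], layer=self.layer, snvs=snvs,
        )


@dataclass
class WindowMatrix:
    """Sparse spots x 100-kb genomic window counts.

    Windows are labeled ``chrom@index`` with ``index = pos // window_size``.
    ``smoothed`` holds the Gaussian-weighted matrix M_w = W x M once
    computed.
    """

    spots: SpotTable
    windows: list  # (chrom, index) tuples, ordered
    counts: sp.csr_matrix  # M
    window_size: int
    smoothed: Optional[np.ndarray] = None  # M_w

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (self.spots.n_spots, len(self.windows)):
            raise ValueError("window matrix shape mismatch")

    @property
    def labels(self) -> list:
        return [f"{c}@{i}" for c, i in self.windows]

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass
class SpatialWeights:
    """Gaussian k-NN spatial weight matrix over spots.

    W_ij = exp(-D_ij^2 / (2 alpha^2)) for j among i's k nearest
    neighbors (union-symmetrized) and for j = i (W_ii = 1); zero
    elsewhere.
    """

    W: sp.csr_matrix
    k: int
    alpha: float

    def without_self(self) -> sp.csr_matrix:
        W = self.W.tolil(copy=True)
        W.setdiag(0.0)
        return W.tocsr()


@dataclass(frozen=True)
class EffectiveFilterParams:
    """Thresholds defining an effective SNV: supported by at least
    ``min_unique_reads`` deduplicated reads and observed in at least
    ``min_spots`` spots."""

    min_unique_reads: int = 20
    min_spots: int = 5

    def __post_init__(self) -> None:
        if self.min_unique_reads < 1 or self.min_spots < 1:
            raise ValueError("thresholds must be >= 1")


@dataclass
class MoranResult:
    feature: str
    I: float
    n: int


@dataclass
class DistanceRegression:
    """Log-log fit of margin-spot mutation burden against mean distance
    to the k nearest tumor spots."""

    slope: float
    intercept: float
    r_squared: float
    n_margin_spots: int
    k: int
    n_dropped: int = 0


@dataclass
class MutantContext:
    """Amino-acid context around a nonsynonymous substitution: up to 15
    residues on each flank of the mutated residue (31 aa total for an
    interior site)."""

    snv: SNVRecord
    wt_context: str
    mut_context: str
    center_index: int
    truncated_by_stop: bool = False

    def __post_init__(self) -> None:
        if len(self.wt_context) != len(self.mut_context):
            raise ValueError("context length mismatch")
        diffs = [
            i for i, (a, b) in enumerate(zip(self.wt_context, self.mut_context))
            if a != b
        ]
        if diffs != [self.center_index]:
            raise ValueError(
                "wt and mut contexts must differ exactly at center_index"
            )


@dataclass
class PeptideCandidate:
    """A mutant 8-15-mer covering the substituted residue."""

    sequence: str
    snv_id: str
    gene: Optional[str]
    start_offsets: list  # offsets within the mutant context
    in_normal_proteome: bool = False
    in_healthy_ligandome: bool = False
    in_known_epitope_db: bool = False

    @property
    def is_candidate(self) -> bool:
        return not (self.in_normal_proteome or self.in_healthy_ligandome)
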