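"""Pipeline configuration: every tunable with its default, serialized
alongside outputs for provenance."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    """All pipeline tunables.

    Attributes
    ----------
    min_unique_reads, min_spots
        Effective-SNV thresholds (unique deduplicated reads; spots with
        nonzero signal).
    bin_size
        Lattice block edge for spot binning (100 = Stereo-seq bin100);
        1 disables binning.
    window_size
        Genomic window width in bp for SNV aggregation.
    knn_k
        Neighbor count for the Gaussian spatial weight matrix.
    alpha
        Gaussian bandwidth (coordinate units); None means the section's
        mean k-NN distance.
    top_fraction
        Fraction of spots (per window) and of partners (per row) kept
        when masking and pruning the correlation structure.
    decay_alpha
        Bandwidth of the Gaussian decay applied to rank-normalized
        correlation scores when weighting graph edges.
    leiden_resolution
        Leiden resolution parameter for SNV grouping.
    distance_k
        Number of nearest tumor spots averaged for margin distances.
    kmin, kmax
        Peptide length range for neoantigen enumeration.
    lfc_min, p_max
        Differential-SNV thresholds (log2 fold change; rank-sum p).
    seed
        Seed for every stochastic step.
    """

    min_unique_reads: int = 20
    min_spots: int = 5
    bin_size: int = 1
    window_size: int = 100_000
    knn_k: int = 6
    alpha: Optional[float] = None
    top_fraction: float = 0.5
    decay_alpha: float = 0.5
    leiden_resolution: float = 5.0
    distance_k: int = 5
    kmin: int = 8
    kmax: int = 15
    lfc_min: float = 1.0
    p_max: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_unique_reads < 1 or self.min_spots < 1:
            raise ValueError("effective thresholds must be >= 1")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if not (1 <= self.kmin <= self.kmax):
            raise ValueError("need 1 <= kmin <= kmax")
        if self.leiden_resolution <= 0 or self.decay_alpha <= 0:
            raise ValueError("resolution and decay_alpha must be positive")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def override(self, **kwargs) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return PipelineConfig(**data)
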