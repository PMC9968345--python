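"""Configuration objects shared across the pipeline stages.

Defaults mirror the published method: cells with fewer than 200 detected
genes and genes expressed in under 1% of cells are dropped; confident
non-malignant cells require a single-sample gene-set test P < 1e-10 and
NES > 1.0 (at most 30 cells kept); the segmentation stopping constant is
beta = 0.5 for the whole sample and beta = 3.0 for per-clone
re-segmentation; alterations closer than 10 Mb with the same state are
merged, and alterations in different clones match when a boundary is
within 10 Mb and sizes differ by less than 40%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class SmoothingConfig:
    """Edge-preserving smoothing parameters.

    iterations : number of explicit descent steps.
    dt : step size; values above 0.5 are rejected for stability.
    gamma : data-fidelity weight; 0 recovers a pure TV-type flow.
    per_chromosome : smooth each chromosome independently (no diffusion
        across chromosome ends).
    """

    iterations: int = 100
    dt: float = 0.1
    gamma: float = 0.01
    per_chromosome: bool = True

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0 < self.dt <= 0.5):
            raise ValueError("dt must be in (0, 0.5] for stability")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass
class SegConfig:
    """Joint-segmentation parameters.

    beta : positive stopping constant; merging continues while the jump in
        the dynamic scale parameter lambda stays below beta * nu, where nu
        is the total variability of the smoothed matrix. Larger beta gives
        coarser segmentations.
    epsilon : lambda bump added when the schedule is raised; if None an
        automatic scale-aware value 1e-9 * max(nu, 1) is used.
    min_region_size : minimum region size in genes (1 = no floor).
    """

    beta: float = 0.5
    epsilon: float | None = None
    min_region_size: int = 1

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class MixtureConfig:
    """Initial parameters of the five-state truncated-normal mixture.

    States are deletion(0), loss(1), neutral(2), gain(3), amplification(4).
    Truncation bounds sit at the midpoints between adjacent initial means,
    with infinite bounds at the extremes.
    """

    means: tuple = (-1.0, -0.4, 0.0, 0.4, 1.0)
    sds: tuple = (0.15, 0.15, 0.15, 0.15, 0.15)
    weights: tuple = (0.05, 0.1, 0.7, 0.1, 0.05)
    sd_floor: float = 0.02
    max_iter: int = 100
    tol: float = 1e-4


@dataclass
class CloneConfig:
    """Subclone deconvolution parameters."""

    k_neighbors: int = 20
    resolution: float = 1.0
    min_clone_size: int = 10
    beta_clonal: float = 3.0
    merge_gap_bp: int = 10_000_000
    match_distance_bp: int = 10_000_000
    match_size_frac: float = 0.40


@dataclass
class PipelineConfig:
    """Top-level configuration; field groups mirror the pipeline stages."""

    min_genes_per_cell: int = 200
    min_cell_fraction_per_gene: float = 0.01
    p_threshold: float = 1e-10
    nes_threshold: float = 1.0
    max_confident_normals: int = 30
    baseline_statistic: str = "mean"
    standardize_genes: bool = True
    gene_sd_floor: float = 0.3
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    segmentation: SegConfig = field(default_factory=SegConfig)
    mixture: MixtureConfig = field(default_factory=MixtureConfig)
    clones: CloneConfig = field(default_factory=CloneConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")
        if not 0 <= self.min_cell_fraction_per_gene <= 1:
            raise ValueError("min_cell_fraction_per_gene must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)
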