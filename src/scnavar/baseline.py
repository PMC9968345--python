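"""Confident non-malignant cell seeding and baseline removal.

A small set (at most 30) of highly confident non-malignant cells is found
with a single-sample Mann-Whitney-Wilcoxon gene-set test against packaged
stromal/immune signatures: a cell qualifies when its best signature gives
P < 1e-10 and a logit-scale normalized enrichment score (NES) above 1.0.
The per-gene median over these cells is the copy-number baseline b, and
the relative matrix is D_r = D - b broadcast over cells. When no confident
cell is found the sample is assumed pure and a synthetic baseline is
removed instead: cells are grouped by Ward hierarchical clustering (k
chosen by the Calinski-Harabasz criterion) and each gene is shifted by a
zero-mean Gaussian draw with that gene's within-cluster standard
deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import mannwhitneyu, norm
from sklearn.metrics import calinski_harabasz_score

from .io import CountMatrix

#: product n1*n2 below which the exact Mann-Whitney null is used
EXACT_LIMIT = 10_000


@dataclass
class GeneSetTestResult:
    cell_id: str
    signature: str
    nes: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0, 1]")


@dataclass
class RelativeMatrix:
    """Baseline-subtracted log expression (cells x genes)."""

    values: np.ndarray
    baseline: np.ndarray | None
    confident_normals: set = field(default_factory=set)
    cell_ids: list = field(default_factory=list)
    genes: pd.DataFrame | None = None

    def chromosome_bounds(self) -> list[tuple[int, int]]:
        if self.genes is None or "chrom" not in self.genes:
            return [(0, self.values.shape[1])]
        chrom = self.genes["chrom"].to_numpy()
        bounds, start = [], 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                bounds.append((start, i))
                start = i
        return bounds


def mww_gst(
    profile: np.ndarray,
    in_signature: np.ndarray,
    cell_id: str = "",
    signature: str = "",
) -> GeneSetTestResult:
    """One-sided Mann-Whitney test of signature genes vs the rest of a cell.

    ``profile`` holds one cell's per-gene values; ``in_signature`` is a
    boolean mask of the same length. The enrichment score is the logit of
    the common-language effect size, nes = log2(pU / (1 - pU)) with
    pU = U / (n1 * n2), so 0 means no enrichment and the +1.0 acceptance
    threshold means pU > 2/3. The p-value tests signature > background;
    the exact null is used for small problems, a tie-corrected normal
    approximation otherwise.
    """
    profile = np.asarray(profile, dtype=float)
    in_signature = np.asarray(in_signature, dtype=bool)
    n1 = int(in_signature.sum())
    n2 = int((~in_signature).sum())
    if n1 == 0:
        raise ValueError("empty-signature: no signature gene is measured")
    if n2 < 2:
        raise ValueError("need at least 2 genes outside the signature")
    x = profile[in_signature]
    y = profile[~in_signature]
    has_ties = len(np.unique(profile)) < len(profile)
    method = "exact" if (n1 * n2 <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="greater", method=method)
    pu = float(res.statistic) / (n1 * n2)
    pu_c = min(max(pu, 1e-12), 1 - 1e-12)
    nes = math.log2(pu_c / (1 - pu_c))
    return GeneSetTestResult(cell_id, signature, nes, float(res.pvalue))


def identify_confident_normals(
    cm: CountMatrix,
    signatures: dict[str, set],
    p_threshold: float = 1e-10,
    nes_threshold: float = 1.0,
    max_cells: int = 30,
) -> set[str]:
    """Cells whose best signature passes both thresholds, top ``max_cells``.

    Each cell is assigned its best signature by maximal NES (ties: smaller
    p, then signature name); passing cells are ranked by NES descending
    and at most ``max_cells`` returned. An empty set is a valid outcome
    (pure tumor).
    """
    if cm.layer != "log":
        raise ValueError("identify_confident_normals expects the log layer")
    gene_ids = cm.genes["gene_id"].to_numpy()
    masks = {}
    for name, genes in sorted(signatures.items()):
        mask = np.isin(gene_ids, list(genes))
        if mask.any() and (~mask).sum() >= 2:
            masks[name] = mask
    best: list[GeneSetTestResult] = []
    for i, cell in enumerate(cm.cell_ids):
        results = [
            mww_gst(cm.values[i], mask, cell_id=cell, signature=name)
            for name, mask in masks.items()
        ]
        if results:
            best.append(
                min(results, key=lambda r: (-r.nes, r.p_value, r.signature))
            )
    passing = [
        r for r in best if r.p_value < p_threshold and r.nes > nes_threshold
    ]
    passing.sort(key=lambda r: -r.nes)
    return {r.cell_id for r in passing[:max_cells]}


def compute_relative_matrix(
    cm: CountMatrix, normals: set[str], statistic: str = "mean"
) -> RelativeMatrix:
    """D_r = D - b with b the per-gene baseline over confident normal cells.

    ``statistic`` selects the baseline estimator: "mean" (default) or
    "median". On sparse droplet data the median of a handful of mostly-zero
    profiles collapses to zero and leaves per-gene composition bias in
    every cell, so the unbiased mean is the default; the median is kept
    for deeply sequenced (plate-based) data where it is robust to
    outlier normals.
    """
    if cm.layer != "log":
        raise ValueError("compute_relative_matrix expects the log layer")
    if not normals:
        raise ValueError("no confident normals; use synthetic_baseline")
    unknown = normals - set(cm.cell_ids)
    if unknown:
        raise ValueError(f"normals not in matrix: {sorted(unknown)[:5]}")
    rows = [i for i, c in enumerate(cm.cell_ids) if c in normals]
    if statistic == "mean":
        baseline = cm.values[rows].mean(axis=0)
    elif statistic == "median":
        baseline = np.median(cm.values[rows], axis=0)
    else:
        raise ValueError("statistic must be 'mean' or 'median'")
    return RelativeMatrix(
        cm.values - baseline,
        baseline,
        set(normals),
        list(cm.cell_ids),
        cm.genes.copy(),
    )


def standardize_genes(rm: RelativeMatrix, cm: CountMatrix,
                      sd_floor: float = 0.3) -> RelativeMatrix:
    """Divide each gene's relative values by that gene's sd across cells.

    Standardization makes every gene contribute comparably to the joint
    segmentation cost, so highly expressed (high-variance) genes cannot
    dominate the breakpoint evidence. The sd is computed on the log layer
    across all cells and floored at ``sd_floor`` so near-silent genes are
    damped rather than amplified.
    """
    sd = np.maximum(cm.values.std(axis=0, ddof=0), sd_floor)
    return RelativeMatrix(
        rm.values / sd, rm.baseline, set(rm.confident_normals),
        list(rm.cell_ids), rm.genes,
    )


def synthetic_baseline(
    cm: CountMatrix,
    seed: int = 0,
    k_max: int = 10,
) -> RelativeMatrix:
    """Relative matrix for pure-tumor samples (no confident normals).

    Cells are split by Ward hierarchical clustering with k in {2..k_max}
    chosen by the Calinski-Harabasz index; within each cluster every gene
    is shifted by an independent N(0, sd_g) draw where sd_g is that gene's
    within-cluster standard deviation. Deterministic given ``seed``.
    """
    if cm.layer != "log":
        raise ValueError("synthetic_baseline expects the log layer")
    rng = np.random.default_rng(seed)
    X = cm.values
    m = X.shape[0]
    if m < 4:  # fewer cells than 2 * k_min -> single cluster
        labels = np.zeros(m, dtype=int)
    else:
        Z = sch.linkage(X, method="ward")
        best_k, best_score = 1, -np.inf
        candidates = {}
        for k in range(2, min(k_max, m - 1) + 1):
            lab = sch.fcluster(Z, t=k, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            score = calinski_harabasz_score(X, lab)
            if not np.isfinite(score):
                continue
            candidates[k] = lab
            if score > best_score:
                best_k, best_score = k, score
        labels = candidates.get(best_k, np.zeros(m, dtype=int))
    out = X.copy()
    for lab in np.unique(labels):
        rows = np.where(labels == lab)[0]
        sd = X[rows].std(axis=0) if len(rows) > 1 else np.zeros(X.shape[1])
        shift = rng.normal(0.0, 1.0, size=X.shape[1]) * sd
        out[rows] -= shift[None, :]
    return RelativeMatrix(out, None, set(), list(cm.cell_ids), cm.genes.copy())
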