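"""Multichannel piecewise-constant segmentation by greedy region merging.

All cells share one breakpoint set: the genome (ordered gene axis) is
partitioned into regions and the matrix approximated, within each region,
by the per-cell mean. The piecewise-constant Mumford-Shah energy

    E(u, Gamma) = sum_regions sum_cells sum_{genes in region} (x - u)^2
                  + lambda * M

is minimized greedily: starting from one region per gene, the adjacent
pair with the smallest merge cost

    lam~ = |R_i| |R_{i+1}| / (|R_i| + |R_{i+1}|) * ||u_i - u_{i+1}||^2

is merged whenever lam~ < lambda; otherwise lambda is raised to the
smallest cost plus epsilon. The merge cost equals exactly the increase of
the data term caused by the merge, so the lambda schedule is monotone
non-decreasing. Merging stops at the first lambda jump exceeding
beta * nu, where nu (total variability) is the sum over cells of the
standard deviation of the smoothed signal; larger beta therefore yields
coarser segmentations. Regions never span two chromosomes; the lambda
schedule and nu are global across the genome.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import SegConfig


@dataclass
class Region:
    """Half-open gene-index span [start, end) with per-cell mean vector."""

    start: int
    end: int
    mean: np.ndarray

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class Segmentation:
    """Result of joint segmentation.

    breakpoints : ordered gene indices; includes both ends of every
        chromosome, so region i spans [breakpoints[i], breakpoints[i+1])
        within its chromosome.
    regions : genome-ordered list of :class:`Region`.
    lambda_history : non-decreasing schedule of the scale parameter.
    energy_history : data term of the energy after each merge.
    merge_log : (removed breakpoint index, merge cost) per merge, in order.
    """

    breakpoints: list[int]
    regions: list[Region]
    chrom_bounds: list[tuple[int, int]]
    nu: float
    lambda_history: list[float] = field(default_factory=list)
    energy_history: list[float] = field(default_factory=list)
    merge_log: list[tuple[int, float]] = field(default_factory=list)

    @property
    def interior_breakpoints(self) -> list[int]:
        ends = {b for se in self.chrom_bounds for b in se}
        return [b for b in self.breakpoints if b not in ends]


def total_variability(matrix: np.ndarray) -> float:
    """nu = sum over cells of the (population) sd of the cell's gene values."""
    matrix = np.asarray(matrix, dtype=float)
    if not np.isfinite(matrix).all():
        raise ValueError("non-finite values in matrix")
    if matrix.shape[1] < 2:
        return 0.0
    return float(matrix.std(axis=1, ddof=0).sum())


def merge_cost(left: Region, right: Region) -> float:
    """Cost of merging two adjacent regions (the data-term increase)."""
    if left.end != right.start:
        raise ValueError("regions are not adjacent")
    d = left.mean - right.mean
    return left.size * right.size / (left.size + right.size) * float(d @ d)


class JointSegmenter(BaseEstimator):
    """sklearn-style estimator for joint multichannel segmentation.

    Parameters
    ----------
    beta : stopping constant (larger -> coarser segmentation).
    epsilon : lambda bump; None selects 1e-9 * max(nu, 1).
    min_region_size : region-size floor applied after stopping.

    Attributes (after ``fit``)
    --------------------------
    segmentation_ : :class:`Segmentation`
    breakpoints_ : list of all breakpoints (chromosome ends included)
    nu_ : total variability of the fitted matrix
    """

    def __init__(self, beta: float = 0.5, epsilon: float | None = None,
                 min_region_size: int = 1):
        self.beta = beta
        self.epsilon = epsilon
        self.min_region_size = min_region_size

    def fit(self, X, y=None, chrom_bounds: list[tuple[int, int]] | None = None):
        cfg = SegConfig(beta=self.beta, epsilon=self.epsilon,
                        min_region_size=self.min_region_size)
        X = np.asarray(X, dtype=float)
        bounds = chrom_bounds or [(0, X.shape[1])]
        self.segmentation_ = _greedy_segment(X, bounds, cfg)
        self.breakpoints_ = self.segmentation_.breakpoints
        self.nu_ = self.segmentation_.nu
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Piecewise-constant CNA matrix of X under the fitted breakpoints."""
        return build_cna_matrix(np.asarray(X, dtype=float), self.segmentation_)

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).transform(X)


def _greedy_segment(X: np.ndarray, chrom_bounds, cfg: SegConfig) -> Segmentation:
    m, n = X.shape
    nu = total_variability(X)
    eps = cfg.epsilon if cfg.epsilon is not None else 1e-9 * max(nu, 1.0)
    threshold = cfg.beta * nu

    # region id = current start index; doubly-linked over the genome
    col = np.ascontiguousarray(X.T)          # gene-major for fast sums
    sums = col.copy()                        # per-region column sums (at id)
    size = np.ones(n, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    prv = np.full(n, -1, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    version = np.zeros(n, dtype=np.int64)
    chrom_of = np.empty(n, dtype=np.int64)
    for ci, (s, e) in enumerate(chrom_bounds):
        chrom_of[s:e] = ci
        for i in range(s, e - 1):
            nxt[i] = i + 1
            prv[i + 1] = i

    def pair_cost(a: int, b: int) -> float:
        ua = sums[a] / size[a]
        ub = sums[b] / size[b]
        d = ua - ub
        return size[a] * size[b] / (size[a] + size[b]) * float(d @ d)

    heap: list[tuple[float, int, int, int, int]] = []
    for a in range(n):
        b = nxt[a]
        if b != -1:
            heapq.heappush(heap, (pair_cost(a, b), a, b, 0, 0))

    lam = 0.0
    energy = 0.0
    lambda_history = [lam]
    energy_history = [energy]
    merge_log: list[tuple[int, float]] = []
    degenerate = nu == 0.0  # constant input: collapse each chromosome fully

    def do_merge(a: int, b: int, cost: float) -> None:
        nonlocal energy
        sums[a] += sums[b]
        size[a] += size[b]
        alive[b] = False
        version[a] += 1
        c = nxt[b]
        nxt[a] = c
        if c != -1:
            prv[c] = a
            heapq.heappush(heap, (pair_cost(a, c), a, c, version[a], version[c]))
        p = prv[a]
        if p != -1:
            heapq.heappush(heap, (pair_cost(p, a), p, a, version[p], version[a]))
        energy += cost
        merge_log.append((b, cost))
        energy_history.append(energy)

    while heap:
        cost, a, b, va, vb = heapq.heappop(heap)
        if not (alive[a] and alive[b]) or nxt[a] != b:
            continue
        if version[a] != va or version[b] != vb:
            continue
        if degenerate or cost < lam:
            do_merge(a, b, cost)
            continue
        new_lam = cost + eps
        if new_lam - lam > threshold:
            heapq.heappush(heap, (cost, a, b, va, vb))  # leave state intact
            break
        lam = new_lam
        lambda_history.append(lam)
        do_merge(a, b, cost)

    if cfg.min_region_size > 1:
        _enforce_min_size(cfg.min_region_size, n, sums, size, nxt, prv, alive,
                          version, merge_log, energy_history)

    starts = sorted(np.where(alive)[0])
    regions = [
        Region(int(s), int(s) + int(size[s]), sums[s] / size[s]) for s in starts
    ]
    breakpoints = sorted({int(s) for s in starts} | {e for _, e in chrom_bounds})
    return Segmentation(breakpoints, regions, list(chrom_bounds), nu,
                        lambda_history, energy_history, merge_log)


def _enforce_min_size(floor, n, sums, size, nxt, prv, alive, version,
                      merge_log, energy_history):
    """Merge any region smaller than the floor with its cheaper neighbour."""
    changed = True
    while changed:
        changed = False
        for a in np.where(alive)[0]:
            if size[a] >= floor:
                continue
            cands = []
            p, c = prv[a], nxt[a]
            for left, right in ((p, a), (a, c)):
                if left != -1 and right != -1:
                    ua = sums[left] / size[left]
                    ub = sums[right] / size[right]
                    d = ua - ub
                    cands.append(
                        (size[left] * size[right] / (size[left] + size[right])
                         * float(d @ d), left, right)
                    )
            if not cands:
                continue
            cost, left, right = min(cands)
            sums[left] += sums[right]
            size[left] += size[right]
            alive[right] = False
            version[left] += 1
            c2 = nxt[right]
            nxt[left] = c2
            if c2 != -1:
                prv[c2] = left
            merge_log.append((int(right), cost))
            energy_history.append(energy_history[-1] + cost)
            changed = True
            break


def build_cna_matrix(matrix: np.ndarray, seg: Segmentation) -> np.ndarray:
    """Replace each value by its cell's mean over the containing region."""
    matrix = np.asarray(matrix, dtype=float)
    out = np.empty_like(matrix)
    for r in seg.regions:
        out[:, r.start:r.end] = matrix[:, r.start:r.end].mean(axis=1, keepdims=True)
    return out


def joint_segment(
    matrix: np.ndarray,
    chrom_bounds: list[tuple[int, int]] | None = None,
    cfg: SegConfig | None = None,
) -> Segmentation:
    """Functional wrapper over :class:`JointSegmenter`."""
    cfg = cfg or SegConfig()
    est = JointSegmenter(cfg.beta, cfg.epsilon, cfg.min_region_size)
    est.fit(matrix, chrom_bounds=chrom_bounds)
    return est.segmentation_


def segment_means(matrix: np.ndarray, seg: Segmentation) -> np.ndarray:
    """cells x regions matrix of per-cell region means."""
    matrix = np.asarray(matrix, dtype=float)
    return np.column_stack(
        [matrix[:, r.start:r.end].mean(axis=1) for r in seg.regions]
    )


def write_seg(seg: Segmentation, matrix: np.ndarray, cell_ids: list[str],
              genes: pd.DataFrame, path: str | Path) -> None:
    """SEG-format TSV (sample, chrom, loc.start, loc.end, num.mark, seg.mean).

    Coordinates are 1-based inclusive, taken from the gene annotation.
    """
    means = segment_means(matrix, seg)
    rows = []
    for j, r in enumerate(seg.regions):
        chrom = genes["chrom"].iloc[r.start]
        start = int(genes["start"].iloc[r.start])
        end = int(genes["end"].iloc[r.end - 1])
        for i, cell in enumerate(cell_ids):
            rows.append((cell, chrom, start, end, r.size, means[i, j]))
    pd.DataFrame(
        rows, columns=["sample", "chrom", "loc.start", "loc.end",
                       "num.mark", "seg.mean"]
    ).to_csv(path, sep="\t", index=False)


def write_breakpoints(seg: Segmentation, genes: pd.DataFrame,
                      path: str | Path) -> None:
    """Breakpoints TSV (chrom, gene_index, bp_position)."""
    rows = []
    for b in seg.breakpoints:
        idx = min(b, len(genes) - 1)
        rows.append((genes["chrom"].iloc[idx], b, int(genes["start"].iloc[idx])))
    pd.DataFrame(rows, columns=["chrom", "gene_index", "bp_position"]).to_csv(
        path, sep="\t", index=False
    )
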