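"""Scoring harness: tolerance-based breakpoint F1, DP pruning with PR/AUC,
and 1-Mb resampling with Pearson correlation against reference profiles.

A predicted breakpoint counts as a true positive when it lies within a
tolerance (in genes, e.g. 20) of an unmatched true breakpoint; matching is
greedy one-to-one by increasing distance, so one prediction cannot absorb
several truths. The dynamic-programming pruner selects, among a method's
candidate breakpoints, the size-k subset minimizing the multichannel
residual sum of squares of the piecewise-constant fit — sweeping k yields
a precision-recall curve whose trapezoidal area summarizes a method
independently of its own regularization parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr


@dataclass
class BreakpointScore:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    tolerance: int


def score_breakpoints(predicted, truth, tolerance: int = 20) -> BreakpointScore:
    """Greedy one-to-one matching of predictions to truths within tolerance."""
    predicted = sorted(int(p) for p in predicted)
    truth = sorted(int(t) for t in truth)
    if not predicted and not truth:
        return BreakpointScore(0, 0, 0, 1.0, 1.0, 1.0, tolerance)
    pairs = sorted(
        (abs(p - t), pi, ti)
        for pi, p in enumerate(predicted)
        for ti, t in enumerate(truth)
        if abs(p - t) <= tolerance
    )
    used_p: set[int] = set()
    used_t: set[int] = set()
    for _, pi, ti in pairs:
        if pi not in used_p and ti not in used_t:
            used_p.add(pi)
            used_t.add(ti)
    tp = len(used_t)
    fp = len(predicted) - len(used_p)
    fn = len(truth) - len(used_t)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return BreakpointScore(tp, fp, fn, precision, recall, f1, tolerance)


def _rss_table(signal: np.ndarray, bounds: list[int]) -> np.ndarray:
    """RSS of the piecewise fit on [bounds[i], bounds[j]) for i < j."""
    m, n = signal.shape
    c1 = np.zeros((m, n + 1))
    c2 = np.zeros((m, n + 1))
    np.cumsum(signal, axis=1, out=c1[:, 1:])
    np.cumsum(signal**2, axis=1, out=c2[:, 1:])
    nb = len(bounds)
    table = np.full((nb, nb), np.inf)
    for i in range(nb):
        for j in range(i + 1, nb):
            a, b = bounds[i], bounds[j]
            w = b - a
            s1 = c1[:, b] - c1[:, a]
            s2 = c2[:, b] - c2[:, a]
            table[i, j] = float((s2 - s1 * s1 / w).sum())
    return table


def prune_breakpoints_dp(signal: np.ndarray, candidates, k: int) -> list[int]:
    """Optimal size-k subset of candidate breakpoints (exact DP).

    Returns the k interior breakpoints, chosen among ``candidates``, whose
    piecewise-constant fit of ``signal`` has minimal residual sum of
    squares. k = 0 gives the single-region fit (empty list).
    """
    signal = np.asarray(signal, dtype=float)
    candidates = sorted({int(c) for c in candidates})
    n = signal.shape[1]
    candidates = [c for c in candidates if 0 < c < n]
    if k > len(candidates):
        raise ValueError("k exceeds the number of candidates")
    if k == 0:
        return []
    bounds = [0] + candidates + [n]
    table = _rss_table(signal, bounds)
    nb = len(bounds)
    # dp[s][i] = best RSS of covering [0, bounds[i]) with s segments
    dp = np.full((k + 2, nb), np.inf)
    back = np.zeros((k + 2, nb), dtype=int)
    dp[0, 0] = 0.0
    for s in range(1, k + 2):
        for i in range(1, nb):
            costs = dp[s - 1, :i] + table[:i, i]
            j = int(np.argmin(costs))
            dp[s, i] = costs[j]
            back[s, i] = j
    i, s = nb - 1, k + 1
    cuts = []
    while s > 0:
        i = int(back[s, i])
        s -= 1
        if i > 0:
            cuts.append(bounds[i])
    return sorted(cuts)


def fit_rss(signal: np.ndarray, breakpoints) -> float:
    """Multichannel RSS of the piecewise-constant fit with given interior cuts."""
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[1]
    bounds = [0] + sorted(int(b) for b in breakpoints) + [n]
    total = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a:
            block = signal[:, a:b]
            total += float(((block - block.mean(axis=1, keepdims=True)) ** 2).sum())
    return total


def pr_curve_auc(signal: np.ndarray, candidates, truth,
                 tolerance: int = 20) -> tuple[float, list[tuple[float, float]]]:
    """Precision-recall AUC over DP-pruned candidate subsets of size 1..K.

    Returns (AUC, [(recall, precision), ...]); the area is the trapezoid
    over the achieved points sorted by recall (points with no predictions
    are skipped).
    """
    candidates = sorted({int(c) for c in candidates})
    if not candidates:
        raise ValueError("candidates must be non-empty")
    points = []
    for k in range(1, len(candidates) + 1):
        sel = prune_breakpoints_dp(signal, candidates, k)
        sc = score_breakpoints(sel, truth, tolerance)
        if sc.tp + sc.fp > 0:
            points.append((sc.recall, sc.precision))
    points.sort()
    if not points:
        return 0.0, []
    recalls = np.array([p[0] for p in points])
    precisions = np.array([p[1] for p in points])
    auc = float(np.trapezoid(precisions, recalls)) if len(points) > 1 else 0.0
    if len(points) == 1:
        auc = float(recalls[0] * precisions[0])
    return auc, points


def resample_1mb_and_correlate(
    profile_values: np.ndarray,
    profile_chrom: np.ndarray,
    profile_start: np.ndarray,
    profile_end: np.ndarray,
    reference,  # DataFrame-like with columns chrom, start, value
    bin_size: int = 1_000_000,
) -> float:
    """Pearson correlation after sampling the profile every 1 Mb.

    The inferred profile is given per segment (or per gene) with genomic
    spans; at each reference bin start the value of the containing span is
    taken. Bins not covered by the profile are dropped; fewer than 3
    shared positions raises an error.
    """
    ref_chrom = np.asarray(reference["chrom"]).astype(str)
    ref_start = np.asarray(reference["start"], dtype=int)
    ref_value = np.asarray(reference["value"], dtype=float)
    prof_chrom = np.asarray(profile_chrom).astype(str)
    sampled = []
    kept_ref = []
    for c, s, v in zip(ref_chrom, ref_start, ref_value):
        on = (prof_chrom == c) & (profile_start <= s) & (s < profile_end)
        idx = np.where(on)[0]
        if idx.size:
            sampled.append(float(profile_values[idx[0]]))
            kept_ref.append(v)
    if len(sampled) < 3:
        raise ValueError("fewer than 3 shared 1-Mb positions; "
                         "correlation undefined")
    x = np.asarray(sampled)
    y = np.asarray(kept_ref)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant profile; correlation undefined")
    return float(pearsonr(x, y)[0])
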