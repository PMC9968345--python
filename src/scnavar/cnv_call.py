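"""Five-state copy-number calling with a truncated-normal mixture.

The per-cell mean expression of each segment is modelled as a mixture of
five truncated normal components mapping to the states deletion(0),
loss(1), neutral(2), gain(3), amplification(4). Parameters are fitted by
EM from fixed initial values; each (cell, segment) mean is assigned its
maximum-posterior state and the segment consensus is the majority vote
across cells (ties resolved toward the state nearer neutral).

The M-step maximises the expected complete-data log-likelihood exactly
per component (two parameters, via the sufficient statistics
sum r_i, sum r_i x_i, sum r_i x_i^2 and a bounded quasi-Newton solve),
which keeps the observed log-likelihood monotone non-decreasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr, logsumexp
from sklearn.base import BaseEstimator

from .config import MixtureConfig
from .segment import Segmentation, segment_means

STATE_NAMES = ("deletion", "loss", "neutral", "gain", "amplification")
NEUTRAL = 2


@dataclass
class MixtureModel:
    """Parameters of the 5-component truncated-normal mixture."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not np.all(np.diff(self.means) > 0):
            raise ValueError("component means must be strictly increasing")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        if np.any(self.lower >= self.upper):
            raise ValueError("truncation bounds must satisfy lower < upper")

    @classmethod
    def from_config(cls, cfg: MixtureConfig | None = None) -> "MixtureModel":
        cfg = cfg or MixtureConfig()
        means = np.asarray(cfg.means, dtype=float)
        mids = (means[:-1] + means[1:]) / 2.0
        lower = np.concatenate([[-np.inf], mids])
        upper = np.concatenate([mids, [np.inf]])
        return cls(means, np.asarray(cfg.sds, float),
                   np.asarray(cfg.weights, float), lower, upper)


@dataclass
class SegmentCall:
    chrom: str
    start_bp: int
    end_bp: int
    n_genes: int
    per_cell_state: np.ndarray
    consensus_state: int
    segment_mean: float


def _log_trunc_pdf(x: np.ndarray, mean: float, sd: float,
                   lower: float, upper: float) -> np.ndarray:
    """Log density of a truncated normal; -inf outside [lower, upper]."""
    z = (x - mean) / sd
    log_phi = -0.5 * z * z - 0.5 * np.log(2 * np.pi) - np.log(sd)
    log_z = _log_partition(mean, sd, lower, upper)
    out = log_phi - log_z
    out = np.where((x < lower) | (x > upper), -np.inf, out)
    return out


def _log_partition(mean: float, sd: float, lower: float, upper: float) -> float:
    """log(Phi((upper-mean)/sd) - Phi((lower-mean)/sd)), overflow-safe."""
    a = -np.inf if np.isneginf(lower) else (lower - mean) / sd
    b = np.inf if np.isposinf(upper) else (upper - mean) / sd
    if np.isneginf(a) and np.isposinf(b):
        return 0.0
    if np.isneginf(a):
        return float(log_ndtr(b))
    if np.isposinf(b):
        return float(log_ndtr(-a))
    hi, lo = log_ndtr(b), log_ndtr(a)
    if hi <= lo:
        return -np.inf
    return float(hi + np.log1p(-np.exp(lo - hi)))


class TruncatedNormalMixture(BaseEstimator):
    """sklearn-style estimator for the 5-state mixture.

    Attributes (after ``fit``)
    --------------------------
    model_ : fitted :class:`MixtureModel`
    log_likelihood_history_ : per-iteration observed log-likelihood
    n_iter_ : EM iterations performed
    """

    def __init__(self, config: MixtureConfig | None = None,
                 max_iter: int | None = None, tol: float | None = None):
        self.config = config
        self.max_iter = max_iter
        self.tol = tol

    def _init_model(self) -> tuple[MixtureModel, int, float, float]:
        cfg = self.config or MixtureConfig()
        model = MixtureModel.from_config(cfg)
        max_iter = self.max_iter if self.max_iter is not None else cfg.max_iter
        tol = self.tol if self.tol is not None else cfg.tol
        return model, max_iter, tol, cfg.sd_floor

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 10:
            raise ValueError("need at least 10 values to fit the mixture")
        if not np.isfinite(x).all():
            raise ValueError("non-finite values")
        model, max_iter, tol, sd_floor = self._init_model()
        k = len(model.means)
        means = model.means.copy()
        sds = model.sds.copy()
        weights = model.weights.copy()
        history: list[float] = []
        for it in range(max_iter):
            log_r = np.empty((x.size, k))
            for j in range(k):
                log_r[:, j] = np.log(weights[j]) + _log_trunc_pdf(
                    x, means[j], sds[j], model.lower[j], model.upper[j])
            ll_obs = float(logsumexp(log_r, axis=1).sum())
            history.append(ll_obs)
            r = np.exp(log_r - logsumexp(log_r, axis=1, keepdims=True))
            nk = r.sum(axis=0)
            new_means, new_sds = means.copy(), sds.copy()
            for j in range(k):
                if nk[j] < 1e-10:
                    warnings.warn(
                        f"component {j} ({STATE_NAMES[j]}) lost all "
                        "responsibility mass; frozen at its current value")
                    continue
                s1 = float(r[:, j] @ x)
                s2 = float(r[:, j] @ (x * x))
                mu, sd = _mstep_component(
                    nk[j], s1, s2, means[j], sds[j],
                    model.lower[j], model.upper[j], sd_floor)
                new_means[j], new_sds[j] = mu, sd
            means, sds = new_means, new_sds
            weights = np.clip(nk / nk.sum(), 1e-12, None)
            weights = weights / weights.sum()
            if it > 0 and abs(history[-1] - history[-2]) < tol * (
                    abs(history[-2]) + 1e-12):
                break
        order = np.argsort(means)
        if not np.array_equal(order, np.arange(k)):
            warnings.warn("component order changed during EM; re-sorted")
            means, sds, weights = means[order], sds[order], weights[order]
        self.model_ = MixtureModel(means, sds, weights, model.lower, model.upper)
        self.log_likelihood_history_ = history
        self.n_iter_ = len(history)
        return self

    def predict_log_proba(self, X):
        x = np.asarray(X, dtype=float).ravel()
        m = self.model_
        log_r = np.empty((x.size, len(m.means)))
        for j in range(len(m.means)):
            log_r[:, j] = np.log(m.weights[j]) + _log_trunc_pdf(
                x, m.means[j], m.sds[j], m.lower[j], m.upper[j])
        # outside all truncation supports: fall back to distance from means
        bad = ~np.isfinite(log_r).any(axis=1)
        if bad.any():
            d = -np.abs(x[bad, None] - m.means[None, :])
            log_r[bad] = d
        return log_r - logsumexp(log_r, axis=1, keepdims=True)

    def predict_proba(self, X):
        return np.exp(self.predict_log_proba(X))

    def predict(self, X):
        return np.argmax(self.predict_log_proba(X), axis=1)


def _mstep_component(nk: float, s1: float, s2: float, mu0: float, sd0: float,
                     lower: float, upper: float, sd_floor: float):
    """Maximise nk * [-log sd - log Z(mu, sd)] - (s2 - 2 mu s1 + nk mu^2)/(2 sd^2).

    Exact per-component M-step using sufficient statistics; falls back to
    the current parameters if the solver fails to improve.
    """

    def neg_q(p):
        mu, log_sd = p
        sd = max(np.exp(log_sd), sd_floor)
        quad = s2 - 2 * mu * s1 + nk * mu * mu
        logz = _log_partition(mu, sd, lower, upper)
        if not np.isfinite(logz):
            return 1e300
        return quad / (2 * sd * sd) + nk * (np.log(sd) + logz)

    x0 = np.array([mu0, np.log(max(sd0, sd_floor))])
    res = minimize(neg_q, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400})
    if res.fun <= neg_q(x0):
        mu, log_sd = res.x
        return float(mu), float(max(np.exp(log_sd), sd_floor))
    return mu0, max(sd0, sd_floor)


def em_fit_truncated_mixture(values, init: MixtureConfig | None = None,
                             max_iter: int | None = None,
                             tol: float | None = None) -> TruncatedNormalMixture:
    """Functional wrapper over :class:`TruncatedNormalMixture`."""
    est = TruncatedNormalMixture(config=init, max_iter=max_iter, tol=tol)
    return est.fit(values)


def _majority_vote(states: np.ndarray) -> int:
    counts = np.bincount(states, minlength=5)
    winners = np.where(counts == counts.max())[0]
    if len(winners) == 1:
        return int(winners[0])
    # tie: prefer the state nearest neutral (conservative calling)
    return int(winners[np.argmin(np.abs(winners - NEUTRAL))])


def call_segment_states(cna: np.ndarray, seg: Segmentation,
                        genes, model: TruncatedNormalMixture) -> list[SegmentCall]:
    """Per-cell max-posterior state per segment + majority-vote consensus."""
    means = segment_means(cna, seg)  # cells x regions
    calls = []
    for j, region in enumerate(seg.regions):
        states = model.predict(means[:, j])
        calls.append(SegmentCall(
            chrom=str(genes["chrom"].iloc[region.start]),
            start_bp=int(genes["start"].iloc[region.start]),
            end_bp=int(genes["end"].iloc[region.end - 1]),
            n_genes=region.size,
            per_cell_state=states,
            consensus_state=_majority_vote(states),
            segment_mean=float(means[:, j].mean()),
        ))
    return calls
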