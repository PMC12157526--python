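"""Model evaluation against repeated presentations of a held-out story.

Trial-to-trial variability caps the correlation any model can reach.  The
noise ceiling ``CCmax`` is estimated from repeats with the signal-power
method of Schoppe et al.: for ``n`` repeats ``y_1..y_n`` of one channel,

    SP    = (Var_t(sum_i y_i) - sum_i Var_t(y_i)) / (n * (n - 1))
    CCmax = sqrt(SP / Var_t(mean_i y_i))

Model performance is then reported as the ceiling-normalized correlation

    CCnorm = Corr(repeat mean, prediction) / CCmax.

Channels whose estimated ceiling is non-finite or below a floor (default 0.2)
are clamped to the floor so that near-zero-signal channels cannot inflate
CCnorm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatSet",
    "EvalReport",
    "ccmax",
    "ccnorm",
    "evaluate_prediction",
    "excess_ccmax",
    "excess_pca",
    "bootstrap_model_comparison",
    "permutation_chance_test",
]


@dataclass
class RepeatSet:
    """Repeated recordings of one story: array ``n_rep x T x C``."""

    repeats: np.ndarray

    def __post_init__(self) -> None:
        self.repeats = np.asarray(self.repeats, dtype=np.float64)
        if self.repeats.ndim != 3:
            raise ValueError("repeats must be n_rep x T x C")
        if self.repeats.shape[0] < 2:
            raise ValueError("noise ceiling requires at least 2 repeats")
        if not np.all(np.isfinite(self.repeats)):
            raise ValueError("repeats contain non-finite values")

    @property
    def n_rep(self) -> int:
        return self.repeats.shape[0]

    @property
    def length(self) -> int:
        return self.repeats.shape[1]

    @property
    def n_channels(self) -> int:
        return self.repeats.shape[2]

    def mean(self) -> np.ndarray:
        """Repeat-mean response, ``T x C``."""
        return self.repeats.mean(axis=0)

    def subset(self, idx: np.ndarray) -> "RepeatSet":
        """Restrict all repeats to a subset of time samples."""
        return RepeatSet(self.repeats[:, idx, :])


@dataclass
class EvalReport:
    """Per-channel ceiling and normalized correlation, with summaries."""

    ccmax: np.ndarray
    ccnorm: np.ndarray
    clamp_applied: np.ndarray

    @property
    def mean_ccnorm(self) -> float:
        return float(np.mean(self.ccnorm))

    def mean_ccnorm_unclamped(self) -> float:
        """Mean over channels whose ceiling was not clamped."""
        keep = ~self.clamp_applied
        if not np.any(keep):
            return float("nan")
        return float(np.mean(self.ccnorm[keep]))

    def to_dict(self) -> dict:
        return {
            "mean_ccnorm": self.mean_ccnorm,
            "ccmax": self.ccmax.tolist(),
            "ccnorm": self.ccnorm.tolist(),
            "clamp_applied": self.clamp_applied.tolist(),
        }


def ccmax(repeats: RepeatSet, floor: float = 0.2) -> np.ndarray:
    """Per-channel noise ceiling (signal-power estimator) with floor clamp.

    Negative signal-power estimates (possible for pure noise), non-finite
    values and values below ``floor`` are all clamped to ``floor``.
    """
    if not isinstance(repeats, RepeatSet):
        repeats = RepeatSet(repeats)
    y = repeats.repeats
    n = repeats.n_rep
    var_sum = np.var(y.sum(axis=0), axis=0)        # Var_t of summed repeats
    sum_var = np.var(y, axis=1).sum(axis=0)        # sum over repeats of Var_t
    sp = (var_sum - sum_var) / (n * (n - 1))
    var_mean = np.var(y.mean(axis=0), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sp / var_mean
        out = np.sqrt(np.where(ratio > 0, ratio, np.nan))
    bad = ~np.isfinite(out) | (out < floor)
    if np.any(~np.isfinite(out)):
        warnings.warn(
            f"{int(np.sum(~np.isfinite(out)))} channel(s) had undefined noise "
            f"ceiling; clamped to {floor}",
            stacklevel=2,
        )
    out = np.where(bad, floor, out)
    return out


def ccnorm(
    prediction: np.ndarray, repeats: RepeatSet, ccmax_vec: np.ndarray
) -> np.ndarray:
    """Ceiling-normalized correlation per channel.

    Channels with zero prediction variance get CCnorm 0 (logged).
    """
    if not isinstance(repeats, RepeatSet):
        repeats = RepeatSet(repeats)
    prediction = np.asarray(prediction, dtype=np.float64)
    if prediction.shape != (repeats.length, repeats.n_channels):
        raise ValueError(
            f"prediction shape {prediction.shape} != repeats "
            f"({repeats.length}, {repeats.n_channels})"
        )
    target = repeats.mean()
    p = prediction - prediction.mean(axis=0)
    m = target - target.mean(axis=0)
    pv = np.einsum("tc,tc->c", p, p)
    mv = np.einsum("tc,tc->c", m, m)
    cov = np.einsum("tc,tc->c", p, m)
    out = np.zeros(repeats.n_channels)
    ok = (pv > 0) & (mv > 0)
    if np.any(~ok):
        logger.info(
            "%d channel(s) with zero prediction or target variance: CCnorm=0",
            int(np.sum(~ok)),
        )
    out[ok] = cov[ok] / np.sqrt(pv[ok] * mv[ok])
    return out / np.asarray(ccmax_vec, dtype=np.float64)


def evaluate_prediction(
    prediction: np.ndarray, repeats: RepeatSet, floor: float = 0.2
) -> EvalReport:
    """Full evaluation: CCmax, CCnorm and clamp bookkeeping in one report."""
    if not isinstance(repeats, RepeatSet):
        repeats = RepeatSet(repeats)
    y = repeats.repeats
    n = repeats.n_rep
    sp = (np.var(y.sum(axis=0), axis=0) - np.var(y, axis=1).sum(axis=0)) / (
        n * (n - 1)
    )
    var_mean = np.var(y.mean(axis=0), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.sqrt(np.where(sp / var_mean > 0, sp / var_mean, np.nan))
    clamped = ~np.isfinite(raw) | (raw < floor)
    cmax = np.where(clamped, floor, raw)
    return EvalReport(cmax, ccnorm(prediction, repeats, cmax), clamped)


def excess_ccmax(
    repeats: RepeatSet,
    onsets: np.ndarray,
    window_ms: float = 100.0,
    max_lag_ms: float = 800.0,
    rate_hz: float = 50.0,
    floor: float = 0.2,
    assignment: str = "all",
) -> np.ndarray:
    """Post-word-onset predictability profile, ``n_windows x C``.

    Samples falling in latency window ``k`` (``[k*w, (k+1)*w)`` samples after
    some word onset, ``w = window_ms`` worth of samples) are concatenated into
    a subsampled series whose noise ceiling is computed and the whole-series
    ceiling subtracted.

    ``assignment='all'`` lets a sample belong to every word within lag range;
    ``'nearest'`` attributes it only to the nearest preceding word.
    """
    if not isinstance(repeats, RepeatSet):
        repeats = RepeatSet(repeats)
    w = window_ms * rate_hz / 1000.0
    n_windows = max_lag_ms * rate_hz / 1000.0 / w
    if abs(w - round(w)) > 1e-9 or abs(n_windows - round(n_windows)) > 1e-9:
        raise ValueError("window and max lag must be whole samples at this rate")
    w = int(round(w))
    n_windows = int(round(n_windows))
    onsets = np.asarray(onsets, dtype=np.int64)
    T = repeats.length
    base = ccmax(repeats, floor=floor)
    out = np.empty((n_windows, repeats.n_channels))
    if assignment == "nearest":
        # lag of each sample to nearest preceding onset
        lag = np.full(T, np.iinfo(np.int64).max)
        prev = np.searchsorted(onsets, np.arange(T), side="right") - 1
        has = prev >= 0
        lag[has] = np.arange(T)[has] - onsets[prev[has]]
    for k in range(n_windows):
        if assignment == "all":
            lo, hi = k * w, (k + 1) * w
            idx = np.unique(
                (onsets[:, None] + np.arange(lo, hi)[None, :]).ravel()
            )
            idx = idx[(idx >= 0) & (idx < T)]
        elif assignment == "nearest":
            idx = np.flatnonzero((lag >= k * w) & (lag < (k + 1) * w))
        else:
            raise ValueError("assignment must be 'all' or 'nearest'")
        if idx.size == 0:
            raise ValueError(f"no samples fall in post-onset window {k}")
        out[k] = ccmax(repeats.subset(idx), floor=floor) - base
    return out


def excess_pca(excess: np.ndarray, n_components: int = 2):
    """PCA of the excess-CCmax matrix over channels.

    Channels are the observations; the principal components are latency
    timecourses and each channel gets a loading per component.

    Returns
    -------
    timecourses : ndarray, ``n_components x n_windows``
    loadings : ndarray, ``C x n_components``
    explained_variance_ratio : ndarray, ``n_components``
    """
    excess = np.asarray(excess, dtype=np.float64)
    if excess.shape[0] < 2:
        raise ValueError("need at least 2 windows for PCA")
    X = excess.T  # C x windows
    k = min(n_components, min(X.shape) - 0)
    pca = PCA(n_components=k, svd_solver="full")
    loadings = pca.fit_transform(X)
    return pca.components_, loadings, pca.explained_variance_ratio_


def bootstrap_model_comparison(
    ccnorm_a: np.ndarray,
    ccnorm_b: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> float:
    """One-sided bootstrap test that model A outperforms model B.

    Channels are resampled with replacement; the p-value is the fraction of
    bootstrap replicates whose mean difference ``a - b`` is below zero, with
    exact ties counted half (so identical inputs give p = 0.5).
    """
    a = np.asarray(ccnorm_a, dtype=np.float64)
    b = np.asarray(ccnorm_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("ccnorm vectors must have equal length")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a coarse p-value", stacklevel=2)
    rng = np.random.default_rng(seed)
    diff = a - b
    idx = rng.integers(0, diff.size, size=(n_boot, diff.size))
    means = diff[idx].mean(axis=1)
    return float(np.mean((means < 0) + 0.5 * (means == 0)))


def permutation_chance_test(
    prediction: np.ndarray,
    repeats: RepeatSet,
    n_perm: int = 1000,
    block_len: int = 50,
    seed: int = 0,
    floor: float = 0.2,
) -> float:
    """Permutation test of mean CCnorm against chance.

    The null distribution circularly shifts the prediction relative to the
    data by random offsets of at least ``block_len`` samples (preserving
    autocorrelation; zero shift excluded).  ``p = (1 + #{null >= observed}) /
    (n_perm + 1)``.
    """
    if not isinstance(repeats, RepeatSet):
        repeats = RepeatSet(repeats)
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    T = repeats.length
    if T <= 2 * block_len:
        raise ValueError(f"series length {T} too short for block_len {block_len}")
    rng = np.random.default_rng(seed)
    cmax = ccmax(repeats, floor=floor)
    observed = float(np.mean(ccnorm(prediction, repeats, cmax)))
    offsets = rng.integers(block_len, T - block_len + 1, size=n_perm)
    count = 0
    for off in offsets:
        shifted = np.roll(prediction, int(off), axis=0)
        stat = float(np.mean(ccnorm(shifted, repeats, cmax)))
        if stat >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)
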