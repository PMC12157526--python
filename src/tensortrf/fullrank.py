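"""Full-rank ridge baseline on the lagged embedding design.

Fits a dense ``D x N x C`` FIR filter by per-channel ridge regression with
sequential K-fold cross-validation over an exponential penalty grid, plus the
ridge-less (ordinary least squares) variant used for control residualization.

Folds are built from contiguous, equal-length time blocks within each story so
that the temporal correlation structure does not leak between training and
validation.  The solver reuses one SVD across the whole penalty grid, which
makes the fit closed-form and exactly reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import SparseEmbeddingSeries, lagged_dense_design

logger = logging.getLogger(__name__)

__all__ = [
    "FullFilter",
    "RidgeConfig",
    "default_penalty_grid",
    "sequential_folds",
    "fit_ridge",
    "fit_ols",
    "predict_full",
    "FullRankRidge",
    "FullRankRidgeResults",
]


@dataclass
class FullFilter:
    """Dense FIR filter tensor, shape ``D x N x C``."""

    tensor: np.ndarray

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        if self.tensor.ndim != 3:
            raise ValueError("filter tensor must be D x N x C")
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("filter tensor contains non-finite entries")

    @property
    def n_delays(self) -> int:
        return self.tensor.shape[0]

    @property
    def embed_dim(self) -> int:
        return self.tensor.shape[1]

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[2]


def default_penalty_grid(n: int = 8) -> np.ndarray:
    """Logarithmically spaced ridge penalties spanning [1e-3, 1e4]."""
    return np.logspace(-3, 4, n)


@dataclass
class RidgeConfig:
    """Cross-validated ridge settings: penalty grid and fold count."""

    penalty_grid: np.ndarray = field(default_factory=default_penalty_grid)
    n_folds: int = 6
    per_channel: bool = True

    def __post_init__(self) -> None:
        self.penalty_grid = np.asarray(self.penalty_grid, dtype=np.float64)
        if self.penalty_grid.size == 0 or np.any(self.penalty_grid <= 0):
            raise ValueError("penalty grid must be non-empty and positive")
        if np.any(np.diff(self.penalty_grid) < 0):
            raise ValueError("penalty grid must be sorted ascending")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def sequential_folds(
    length: int, n_folds: int, story_boundaries: list[int] | None = None
) -> np.ndarray:
    """Assign each of ``length`` samples to one of ``n_folds`` sequential folds.

    Within each story (delimited by ``story_boundaries``, a list of start
    indices beginning with 0), samples are cut into ``n_folds`` contiguous
    equal-length blocks, remainder going to the last block; fold ``k`` is the
    union of block ``k`` across stories.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if story_boundaries is None:
        story_boundaries = [0]
    starts = list(story_boundaries) + [length]
    folds = np.empty(length, dtype=np.int64)
    for s0, s1 in zip(starts[:-1], starts[1:]):
        L = s1 - s0
        if L < n_folds:
            raise ValueError(
                f"story of length {L} shorter than n_folds={n_folds}"
            )
        block = L // n_folds
        idx = np.arange(L) // block
        folds[s0:s1] = np.minimum(idx, n_folds - 1)
    return folds


def _svd_ridge_path(design: np.ndarray, Y: np.ndarray, grid: np.ndarray):
    """Ridge solutions for every penalty from one economy SVD.

    Returns weights with shape ``(len(grid), P, C)`` solving
    ``(X'X + lam I) w = X'y`` per channel.
    """
    U, s, Vt = np.linalg.svd(design, full_matrices=False)
    UtY = U.T @ Y  # K x C
    out = np.empty((grid.size, design.shape[1], Y.shape[1]))
    for i, lam in enumerate(grid):
        shrink = s / (s * s + lam)
        out[i] = Vt.T @ (shrink[:, None] * UtY)
    return out


def fit_ridge(
    design: np.ndarray,
    recording: np.ndarray,
    cfg: RidgeConfig | None = None,
    story_boundaries: list[int] | None = None,
    n_delays: int | None = None,
):
    """Per-channel cross-validated ridge on a lagged design.

    For each channel, the penalty minimizing mean validation MSE across the
    sequential folds is selected, then the filter is refit on all rows at the
    chosen penalty.  Closed-form SVD solve; no iteration.

    Returns
    -------
    weights : ndarray, ``P x C``
    lambdas : ndarray, ``C``
    cv_mse : ndarray, ``len(grid) x C``
        Mean validation MSE per penalty per channel.
    """
    cfg = cfg or RidgeConfig()
    design = np.asarray(design, dtype=np.float64)
    Y = np.asarray(recording, dtype=np.float64)
    if design.shape[0] != Y.shape[0]:
        raise ValueError("design and recording row counts differ")
    folds = sequential_folds(design.shape[0], cfg.n_folds, story_boundaries)
    grid = cfg.penalty_grid
    C = Y.shape[1]
    cv_sse = np.zeros((grid.size, C))
    cv_n = np.zeros(C)
    for k in range(cfg.n_folds):
        val = folds == k
        W = _svd_ridge_path(design[~val], Y[~val], grid)  # G x P x C
        pred = np.einsum("tp,gpc->gtc", design[val], W)
        cv_sse += np.sum((pred - Y[val]) ** 2, axis=1)
        cv_n += val.sum()
    cv_mse = cv_sse / cv_n
    best = np.argmin(cv_mse, axis=0)  # per channel
    if not cfg.per_channel:
        best[:] = np.argmin(cv_mse.mean(axis=1))
    lambdas = grid[best]
    W_all = _svd_ridge_path(design, Y, grid)
    weights = np.empty((design.shape[1], C))
    for c in range(C):
        weights[:, c] = W_all[best[c], :, c]
    logger.info(
        "ridge fit: %d channels, lambda range [%.3g, %.3g]",
        C, lambdas.min(), lambdas.max(),
    )
    return weights, lambdas, cv_mse


def fit_ols(design: np.ndarray, recording: np.ndarray) -> np.ndarray:
    """Ridge-less least-squares weights ``P x C`` (pseudo-inverse fallback).

    Used for control residualization.  Warns when the design is
    rank-deficient.
    """
    design = np.asarray(design, dtype=np.float64)
    Y = np.asarray(recording, dtype=np.float64)
    weights, _, rank, _ = np.linalg.lstsq(design, Y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            f"control design rank {rank} < {design.shape[1]} columns; "
            "minimum-norm pseudo-inverse solution used",
            stacklevel=2,
        )
    return weights


def weights_to_filter(weights: np.ndarray, n_delays: int) -> FullFilter:
    """Reshape flat ``(D*N) x C`` ridge weights into a ``D x N x C`` tensor."""
    P, C = weights.shape
    if P % n_delays:
        raise ValueError("weight rows not divisible by n_delays")
    return FullFilter(weights.reshape(n_delays, P // n_delays, C))


def predict_full(filt: FullFilter, series: SparseEmbeddingSeries) -> np.ndarray:
    """Event-sparse FIR prediction ``pred[t,c] = sum_{d,n} F[d,n,c] X[t-d,n]``.

    Cost scales with the number of events, not with T * D * N * C.
    """
    if series.dim != filt.embed_dim:
        raise ValueError(
            f"series dim {series.dim} != filter embed dim {filt.embed_dim}"
        )
    T = series.length
    out = np.zeros((T, filt.n_channels))
    if series.n_events == 0:
        return out
    # per-event D x C response patterns
    contrib = np.einsum("jn,dnc->jdc", series.embeddings, filt.tensor, optimize=True)
    tau = series.onsets
    for d in range(filt.n_delays):
        t = tau + d
        valid = t < T
        if np.any(valid):
            np.add.at(out, t[valid], contrib[valid, d, :])
    return out


class FullRankRidge:
    """Full-rank ridge encoding model over lagged word-embedding features.

    The statsmodels-style companion to :class:`~tensortrf.cp.CPTensorRegression`:
    construct from per-story recordings and sparse series, then ``fit()``.
    """

    def __init__(
        self,
        recordings: list[np.ndarray],
        series: list[SparseEmbeddingSeries],
        n_delays: int,
    ):
        if len(recordings) == 0 or len(recordings) != len(series):
            raise ValueError("need equal, non-empty recording and series lists")
        self.recordings = [np.asarray(M, dtype=np.float64) for M in recordings]
        self.series = list(series)
        self.n_delays = n_delays
        for M, s in zip(self.recordings, self.series):
            if M.shape[0] != s.length:
                raise ValueError("recording/series length mismatch")

    def _stacked(self):
        designs = [lagged_dense_design(s, self.n_delays) for s in self.series]
        boundaries = list(
            np.cumsum([0] + [s.length for s in self.series[:-1]]).astype(int)
        )
        return np.vstack(designs), np.vstack(self.recordings), boundaries

    def fit(self, cfg: RidgeConfig | None = None) -> "FullRankRidgeResults":
        cfg = cfg or RidgeConfig()
        design, Y, boundaries = self._stacked()
        weights, lambdas, cv_mse = fit_ridge(design, Y, cfg, boundaries)
        filt = weights_to_filter(weights, self.n_delays)
        return FullRankRidgeResults(self, filt, lambdas, cv_mse, cfg)

    def fit_unregularized(self) -> "FullRankRidgeResults":
        """Ridge-less OLS fit (the control-residualization variant)."""
        design, Y, _ = self._stacked()
        weights = fit_ols(design, Y)
        filt = weights_to_filter(weights, self.n_delays)
        return FullRankRidgeResults(
            self, filt, np.zeros(Y.shape[1]), None, None
        )


class FullRankRidgeResults:
    """Fitted full-rank model: dense filter, chosen penalties, CV table."""

    def __init__(self, model, filt: FullFilter, lambdas, cv_mse, config):
        self.model = model
        self.filter = filt
        self.lambdas = np.asarray(lambdas, dtype=np.float64)
        self.cv_mse = cv_mse
        self.config = config

    def predict(self, series: SparseEmbeddingSeries) -> np.ndarray:
        return predict_full(self.filter, series)

    def evaluate(self, series, repeats, floor: float = 0.2):
        from .evaluation import evaluate_prediction

        return evaluate_prediction(self.predict(series), repeats, floor=floor)

    def summary(self) -> str:
        f = self.filter
        lines = [
            "Full-rank ridge encoding model",
            "=" * 48,
            f"delays D                {f.n_delays}",
            f"embedding dims N        {f.embed_dim}",
            f"channels C              {f.n_channels}",
            f"parameters per channel  {f.n_delays * f.embed_dim}",
            f"lambda (median)         {np.median(self.lambdas):.4g}",
            f"lambda range            [{self.lambdas.min():.4g}, "
            f"{self.lambdas.max():.4g}]",
        ]
        return "\n".join(lines)
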