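"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorized/event-sparse
code paths: prediction is a direct double sum over time and delay on the
dense stimulus matrix, and tensor expansion is a per-entry triple loop.
"""

import numpy as np
import pytest

from tensortrf.cp import CPFilter
from tensortrf.design import SparseEmbeddingSeries


def dense_predict_oracle(F: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Direct FIR sum: out[t, c] = sum_d sum_n F[d, n, c] X[t-d, n]."""
    T = X.shape[0]
    D, _, C = F.shape
    out = np.zeros((T, C))
    for t in range(T):
        for d in range(D):
            if t - d >= 0:
                out[t] += X[t - d] @ F[d]
    return out


def expand_oracle(filt: CPFilter) -> np.ndarray:
    """Per-entry CP expansion by explicit summation over components."""
    D, N, C = filt.n_delays, filt.embed_dim, filt.n_channels
    F = np.zeros((D, N, C))
    for d in range(D):
        for n in range(N):
            for c in range(C):
                for r in range(filt.rank):
                    F[d, n, c] += (
                        filt.scales[r]
                        * filt.delay_factors[r, d]
                        * filt.embed_factors[r, n]
                        * filt.channel_factors[r, c]
                    )
    return F


def random_series(rng, T, N, n_events) -> SparseEmbeddingSeries:
    onsets = np.sort(rng.choice(T, size=min(n_events, T), replace=False))
    return SparseEmbeddingSeries(T, onsets, rng.normal(size=(onsets.size, N)))


def random_cp(rng, R, D, N, C, normalized=False) -> CPFilter:
    filt = CPFilter(
        rng.normal(size=(R, D)),
        rng.normal(size=(R, N)),
        rng.normal(size=(R, C)),
        rng.uniform(0.5, 2.0, size=R),
    )
    return filt.normalize() if normalized else filt


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
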