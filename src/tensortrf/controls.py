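"""Low-level control features and residualization.

Before asking what semantic structure a model captures, low-level covariates
of speech are removed from the recording: a log-mel spectrogram of the story
audio plus binary event series for word onsets and sentence starts/ends.  A
ridge-less full-rank regression of the recording on the lagged control
features (fit jointly over train and test data) is subtracted, and the
residual is re-z-scored per channel per story before any further model fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window, resample_poly

from .data import zscore
from .design import WordStream
from .fullrank import fit_ols

__all__ = [
    "MelConfig",
    "ControlFeatures",
    "logmel_features",
    "event_features",
    "build_control_design",
    "residualize",
]


@dataclass
class MelConfig:
    """Log-mel front end: 16 kHz analysis rate, 25 ms hop, 80 bands."""

    target_sr: int = 16_000
    hop_ms: float = 25.0
    n_mels: int = 80
    n_fft: int = 1024
    fmin: float = 0.0
    fmax: float | None = None  # default Nyquist
    floor_ratio: float = 1e-10  # log floor as a fraction of max power


@dataclass
class ControlFeatures:
    """``T x P`` control matrix aligned to the recording grid."""

    series: np.ndarray
    feature_names: list[str]
    delays_used: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.series = np.atleast_2d(np.asarray(self.series, dtype=np.float64))
        if self.series.shape[1] != len(self.feature_names):
            raise ValueError("one name required per feature column")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("control features contain non-finite values")


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, sr: int, fmin: float = 0.0, fmax: float | None = None
) -> np.ndarray:
    """Triangular mel filterbank (HTK mel scale), shape ``n_mels x (n_fft//2+1)``."""
    fmax = fmax or sr / 2
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    fb = np.zeros((n_mels, freqs.size))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def logmel_features(
    audio: np.ndarray,
    sr: int,
    out_rate_hz: float = 50.0,
    out_length: int | None = None,
    cfg: MelConfig | None = None,
) -> np.ndarray:
    """Log-mel spectrogram frames interpolated onto the recording grid.

    The waveform is resampled to ``cfg.target_sr``, framed with a Hann window
    of ``n_fft`` samples every ``hop_ms``, converted to mel power, floored at
    ``floor_ratio`` of the maximum power, and log-transformed.  Frames are
    then linearly interpolated at the output-grid sample times.

    Returns a ``T x n_mels`` matrix (``T = out_length`` when given).
    """
    cfg = cfg or MelConfig()
    audio = np.asarray(audio, dtype=np.float64)
    if audio.ndim != 1:
        raise ValueError("audio must be mono")
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio contains non-finite samples")
    if sr != cfg.target_sr:
        from math import gcd

        g = gcd(int(cfg.target_sr), int(sr))
        audio = resample_poly(audio, cfg.target_sr // g, sr // g)
        sr = cfg.target_sr
    hop = int(round(cfg.hop_ms / 1000.0 * sr))
    n_fft = cfg.n_fft
    if audio.size < n_fft:
        audio = np.pad(audio, (0, n_fft - audio.size))
    n_frames = 1 + (audio.size - n_fft) // hop
    win = get_window("hann", n_fft, fftbins=True)
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    spec = np.abs(np.fft.rfft(audio[idx] * win, axis=1)) ** 2
    fb = mel_filterbank(cfg.n_mels, n_fft, sr, cfg.fmin, cfg.fmax)
    mel = spec @ fb.T  # frames x n_mels
    eps = cfg.floor_ratio * max(mel.max(), 1e-300)
    logmel = np.log(np.maximum(mel, eps))
    # frame k is centred at (k*hop + n_fft/2) / sr seconds
    frame_t = (np.arange(n_frames) * hop + n_fft / 2) / sr
    duration = audio.size / sr
    T = out_length or int(round(duration * out_rate_hz))
    grid_t = np.arange(T) / out_rate_hz
    out = np.empty((T, cfg.n_mels))
    for b in range(cfg.n_mels):
        out[:, b] = np.interp(grid_t, frame_t, logmel[:, b])
    return out


def event_features(stream: WordStream, length: int) -> ControlFeatures:
    """Binary word-onset / sentence-start / sentence-end series, ``T x 3``."""
    if len(stream) and stream.onsets.max() >= length:
        raise ValueError(f"{stream.story_id}: onset beyond length {length}")
    out = np.zeros((length, 3))
    out[stream.onsets, 0] = 1.0
    out[stream.onsets[stream.sentence_start], 1] = 1.0
    out[stream.onsets[stream.sentence_end], 2] = 1.0
    return ControlFeatures(out, ["word_onset", "sentence_start", "sentence_end"])


def _lag_matrix(X: np.ndarray, n_delays: int) -> np.ndarray:
    T, P = X.shape
    out = np.zeros((T, n_delays * P))
    for d in range(n_delays):
        out[d:, d * P : (d + 1) * P] = X[: T - d]
    return out


def build_control_design(
    stream: WordStream,
    length: int,
    logmel: np.ndarray | None = None,
    mel_delays: int = 15,
    event_delays: int = 1,
) -> np.ndarray:
    """Lagged control design for one story.

    The spectrogram enters with ``mel_delays`` lags (15 at 50 Hz covers
    300 ms); the binary event features enter unlagged by default
    (``event_delays`` raises that if wanted).
    """
    ev = event_features(stream, length).series
    parts = [_lag_matrix(ev, event_delays) if event_delays > 1 else ev]
    if logmel is not None:
        if logmel.shape[0] != length:
            raise ValueError("log-mel frames not aligned to recording grid")
        parts.append(_lag_matrix(logmel, mel_delays))
    return np.hstack(parts)


def residualize(
    recordings: list[np.ndarray],
    control_designs: list[np.ndarray],
    fit_rows: list[np.ndarray] | None = None,
    renormalize: bool = True,
):
    """Regress lagged control features out of the recordings.

    An ordinary least-squares fit of the stacked recordings on the stacked
    control designs (an intercept column is appended) is computed over all
    provided stories — train and test jointly, which is the default study
    protocol; pass ``fit_rows`` (per-story boolean masks) for a strict
    train-only fit.  The control prediction is subtracted everywhere and, when
    ``renormalize``, each residual story is re-z-scored per channel.

    Returns
    -------
    residuals : list of ndarray
    weights : ndarray
        OLS weights including the final intercept row.
    """
    if len(recordings) != len(control_designs):
        raise ValueError("one control design required per recording")
    designs = []
    for M, X in zip(recordings, control_designs):
        if M.shape[0] != X.shape[0]:
            raise ValueError("control design not aligned to recording")
        designs.append(np.hstack([X, np.ones((X.shape[0], 1))]))
    stacked_X = np.vstack(designs)
    stacked_Y = np.vstack(recordings)
    if fit_rows is not None:
        mask = np.concatenate(fit_rows)
        weights = fit_ols(stacked_X[mask], stacked_Y[mask])
    else:
        weights = fit_ols(stacked_X, stacked_Y)
    residuals = []
    for M, X in zip(recordings, designs):
        r = np.asarray(M, dtype=np.float64) - X @ weights
        residuals.append(zscore(r) if renormalize else r)
    return residuals, weights
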