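"""Synthetic data with the statistical structure the encoding model assumes.

Emulates the study conditions end to end so every stage is testable without
the original recordings: Poisson-like word onsets (geometric inter-word gaps),
low-dimensional Gaussian word embeddings, a smooth ground-truth CP filter,
white Gaussian channel noise, and repeated presentations of a held-out story.

What this generator does NOT emulate: correlated sensor noise, realistic
sensor geometry or lead fields, prosody, or any audio waveform structure.
Word timing is a memoryless point process; real speech is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cp import CPFilter, predict_lowrank
from .data import Story, StoryDataset, StoryRecording
from .design import EmbeddingSet, WordStream, build_series
from .evaluation import RepeatSet

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_word_stream",
    "generate_ground_truth",
    "simulate_recording",
    "simulate_repeats",
    "simulate_dataset",
]

# substream labels to decorrelate the per-purpose RNGs
_STREAM, _NOISE, _TRUTH = 1, 2, 3


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Parameters
    ----------
    n_stories : int
        Number of training stories.
    samples_per_story : int
        T, length of each story in samples.
    n_channels, embed_dim, n_delays, rank : int
        C, N, D and the ground-truth rank R.
    mean_word_gap : float
        Mean inter-word gap in samples (geometric law).  20 samples at 50 Hz
        is a word every 400 ms, a natural speech rate.
    noise_sd : float
        Per-channel white-noise standard deviation.
    n_repeats : int
        Repeat count for the held-out story (noise ceiling needs >= 2).
    seed : int
        Master seed; all outputs are bit-reproducible given the config.
    embed_decay : float
        Ratio of the geometric eigenvalue decay of the embedding covariance,
        mimicking the effectively low-dimensional embeddings of LLMs.
    """

    n_stories: int = 3
    samples_per_story: int = 10_000
    n_channels: int = 20
    embed_dim: int = 15
    n_delays: int = 10
    rank: int = 3
    mean_word_gap: float = 20.0
    noise_sd: float = 0.5
    n_repeats: int = 5
    seed: int = 0
    embed_decay: float = 0.85

    def __post_init__(self) -> None:
        for name in ("n_stories", "samples_per_story", "n_channels",
                     "embed_dim", "n_delays", "rank", "n_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mean_word_gap < 1:
            raise ValueError("mean_word_gap must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_delays > self.samples_per_story:
            raise ValueError("n_delays cannot exceed samples_per_story")
        if not 0 < self.embed_decay <= 1:
            raise ValueError("embed_decay must be in (0, 1]")

    @property
    def embed_variances(self) -> np.ndarray:
        """Diagonal embedding covariance with geometric eigenvalue decay."""
        v = self.embed_decay ** np.arange(self.embed_dim)
        return v / v.mean()  # unit average variance


@dataclass
class GroundTruth:
    """The generating CP filter plus the embedding covariance used to draw words."""

    filter: CPFilter
    embed_variances: np.ndarray


def _rng(cfg: SimConfig, *labels: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *labels])


def generate_word_stream(
    cfg: SimConfig, story_index: int = 0
) -> tuple[WordStream, EmbeddingSet]:
    """Draw one story's word events and their embeddings.

    Inter-onset gaps are geometric with mean ``mean_word_gap``; the first
    onset is forced into ``[0, T)`` so a story never has zero words.  Sentence
    lengths are uniform on [4, 15] words, with the first word of each sentence
    flagged start and the last flagged end.  Deterministic given
    ``(cfg.seed, story_index)``.
    """
    T = cfg.samples_per_story
    if T < 1:
        raise ValueError("samples_per_story too small to place a word")
    rng = _rng(cfg, _STREAM, story_index)
    p = min(1.0, 1.0 / cfg.mean_word_gap)
    # draw generously, then truncate at T
    n_guess = max(16, int(3 * T / cfg.mean_word_gap) + 8)
    gaps = rng.geometric(p, size=n_guess)
    onsets = np.cumsum(gaps) - 1  # first onset = first gap - 1, in [0, inf)
    while onsets[-1] < T:  # pragma: no cover - extremely short draws
        extra = rng.geometric(p, size=n_guess)
        onsets = np.concatenate([onsets, onsets[-1] + 1 + np.cumsum(extra) - 1])
    onsets = onsets[onsets < T]
    if onsets.size == 0:
        onsets = np.array([min(int(gaps[0]) - 1, T - 1)], dtype=np.int64)
    S = onsets.size

    # Markov sentence process: i.i.d. uniform sentence lengths on [4, 15]
    starts = np.zeros(S, dtype=bool)
    ends = np.zeros(S, dtype=bool)
    pos = 0
    while pos < S:
        length = int(rng.integers(4, 16))
        starts[pos] = True
        ends[min(pos + length - 1, S - 1)] = True
        pos += length

    std = np.sqrt(cfg.embed_variances)
    emb = rng.normal(size=(S, cfg.embed_dim)) * std
    words = [f"w{story_index:02d}_{j:05d}" for j in range(S)]
    stream = WordStream(words, onsets, starts, ends, story_id=f"story_{story_index:03d}")
    return stream, EmbeddingSet(emb, provenance="synthetic")


def _smooth_bumps(rng: np.random.Generator, rank: int, n_delays: int) -> np.ndarray:
    """Randomized Gaussian bumps over the delay axis, one row per component."""
    d = np.arange(n_delays)
    centers = rng.uniform(0.15 * n_delays, 0.85 * n_delays, size=rank)
    widths = rng.uniform(0.08 * n_delays, 0.25 * n_delays, size=rank)
    U = np.exp(-0.5 * ((d[None, :] - centers[:, None]) / widths[:, None]) ** 2)
    return U


def generate_ground_truth(
    cfg: SimConfig, scales: np.ndarray | None = None
) -> GroundTruth:
    """Draw a normalized ground-truth CP filter.

    Delay factors are smooth Gaussian bumps; embedding and channel factors are
    random unit directions; ``scales`` defaults to ``rank .. 1`` so components
    are well separated in amplitude.  Deterministic given ``cfg.seed``.
    """
    rng = _rng(cfg, _TRUTH)
    R = cfg.rank
    U_D = _smooth_bumps(rng, R, cfg.n_delays)
    U_E = rng.normal(size=(R, cfg.embed_dim))
    U_C = rng.normal(size=(R, cfg.n_channels))
    if scales is None:
        scales = np.arange(R, 0, -1, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if scales.shape != (R,) or np.any(scales <= 0):
        raise ValueError("scales must be R positive values")
    filt = CPFilter(U_D, U_E, U_C, np.ones(R)).normalize()
    filt = CPFilter(
        filt.delay_factors, filt.embed_factors, filt.channel_factors,
        scales, normalized=True,
    )
    return GroundTruth(filt, cfg.embed_variances)


def _signal(stream: WordStream, emb: EmbeddingSet, truth: GroundTruth,
            cfg: SimConfig) -> np.ndarray:
    series = build_series(stream, emb, cfg.samples_per_story)
    if series.dim != truth.filter.embed_dim:
        raise ValueError(
            f"embedding dim {series.dim} != ground-truth dim "
            f"{truth.filter.embed_dim}"
        )
    return predict_lowrank(truth.filter, series)


def simulate_recording(
    stream: WordStream,
    emb: EmbeddingSet,
    truth: GroundTruth,
    cfg: SimConfig,
    story_index: int = 0,
) -> StoryRecording:
    """Forward-model recording: CP-filter prediction plus white channel noise.

    The output is NOT z-scored; normalization is an explicit separate step.
    """
    signal = _signal(stream, emb, truth, cfg)
    rng = _rng(cfg, _NOISE, story_index)
    noise = rng.normal(0.0, cfg.noise_sd, size=signal.shape) if cfg.noise_sd else 0.0
    return StoryRecording(signal + noise, story_id=stream.story_id)


def simulate_repeats(
    stream: WordStream,
    emb: EmbeddingSet,
    truth: GroundTruth,
    cfg: SimConfig,
    story_index: int = 10_000,
) -> RepeatSet:
    """Repeat presentations: one deterministic signal, fresh noise per repeat."""
    if cfg.n_repeats < 2:
        raise ValueError("n_repeats must be >= 2 (noise ceiling undefined)")
    signal = _signal(stream, emb, truth, cfg)
    reps = np.empty((cfg.n_repeats, *signal.shape))
    for i in range(cfg.n_repeats):
        rng = _rng(cfg, _NOISE, story_index, i)
        noise = rng.normal(0.0, cfg.noise_sd, size=signal.shape) if cfg.noise_sd else 0.0
        reps[i] = signal + noise
    return RepeatSet(reps)


def simulate_dataset(
    cfg: SimConfig,
    truth: GroundTruth | None = None,
    zscore_recordings: bool = False,
) -> tuple[StoryDataset, GroundTruth]:
    """Full study-shaped dataset: training stories plus a held-out repeat story.

    The test story uses story index ``n_stories`` (never a training index), so
    no training sample leaks into the evaluation set.
    """
    truth = truth or generate_ground_truth(cfg)
    stories = []
    for i in range(cfg.n_stories):
        stream, emb = generate_word_stream(cfg, i)
        rec = simulate_recording(stream, emb, truth, cfg, story_index=i)
        if zscore_recordings:
            rec = rec.zscored_copy()
        stories.append(Story(rec, stream, emb))
    t_idx = cfg.n_stories
    t_stream, t_emb = generate_word_stream(cfg, t_idx)
    repeats = simulate_repeats(t_stream, t_emb, truth, cfg, story_index=t_idx)
    test_story = Story(
        StoryRecording(repeats.mean(), story_id=t_stream.story_id),
        t_stream,
        t_emb,
    )
    return (
        StoryDataset(stories, test_story=test_story, test_repeats=repeats),
        truth,
    )
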