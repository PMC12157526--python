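"""In-memory containers pairing recordings with word streams and embeddings."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import EmbeddingSet, SparseEmbeddingSeries, WordStream, build_series
from .evaluation import RepeatSet

__all__ = ["StoryRecording", "Story", "StoryDataset", "zscore"]


def zscore(data: np.ndarray, axis: int = 0, eps: float = 1e-12) -> np.ndarray:
    """Standardize to zero mean and unit variance along ``axis``.

    Constant columns are left at zero rather than dividing by zero.
    """
    data = np.asarray(data, dtype=np.float64)
    mu = data.mean(axis=axis, keepdims=True)
    sd = data.std(axis=axis, keepdims=True)
    return (data - mu) / np.where(sd < eps, 1.0, sd)


@dataclass
class StoryRecording:
    """One story's ``T x C`` neural matrix with sampling rate and state."""

    data: np.ndarray
    rate_hz: float = 50.0
    zscored: bool = False
    story_id: str = "story"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("recording must be T x C")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.story_id}: recording has non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def zscored_copy(self) -> "StoryRecording":
        """Per-channel z-scored copy (the normalization applied per story)."""
        return StoryRecording(
            zscore(self.data), self.rate_hz, zscored=True, story_id=self.story_id
        )


@dataclass
class Story:
    """Aligned (recording, word stream, embeddings) triple for one story."""

    recording: StoryRecording
    stream: WordStream
    embeddings: EmbeddingSet

    def __post_init__(self) -> None:
        if len(self.stream) != self.embeddings.n_words:
            raise ValueError(
                f"{self.stream.story_id}: {self.embeddings.n_words} embedding "
                f"rows for {len(self.stream)} words"
            )
        if len(self.stream) and self.stream.onsets.max() >= self.recording.n_samples:
            raise ValueError(
                f"{self.stream.story_id}: onset beyond recording length"
            )

    def series(self) -> SparseEmbeddingSeries:
        return build_series(self.stream, self.embeddings, self.recording.n_samples)


@dataclass
class StoryDataset:
    """A set of training stories plus an optional held-out repeat story."""

    stories: list[Story]
    rate_hz: float = 50.0
    test_story: Story | None = None
    test_repeats: RepeatSet | None = None

    def recordings(self) -> list[np.ndarray]:
        return [s.recording.data for s in self.stories]

    def series_list(self) -> list[SparseEmbeddingSeries]:
        return [s.series() for s in self.stories]

    def stacked_embeddings(self) -> np.ndarray:
        return np.vstack([s.embeddings.matrix for s in self.stories])
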