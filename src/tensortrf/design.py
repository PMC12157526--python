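"""Stimulus design: word streams, sparse embedding time series, lagged designs, PCA.

The encoding model treats each word as a point event carrying an embedding
vector.  The stimulus for a story of ``T`` samples is a conceptually dense
``T x N`` matrix that is zero everywhere except at word-onset samples, where it
holds the word's embedding.  Because words are sparse in time, the series is
stored as (onset, embedding-row) events and only densified on demand.

Conventions
-----------
* Sample indices are 0-based.
* Delay ``d = 0`` means "at word onset"; a filter with ``D`` delays acts on the
  window ``[tau, tau + D - 1]`` after an onset at ``tau``.
* Story starts are zero-padded: predictions never look before sample 0.
* Two words sharing an onset sample collapse to one event whose embedding is
  their sum (forced by linearity of the model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class WordStream:
    """Ordered word events of one story.

    Parameters
    ----------
    words : list of str
        The tokens, in spoken order.
    onsets : ndarray of int
        Onset sample of each word, non-decreasing, each in ``[0, T)`` of the
        paired recording.
    sentence_start, sentence_end : ndarray of bool
        Flags marking the first/last word of each sentence.
    story_id : str
        Identifier used for alignment checks and error messages.
    """

    words: list[str]
    onsets: np.ndarray
    sentence_start: np.ndarray
    sentence_end: np.ndarray
    story_id: str = "story"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.sentence_start = np.asarray(self.sentence_start, dtype=bool)
        self.sentence_end = np.asarray(self.sentence_end, dtype=bool)
        n = len(self.words)
        for name in ("onsets", "sentence_start", "sentence_end"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"{self.story_id}: {name} has length "
                    f"{len(getattr(self, name))}, expected {n}"
                )
        if n and np.any(np.diff(self.onsets) < 0):
            raise ValueError(f"{self.story_id}: onsets must be non-decreasing")
        if n and self.onsets[0] < 0:
            raise ValueError(f"{self.story_id}: negative onset")

    def __len__(self) -> int:
        return len(self.words)


@dataclass
class EmbeddingSet:
    """Per-word embedding matrix paired with a :class:`WordStream`.

    ``matrix`` is ``S x N``: one row per word.  ``context_len`` records how many
    preceding words conditioned each embedding (purely provenance here; the
    embeddings are taken as given numeric input).
    """

    matrix: np.ndarray
    context_len: int = 20
    provenance: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def n_words(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SparseEmbeddingSeries:
    """Event-sparse stimulus series: ``T x N`` matrix stored as events.

    ``onsets`` are strictly increasing (duplicates have been merged by
    summation) and ``embeddings`` holds one row per event.
    """

    length: int
    onsets: np.ndarray
    embeddings: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.embeddings = np.atleast_2d(np.asarray(self.embeddings, dtype=np.float64))
        if self.onsets.size == 0:
            self.embeddings = self.embeddings.reshape(0, self.embeddings.shape[-1])
        if self.embeddings.shape[0] != self.onsets.size:
            raise ValueError("one embedding row required per event")
        if self.onsets.size and (
            self.onsets.min() < 0 or self.onsets.max() >= self.length
        ):
            raise ValueError("event onset outside [0, length)")
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]

    @property
    def n_events(self) -> int:
        return self.onsets.size

    def to_dense(self) -> np.ndarray:
        """Materialize the ``T x N`` stimulus matrix."""
        X = np.zeros((self.length, self.dim))
        X[self.onsets] = self.embeddings
        return X


def build_series(
    stream: WordStream, emb: EmbeddingSet, length: int
) -> SparseEmbeddingSeries:
    """Build the sparse stimulus series for one story.

    Words sharing a sample are merged into a single event whose embedding is
    the sum of the words' embeddings.
    """
    if emb.n_words != len(stream):
        raise ValueError(
            f"{stream.story_id}: {emb.n_words} embedding rows for "
            f"{len(stream)} words"
        )
    if len(stream) and stream.onsets.max() >= length:
        raise ValueError(
            f"{stream.story_id}: onset {stream.onsets.max()} >= length {length}"
        )
    if len(stream) == 0:
        return SparseEmbeddingSeries(length, np.empty(0, dtype=np.int64),
                                     np.empty((0, emb.dim)))
    uniq, inverse = np.unique(stream.onsets, return_inverse=True)
    merged = np.zeros((uniq.size, emb.dim))
    np.add.at(merged, inverse, emb.matrix)
    return SparseEmbeddingSeries(length, uniq, merged)


def lagged_dense_design(series: SparseEmbeddingSeries, n_delays: int) -> np.ndarray:
    """Dense ``T x (D*N)`` lagged design for the full-rank solver.

    Row ``t``, block ``d`` holds ``X[t - d]`` with zero padding for ``t < d``.
    The low-rank path never calls this; it consumes the sparse form directly.
    """
    if n_delays < 1:
        raise ValueError("n_delays must be >= 1")
    if n_delays > series.length:
        raise ValueError(
            f"n_delays={n_delays} exceeds series length {series.length}"
        )
    T, N = series.length, series.dim
    X = series.to_dense()
    out = np.zeros((T, n_delays * N))
    for d in range(n_delays):
        out[d:, d * N : (d + 1) * N] = X[: T - d]
    return out


class EmbeddingPCA:
    """PCA reducer for word embeddings, fit on training stories only.

    Retains the smallest number of components whose cumulative explained
    variance ratio reaches ``variance_threshold``.  Rotation only — components
    are not whitened.

    Attributes
    ----------
    components : ndarray, ``N x K``
        Orthonormal basis columns.
    mean : ndarray, ``N``
        Training mean subtracted before projection.
    explained_variance_ratio : ndarray, ``K``
    """

    def __init__(self, variance_threshold: float = 0.95):
        if not 0.0 < variance_threshold <= 1.0:
            raise ValueError("variance_threshold must be in (0, 1]")
        self.variance_threshold = variance_threshold
        self.components: np.ndarray | None = None
        self.mean: np.ndarray | None = None
        self.explained_variance_ratio: np.ndarray | None = None

    def fit(self, train_embeddings: np.ndarray) -> "EmbeddingPCA":
        X = np.asarray(train_embeddings, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 rows")
        if np.allclose(X, X[0], atol=0.0, rtol=0.0) or np.allclose(
            X.var(axis=0).sum(), 0.0
        ):
            raise ValueError("degenerate (constant) embeddings: PCA undefined")
        pca = PCA(n_components=None, svd_solver="full")
        pca.fit(X)
        cum = np.cumsum(pca.explained_variance_ratio_)
        # float tolerance so threshold=1.0 resolves to the numerical rank
        k = int(np.searchsorted(cum, self.variance_threshold - 1e-9) + 1)
        k = min(k, cum.size)
        self.components = pca.components_[:k].T.copy()
        self.mean = pca.mean_.copy()
        self.explained_variance_ratio = pca.explained_variance_ratio_[:k].copy()
        return self

    @property
    def n_components(self) -> int:
        if self.components is None:
            raise RuntimeError("reducer not fit")
        return self.components.shape[1]

    def transform_matrix(self, matrix: np.ndarray) -> np.ndarray:
        if self.components is None:
            raise RuntimeError("reducer not fit")
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.shape[1] != self.mean.size:
            raise ValueError(
                f"embedding dim {matrix.shape[1]} != fitted dim {self.mean.size}"
            )
        return (matrix - self.mean) @ self.components

    def transform(self, emb: EmbeddingSet) -> EmbeddingSet:
        """Project an :class:`EmbeddingSet` onto the retained components."""
        return EmbeddingSet(
            self.transform_matrix(emb.matrix),
            context_len=emb.context_len,
            provenance=f"{emb.provenance}|pca{self.n_components}",
        )


def fit_pca(train_embeddings: np.ndarray, variance_threshold: float = 0.95) -> EmbeddingPCA:
    """Functional wrapper: fit an :class:`EmbeddingPCA` on stacked training rows."""
    return EmbeddingPCA(variance_threshold).fit(train_embeddings)


def read_transcript_tsv(path, rate_hz: float, story_id: str | None = None) -> WordStream:
    """Read a word-timing transcript.

    Expected columns: ``word``, ``onset_seconds``, ``sentence_start``,
    ``sentence_end``.  Onsets are converted to sample indices at ``rate_hz``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"word", "onset_seconds", "sentence_start", "sentence_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transcript missing columns: {sorted(missing)}")
    onsets = np.round(df["onset_seconds"].to_numpy(dtype=float) * rate_hz).astype(
        np.int64
    )
    return WordStream(
        words=[str(w) for w in df["word"]],
        onsets=onsets,
        sentence_start=df["sentence_start"].to_numpy(dtype=bool),
        sentence_end=df["sentence_end"].to_numpy(dtype=bool),
        story_id=story_id or str(path),
    )
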