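"""Characterize fitted CP components.

Three lenses on a normalized rank-R filter:

* component weight timecourses ``W[r, t] = alpha_r * sum_{n,d} U_D[r,d]
  U_E[r,n] X[t-d, n]`` — the strength of each component's channel pattern in
  the prediction at every sample (``pred = W' @ U_C`` exactly);
* most-activating contexts — corpus snippets whose embeddings have the
  largest (or most negative) dot product with a component's embedding factor;
* normalized power over the delay and channel modes,
  ``Q_D[d] = sum_r alpha_r^2 U_D[r,d]^2`` (and analogously over channels),
  reported as ``P = Q / ||Q||``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cp import CPFilter, _component_timecourses
from .design import SparseEmbeddingSeries

__all__ = [
    "component_weights",
    "top_contexts",
    "delay_power",
    "channel_power",
    "ComponentProfile",
    "profile_components",
]


def component_weights(filt: CPFilter, series: SparseEmbeddingSeries) -> np.ndarray:
    """Per-component weight timecourses, shape ``R x T``.

    Satisfies the reconstruction identity
    ``prediction[t, c] = sum_r W[r, t] * channel_factors[r, c]``.
    """
    if not filt.normalized:
        raise ValueError("component weights are defined on a normalized filter")
    return _component_timecourses(filt, series).T


def top_contexts(
    filt: CPFilter,
    corpus_contexts: list[tuple[str, np.ndarray]],
    k: int = 5,
    sign: str = "positive",
) -> list[list[tuple[str, float]]]:
    """Most-activating corpus contexts per component.

    Scores are raw dot products between each context embedding and the
    component's embedding factor; ``sign='negative'`` returns the most
    negative instead.  Ties break by corpus order.

    Returns one ranked ``[(text, score), ...]`` list per component.
    """
    if len(corpus_contexts) == 0:
        raise ValueError("empty context corpus")
    if k > len(corpus_contexts):
        raise ValueError(f"k={k} exceeds corpus size {len(corpus_contexts)}")
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    texts = [t for t, _ in corpus_contexts]
    E = np.asarray([e for _, e in corpus_contexts], dtype=np.float64)
    if E.shape[1] != filt.embed_dim:
        raise ValueError(
            f"context embedding dim {E.shape[1]} != filter dim {filt.embed_dim}"
        )
    scores = E @ filt.embed_factors.T  # corpus x R
    out = []
    for r in range(filt.rank):
        s = scores[:, r] if sign == "positive" else -scores[:, r]
        # stable sort on descending score; equal scores keep corpus order
        order = np.argsort(-s, kind="stable")[:k]
        out.append([(texts[i], float(scores[i, r])) for i in order])
    return out


def _mode_power(filt: CPFilter, factors: np.ndarray, normalization: str) -> np.ndarray:
    if not filt.normalized:
        raise ValueError("power analysis is defined on a normalized filter")
    q = np.sum((filt.scales[:, None] ** 2) * factors**2, axis=0)
    total = np.linalg.norm(q) if normalization == "euclidean" else q.sum()
    if total == 0:
        raise ValueError("all-zero filter: power undefined")
    return q / total


def delay_power(filt: CPFilter, normalization: str = "euclidean") -> np.ndarray:
    """Normalized power over delays, ``P_D = Q_D / ||Q_D||``."""
    return _mode_power(filt, filt.delay_factors, normalization)


def channel_power(filt: CPFilter, normalization: str = "euclidean") -> np.ndarray:
    """Normalized power over channels, ``P_C = Q_C / ||Q_C||``."""
    return _mode_power(filt, filt.channel_factors, normalization)


@dataclass
class ComponentProfile:
    """Full interpretation bundle for one fitted filter."""

    scales: np.ndarray
    influence: np.ndarray | None
    order: np.ndarray
    top_positive: list
    top_negative: list
    delay_power: np.ndarray
    channel_power: np.ndarray


def profile_components(
    filt: CPFilter,
    corpus_contexts: list[tuple[str, np.ndarray]] | None = None,
    influence: np.ndarray | None = None,
    k: int = 5,
) -> ComponentProfile:
    """Assemble the interpretation report for a fitted filter.

    Components are ordered by leave-one-out influence (descending) when given,
    otherwise by scale; ties break by component index.
    """
    key = influence if influence is not None else filt.scales
    order = np.argsort(-np.asarray(key), kind="stable")
    pos = neg = []
    if corpus_contexts:
        pos = top_contexts(filt, corpus_contexts, k=k, sign="positive")
        neg = top_contexts(filt, corpus_contexts, k=k, sign="negative")
    return ComponentProfile(
        scales=filt.scales,
        influence=influence,
        order=order,
        top_positive=pos,
        top_negative=neg,
        delay_power=delay_power(filt),
        channel_power=channel_power(filt),
    )
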