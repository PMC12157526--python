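"""HDF5 persistence for datasets, filters and reports.

Dataset schema: one group per story (``story_000`` ...) holding ``recording``
(T x C), ``onsets``, ``embeddings`` (S x N), ``sentence_start``,
``sentence_end`` and a ``words`` string dataset; root attributes carry the
sampling rate.  An optional ``test`` group holds the held-out story plus its
``repeats`` (n_rep x T x C).  A JSON sidecar stores the generating or run
configuration when one exists.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .cp import CPFilter
from .data import Story, StoryDataset, StoryRecording
from .design import EmbeddingSet, WordStream
from .evaluation import RepeatSet
from .fullrank import FullFilter

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_cp_filter",
    "load_cp_filter",
    "save_full_filter",
    "load_full_filter",
    "write_json",
]


def write_json(path, obj) -> None:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def _write_story(grp: h5py.Group, story: Story) -> None:
    grp.create_dataset("recording", data=story.recording.data)
    grp.create_dataset("onsets", data=story.stream.onsets)
    grp.create_dataset("embeddings", data=story.embeddings.matrix)
    grp.create_dataset("sentence_start", data=story.stream.sentence_start)
    grp.create_dataset("sentence_end", data=story.stream.sentence_end)
    grp.create_dataset(
        "words", data=np.array(story.stream.words, dtype=h5py.string_dtype())
    )
    grp.attrs["story_id"] = story.stream.story_id
    grp.attrs["zscored"] = story.recording.zscored
    grp.attrs["context_len"] = story.embeddings.context_len


def _read_story(grp: h5py.Group, rate_hz: float) -> Story:
    story_id = str(grp.attrs.get("story_id", grp.name.strip("/")))
    rec = np.asarray(grp["recording"])
    onsets = np.asarray(grp["onsets"])
    words = [w.decode() if isinstance(w, bytes) else str(w) for w in grp["words"]]
    emb = np.asarray(grp["embeddings"])
    if emb.shape[0] != len(words):
        raise ValueError(
            f"{story_id}: {emb.shape[0]} embedding rows for {len(words)} words"
        )
    if onsets.size and onsets.max() >= rec.shape[0]:
        raise ValueError(f"{story_id}: onset beyond recording length")
    stream = WordStream(
        words,
        onsets,
        np.asarray(grp["sentence_start"]),
        np.asarray(grp["sentence_end"]),
        story_id=story_id,
    )
    recording = StoryRecording(
        rec, rate_hz, zscored=bool(grp.attrs.get("zscored", False)),
        story_id=story_id,
    )
    return Story(
        recording,
        stream,
        EmbeddingSet(emb, context_len=int(grp.attrs.get("context_len", 20))),
    )


def save_dataset(path, dataset: StoryDataset, config=None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["rate_hz"] = dataset.rate_hz
        f.attrs["n_stories"] = len(dataset.stories)
        for i, story in enumerate(dataset.stories):
            _write_story(f.create_group(f"story_{i:03d}"), story)
        if dataset.test_story is not None:
            grp = f.create_group("test")
            _write_story(grp, dataset.test_story)
            if dataset.test_repeats is not None:
                grp.create_dataset("repeats", data=dataset.test_repeats.repeats)
    if config is not None:
        write_json(path.with_suffix(".json"), config)


def load_dataset(path) -> StoryDataset:
    """Load and validate a dataset container.

    Alignment checks (onsets in range, embedding rows matching word counts)
    run per story; the first violation raises with the story id named.
    """
    with h5py.File(path, "r") as f:
        rate = float(f.attrs["rate_hz"])
        n = int(f.attrs["n_stories"])
        stories = [_read_story(f[f"story_{i:03d}"], rate) for i in range(n)]
        test_story = None
        repeats = None
        if "test" in f:
            test_story = _read_story(f["test"], rate)
            if "repeats" in f["test"]:
                repeats = RepeatSet(np.asarray(f["test"]["repeats"]))
    return StoryDataset(stories, rate_hz=rate, test_story=test_story,
                        test_repeats=repeats)


def save_cp_filter(path, filt: CPFilter, metadata: dict | None = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("U_D", data=filt.delay_factors)
        f.create_dataset("U_E", data=filt.embed_factors)
        f.create_dataset("U_C", data=filt.channel_factors)
        f.create_dataset("alpha", data=filt.scales)
        f.attrs["normalized"] = filt.normalized
    if metadata is not None:
        write_json(path.with_suffix(".json"), metadata)


def load_cp_filter(path) -> CPFilter:
    with h5py.File(path, "r") as f:
        return CPFilter(
            np.asarray(f["U_D"]),
            np.asarray(f["U_E"]),
            np.asarray(f["U_C"]),
            np.asarray(f["alpha"]),
            normalized=bool(f.attrs["normalized"]),
        )


def save_full_filter(path, filt: FullFilter, lambdas=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("tensor", data=filt.tensor)
        if lambdas is not None:
            f.create_dataset("lambda", data=np.asarray(lambdas))


def load_full_filter(path):
    with h5py.File(path, "r") as f:
        lam = np.asarray(f["lambda"]) if "lambda" in f else None
        return FullFilter(np.asarray(f["tensor"])), lam
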