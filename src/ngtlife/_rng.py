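"""Seed plumbing.

Every source of randomness in the package flows from one integer seed via
``numpy.random.SeedSequence`` spawn keys.  Streams are named, and per-record
generators are keyed by the record index, so regenerating a single image does
not depend on how many other images were drawn before it.
"""

from __future__ import annotations

import numpy as np

# stable stream identifiers; order is part of the reproducibility contract
_STREAMS = {
    "manifest": 0,
    "render": 1,
    "embed": 2,
    "drift": 3,
    "split": 4,
    "train": 5,
    "tune": 6,
    "monitor": 7,
    "bootstrap": 8,
    "reduce": 9,
    "ratings": 10,
}


def stream_rng(seed: int, stream: str, index: int | None = None) -> np.random.Generator:
    """Generator for a named stream (optionally keyed per record)."""
    key = (_STREAMS[stream],) if index is None else (_STREAMS[stream], int(index))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def child_seed(seed: int, stream: str, index: int = 0) -> int:
    """A derived integer seed (< 2**31) for libraries that want one."""
    return int(stream_rng(seed, stream, index).integers(2**31))
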