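"""Shared in-memory containers.

A cohort manifest is an ordinary :class:`pandas.DataFrame` with the column
schema in :data:`ngtlife.io.MANIFEST_COLUMNS` (one row per image record).
Latent embeddings travel as :class:`EmbeddingSet`: an ``n x d`` matrix with
row-aligned record ids, labels and metadata tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the three tube-position classes, in canonical order
CLASSES = ("satisfactory", "malpositioned", "bronchial")


@dataclass
class EmbeddingSet:
    """Latent vectors with aligned identifiers and metadata.

    Attributes
    ----------
    X : ndarray, shape (n, d)
        One latent vector per image.
    record_id : ndarray of str, shape (n,)
    labels : ndarray of str or None
        Tube-position class per row, when known.
    tags : DataFrame
        Row-aligned metadata (manufacturer, age, department, ...). May be
        empty.
    provenance : list of str
        Human-readable notes on how this set was produced/transformed.
    """

    X: np.ndarray
    record_id: np.ndarray
    labels: np.ndarray | None = None
    tags: pd.DataFrame = field(default_factory=pd.DataFrame)
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (n rows, d dims)")
        self.record_id = np.asarray(self.record_id)
        if len(self.record_id) != len(self.X):
            raise ValueError("record_id length must match X rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.X):
                raise ValueError("labels length must match X rows")
        if len(self.tags) not in (0, len(self.X)):
            raise ValueError("tags must be empty or row-aligned with X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def copy(self) -> "EmbeddingSet":
        return EmbeddingSet(
            X=self.X.copy(),
            record_id=self.record_id.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            tags=self.tags.copy(),
            provenance=list(self.provenance),
        )

    def take(self, idx) -> "EmbeddingSet":
        idx = np.asarray(idx)
        return EmbeddingSet(
            X=self.X[idx],
            record_id=self.record_id[idx],
            labels=None if self.labels is None else self.labels[idx],
            tags=self.tags.iloc[idx].reset_index(drop=True) if len(self.tags) else self.tags,
            provenance=list(self.provenance),
        )
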