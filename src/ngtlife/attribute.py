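"""Latent-embedding attribution: how much variance of a 2-D embedding each
metadata tag explains.

For each DICOM-style tag (manufacturer, patient age in days, department,
label, ...) we regress both embedding coordinates on the encoded tag by
least squares and report the pooled coefficient of determination

    R^2 = 1 - RSS_pooled / TSS_pooled,

where RSS and TSS are summed over the two coordinate columns (TSS about the
column means).  Numeric tags contribute one standardized column; categorical
tags contribute reference-level indicator columns (missing values become a
dedicated level).  Joint ("cumulative") R^2 regresses on the concatenation of
several encodings, solved by pseudoinverse so rank-deficient encodings are
safe.  No significance test is attached: with n in the thousands and effects
of interest around 0.05-0.6, the sampling error of R^2 is not the question
being asked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EncodedTag:
    """A tag encoded for regression: n x k design columns."""

    name: str
    kind: str  # "numeric" | "categorical"
    encoding: np.ndarray

    def __post_init__(self):
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown tag kind {self.kind!r}")
        self.encoding = np.asarray(self.encoding, dtype=float)
        if self.encoding.ndim == 1:
            self.encoding = self.encoding[:, None]


@dataclass
class AttributionResult:
    tag: str
    r2: float
    n: int
    rank: int | None = None


def encode_age(study_date, birth_date) -> int:
    """Patient age as the exact number of whole days between birth and study."""
    s = pd.Timestamp(study_date)
    b = pd.Timestamp(birth_date)
    if b > s:
        raise ValueError(f"birth date {birth_date} after study date {study_date}")
    return int((s - b).days)


def encode_tag(name: str, values, kind: str | None = None) -> EncodedTag:
    """Encode a raw tag column.

    Numeric tags are standardized to one column (constant columns become
    zeros).  Categorical tags become levels-1 indicator columns against the
    first (sorted) reference level; missing values form their own level.
    """
    ser = pd.Series(values)
    if kind is None:
        kind = "numeric" if pd.api.types.is_numeric_dtype(ser) else "categorical"
    if kind == "numeric":
        x = ser.to_numpy(dtype=float)
        if np.isnan(x).any():
            x = np.where(np.isnan(x), np.nanmean(x), x)
        sd = x.std()
        enc = (x - x.mean())[:, None] / sd if sd > 0 else np.zeros((len(x), 1))
        return EncodedTag(name, "numeric", enc)
    ser = ser.astype(object).where(~ser.isna(), "(missing)").astype(str)
    levels = sorted(ser.unique())
    enc = np.column_stack(
        [(ser == lev).to_numpy(dtype=float) for lev in levels[1:]]
    ) if len(levels) > 1 else np.zeros((len(ser), 0))
    return EncodedTag(name, "categorical", enc)


def _pooled_r2(coords: np.ndarray, design: np.ndarray) -> float:
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    yc = coords - coords.mean(axis=0)
    tss = float((yc**2).sum())
    if tss == 0:
        return 0.0
    if design.shape[1] == 0:
        return 0.0
    X = np.column_stack([np.ones(n), design])
    beta, *_ = np.linalg.lstsq(X, coords, rcond=None)
    resid = coords - X @ beta
    rss = float((resid**2).sum())
    # guard numerical round-off at the boundaries
    return float(min(1.0, max(0.0, 1.0 - rss / tss)))


def tag_r2(coords, tag: EncodedTag) -> AttributionResult:
    """Explained-variance R^2 of one tag against the 2-D coordinates."""
    coords = np.asarray(coords, dtype=float)
    n, k = len(coords), tag.encoding.shape[1]
    if tag.encoding.shape[0] != n:
        raise ValueError("tag encoding rows must match coords rows")
    if n < k + 2:
        raise ValueError(f"need n >= k+2 rows (n={n}, k={k})")
    if k == 0 or not np.any(tag.encoding.std(axis=0) > 0):
        warnings.warn(f"tag {tag.name!r} is constant; R^2 set to 0", stacklevel=2)
        return AttributionResult(tag.name, 0.0, n)
    return AttributionResult(tag.name, _pooled_r2(coords, tag.encoding), n)


def cumulative_r2(coords, tags) -> AttributionResult:
    """Joint R^2 of several tags (column-concatenated encodings).

    Monotone by construction: adding tags can only grow the column space,
    so the joint R^2 is at least any subset's.
    """
    tags = list(tags)
    coords = np.asarray(coords, dtype=float)
    if not tags:
        return AttributionResult("(none)", 0.0, len(coords))
    design = np.column_stack([t.encoding for t in tags])
    name = "+".join(t.name for t in tags)
    return AttributionResult(name, _pooled_r2(coords, design), len(coords))


def rank_tags(coords, tags) -> list:
    """Single-tag attributions in descending R^2 order (ties by tag name)."""
    results = [tag_r2(coords, t) for t in tags]
    results.sort(key=lambda r: (-r.r2, r.tag))
    for i, r in enumerate(results):
        r.rank = i + 1
    return results


def manifest_tags(manifest: pd.DataFrame, include_label: bool = True) -> list:
    """Standard encoded tag set from a cohort manifest.

    Age enters as days between study and birth date; manufacturer,
    department, sex and view as indicator encodings; the class label
    itself is included by default (it is expected to dominate).
    """
    tags = [
        encode_tag(
            "age_days",
            [encode_age(s, b) for s, b in zip(manifest["study_date"], manifest["birth_date"])],
            kind="numeric",
        ),
        encode_tag("manufacturer", manifest["manufacturer"]),
        encode_tag("department", manifest["department"]),
        encode_tag("sex", manifest["sex"]),
        encode_tag("view", manifest["view"]),
    ]
    if include_label and "label" in manifest.columns:
        tags.insert(0, encode_tag("label", manifest["label"]))
    return tags
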