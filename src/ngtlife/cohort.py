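"""Cohort curation: QC filters, keyword retention, consensus labels, and
patient-grouped stratified splitting.

The curation contract mirrors a hospital-archive workflow: records below
1024 px in either dimension, non-chest body parts, non-frontal views and
pediatric patients (< 16 years at study date) are excluded with a per-record
reason; radiology reports are retained by case-insensitive keyword regex;
three raters' labels are reduced by majority vote; and records are split
90/5/5 with patients kept whole and label/sex/view frequencies preserved.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from ._rng import stream_rng
from .containers import CLASSES

DEFAULT_KEYWORDS = ("nasogastric", "tube", "placement", "insertion", "bronchus")

_REQUIRED_QC_FIELDS = (
    "width", "height", "view", "body_part", "study_date", "birth_date",
)

MIN_SIDE_PX = 1024
MIN_AGE_YEARS = 16


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NaT or v == ""


def _at_least_years(birth: date, study: date, years: int) -> bool:
    """True when the patient is at least `years` calendar years old at study."""
    try:
        cutoff = birth.replace(year=birth.year + years)
    except ValueError:  # Feb 29 birth, non-leap target year
        cutoff = birth.replace(year=birth.year + years, day=28)
    return study >= cutoff


def qc_filter(cohort: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Apply the quality-control rules; returns (retained, exclusion log).

    Rules, in the order logged for a failing record: ``missing_field``,
    ``resolution`` (width or height < 1024 px), ``body_part`` (must contain
    "chest", case-insensitive), ``view`` (AP or PA only), ``age`` (< 16
    calendar years at study date). Each excluded record is logged once with
    its first failing rule; malformed fields count as missing, never crash.
    """
    keep = []
    log = []
    for _, rec in cohort.iterrows():
        rule = _first_failing_rule(rec)
        if rule is None:
            keep.append(rec)
        else:
            log.append({"record_id": rec.get("record_id"), "rule": rule})
    kept = pd.DataFrame(keep, columns=cohort.columns).reset_index(drop=True)
    kept.attrs["provenance"] = list(cohort.attrs.get("provenance", [])) + [
        f"qc_filter(kept={len(kept)}, excluded={len(log)})"
    ]
    return kept, log


def _first_failing_rule(rec) -> str | None:
    for f in _REQUIRED_QC_FIELDS:
        if f not in rec or _is_missing(rec[f]):
            return "missing_field"
    try:
        w, h = int(rec["width"]), int(rec["height"])
        birth = pd.Timestamp(rec["birth_date"]).date()
        study = pd.Timestamp(rec["study_date"]).date()
    except (ValueError, TypeError):
        return "missing_field"
    if w < MIN_SIDE_PX or h < MIN_SIDE_PX:
        return "resolution"
    if "chest" not in str(rec["body_part"]).lower():
        return "body_part"
    if str(rec["view"]).upper() not in ("AP", "PA"):
        return "view"
    if not _at_least_years(birth, study, MIN_AGE_YEARS):
        return "age"
    return None


def keyword_filter(cohort: pd.DataFrame, keywords=DEFAULT_KEYWORDS) -> pd.DataFrame:
    """Retain records whose report matches any keyword, case-insensitively.

    Absent report text never matches. An empty keyword list is an error
    (it would silently drop the whole cohort).
    """
    keywords = list(keywords)
    if not keywords:
        raise ValueError("keyword list must not be empty")
    pattern = re.compile("|".join(re.escape(k) for k in keywords), re.IGNORECASE)
    text = cohort["report_text"].fillna("").astype(str)
    mask = text.str.contains(pattern)
    out = cohort.loc[mask.to_numpy()].reset_index(drop=True)
    out.attrs["provenance"] = list(cohort.attrs.get("provenance", [])) + [
        f"keyword_filter(kept={len(out)}/{len(cohort)})"
    ]
    return out


def consensus_label(rater_labels) -> str | None:
    """Majority vote of exactly three rater labels.

    Returns the label held by at least two raters, or ``None`` when all
    three disagree (no consensus; such records are excluded from downstream
    agreement metrics rather than resolved arbitrarily).
    """
    labels = list(rater_labels)
    if len(labels) != 3:
        raise ValueError(f"consensus requires exactly 3 rater labels, got {len(labels)}")
    vals, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    top = counts.max()
    if top < 2:
        return None
    return str(vals[counts.argmax()])


def consensus_labels(cohort: pd.DataFrame) -> pd.Series:
    """Row-wise majority vote over the rater1..rater3 columns (NA = tie)."""
    out = [
        consensus_label((r["rater1"], r["rater2"], r["rater3"]))
        for _, r in cohort.iterrows()
    ]
    return pd.Series(out, index=cohort.index, dtype=object)


@dataclass
class SplitAssignment:
    """Result of the grouped stratified split."""

    assignment: dict  # record_id -> split name
    fractions: dict  # split -> realized fraction
    stratum_table: pd.DataFrame  # per (stratum, split) record counts
    flagged: bool = False  # tolerance not achieved
    multi_strata_patients: list = field(default_factory=list)

    def split_ids(self, name: str) -> list:
        return [r for r, s in self.assignment.items() if s == name]


SPLIT_NAMES = ("train", "validation", "test")


def grouped_stratified_split(
    cohort: pd.DataFrame,
    fractions=(0.90, 0.05, 0.05),
    strata=("label", "sex", "view"),
    group: str = "patient_id",
    seed: int = 0,
    tolerance: float = 0.02,
) -> SplitAssignment:
    """Patient-disjoint stratified split with target fractions.

    All records of one patient land in one split.  Patients (shuffled by
    seed) are assigned greedily to the split with the largest remaining
    record deficit for the patient's stratum; a patient whose records span
    several strata is filed under their modal stratum and logged.  Exact
    grouped stratification is infeasible in general, so realized fractions
    outside ``tolerance`` produce a warning and a flagged best-effort
    result, never an exception.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise ValueError("fractions must be 3 values summing to 1")
    for s in strata:
        if s not in cohort.columns:
            raise ValueError(f"stratum column {s!r} missing from cohort")
    if cohort.empty:
        return SplitAssignment({}, dict.fromkeys(SPLIT_NAMES, 0.0), pd.DataFrame())

    df = cohort.reset_index(drop=True)
    stratum_of_record = df[list(strata)].astype(str).agg("|".join, axis=1)

    # patient -> modal stratum (ties broken lexicographically), record count
    pat_groups = {}
    multi = []
    for pid, idx in df.groupby(group).groups.items():
        counts = stratum_of_record.loc[idx].value_counts()
        if len(counts) > 1:
            multi.append(pid)
            top = counts.max()
            modal = sorted(counts[counts == top].index)[0]
        else:
            modal = counts.index[0]
        pat_groups[pid] = (modal, list(idx))

    # per-stratum record targets per split
    strat_sizes = stratum_of_record.value_counts()
    target = {
        st: {name: strat_sizes[st] * f for name, f in zip(SPLIT_NAMES, fractions)}
        for st in strat_sizes.index
    }
    assigned = {st: dict.fromkeys(SPLIT_NAMES, 0) for st in strat_sizes.index}

    rng = stream_rng(seed, "split")
    patients = sorted(pat_groups)
    rng.shuffle(patients)

    assignment = {}
    for pid in patients:
        st, idx = pat_groups[pid]
        deficits = {s: target[st][s] - assigned[st][s] for s in SPLIT_NAMES}
        best = max(SPLIT_NAMES, key=lambda s: (deficits[s], fractions[SPLIT_NAMES.index(s)]))
        for i in idx:
            assignment[df.at[i, "record_id"]] = best
            assigned[stratum_of_record[i]][best] = (
                assigned[stratum_of_record[i]].get(best, 0) + 1
            )
        for s2 in set(stratum_of_record[i] for i in idx):
            assigned.setdefault(s2, dict.fromkeys(SPLIT_NAMES, 0))

    n = len(df)
    realized = {
        s: sum(1 for v in assignment.values() if v == s) / n for s in SPLIT_NAMES
    }
    table = (
        pd.DataFrame(
            {
                "stratum": stratum_of_record,
                "split": [assignment[r] for r in df["record_id"]],
            }
        )
        .value_counts()
        .unstack(fill_value=0)
    )

    flagged = any(
        abs(realized[s] - f) > tolerance for s, f in zip(SPLIT_NAMES, fractions)
    )
    if flagged:
        warnings.warn(
            "grouped split fractions outside tolerance: "
            + ", ".join(f"{s}={realized[s]:.3f}" for s in SPLIT_NAMES),
            stacklevel=2,
        )

    # hard invariants: full partition, patient-disjoint
    assert set(assignment) == set(df["record_id"])
    pat_splits = df.assign(split=[assignment[r] for r in df["record_id"]]).groupby(group)[
        "split"
    ].nunique()
    assert (pat_splits == 1).all(), "patient assigned to more than one split"

    return SplitAssignment(assignment, realized, table, flagged, multi)
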