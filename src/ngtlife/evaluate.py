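"""Evaluation and reader-agreement statistics.

Covers the classifier side (confusion matrix, per-class accuracy/PPV/
sensitivity/specificity with exact Clopper–Pearson intervals, one-vs-rest
ROC AUC with percentile-bootstrap CIs, reliability curves with expected
calibration error) and the reader-study side (Cohen κ with its observed and
chance agreement components, pairwise κ matrices, and the paired two-tailed
t test comparing unaided vs AI-aided reader-consensus agreement).

Every reported percentage keeps its (x, n) counts alongside, so nothing in
an output table is an orphaned rounded number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from ._rng import stream_rng


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (reporting convention for percentages)."""
    scale = 10**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# confusion matrix and per-class metrics

@dataclass
class ConfusionMatrix:
    """K x K counts; rows are ground truth, columns are argmax predictions."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def confusion(y_true, proba, classes) -> ConfusionMatrix:
    """Confusion matrix from truth labels and a probability matrix.

    The predicted label is the class with the greatest classification
    probability (ties broken toward the earlier class in ``classes``).
    """
    classes = tuple(classes)
    proba = np.asarray(proba, dtype=float)
    pred_idx = proba.argmax(axis=1)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, pred_idx):
        counts[idx[t], p] += 1
    return ConfusionMatrix(counts, classes)


@dataclass
class MetricWithCI:
    """A binomial proportion with its exact interval and raw counts."""

    estimate: float
    ci_low: float
    ci_high: float
    x: int
    n: int
    method: str = "clopper-pearson"
    defined: bool = True

    def as_percent(self) -> tuple:
        """(estimate, low, high) as half-up-rounded integer percentages."""
        return tuple(
            int(round_half_up(v * 100)) for v in (self.estimate, self.ci_low, self.ci_high)
        )


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple:
    """Exact binomial CI from beta quantiles; closed at the boundaries."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError(f"need 0 <= x <= n with n > 0, got x={x}, n={n}")
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def _metric(x: int, n: int, alpha: float) -> MetricWithCI:
    if n == 0:
        return MetricWithCI(float("nan"), float("nan"), float("nan"), 0, 0, defined=False)
    lo, hi = clopper_pearson(x, n, alpha)
    return MetricWithCI(x / n, lo, hi, int(x), int(n))


def class_metrics(cm: ConfusionMatrix, cls, alpha: float = 0.05) -> dict:
    """One-vs-rest accuracy, PPV, sensitivity and specificity for one class.

    All four are binomial proportions of their one-vs-rest counts and carry
    Clopper–Pearson intervals (the interval method is recorded; the exact
    method is standard for sensitivity/specificity/accuracy and applied to
    PPV as well for consistency).  A zero denominator yields a metric with
    ``defined=False`` rather than NaN propagation.
    """
    if cls not in cm.classes:
        raise ValueError(f"class {cls!r} not in confusion matrix")
    i = cm.classes.index(cls)
    c = cm.counts
    tp = int(c[i, i])
    fn = int(c[i, :].sum() - tp)
    fp = int(c[:, i].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    return {
        "accuracy": _metric(tp + tn, cm.n, alpha),
        "ppv": _metric(tp, tp + fp, alpha),
        "sensitivity": _metric(tp, tp + fn, alpha),
        "specificity": _metric(tn, tn + fp, alpha),
    }


def metrics_table(cm: ConfusionMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Tidy per-class metric table (class, metric, estimate, CI, x, n)."""
    rows = []
    for cls in cm.classes:
        for name, m in class_metrics(cm, cls, alpha).items():
            rows.append(
                {
                    "class": cls, "metric": name, "estimate": m.estimate,
                    "ci_low": m.ci_low, "ci_high": m.ci_high, "x": m.x, "n": m.n,
                    "method": m.method,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC / AUC

@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    n: int


def roc_auc(scores, binary_labels, n_boot: int = 2000, seed: int = 0) -> RocResult:
    """One-vs-rest ROC with a seeded percentile-bootstrap CI.

    The AUC is the probability a random positive outscores a random
    negative, ties counted half (rank/Mann–Whitney definition).  The CI
    resamples cases with replacement ``n_boot`` times (default 2000) and
    takes the 2.5/97.5 percentiles; degenerate single-class resamples are
    redrawn implicitly by skipping.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    if len(scores) != len(y):
        raise ValueError("scores and labels must be aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    auc = _auc_rank(scores, y)
    fpr, tpr, thr = roc_curve(y, scores)
    rng = stream_rng(seed, "bootstrap")
    boots = []
    n = len(y)
    while len(boots) < n_boot:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        boots.append(_auc_rank(scores[idx], yb))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocResult(fpr, tpr, thr, auc, float(lo), float(hi), n_boot, n)


def _auc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC: midranks count tied positive-negative pairs half."""
    r = stats.rankdata(scores)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    u = r[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def one_vs_rest_aucs(y_true, proba, classes, n_boot: int = 2000, seed: int = 0) -> dict:
    """Per-class one-vs-rest RocResult keyed by class name."""
    proba = np.asarray(proba, dtype=float)
    y_true = np.asarray(y_true)
    return {
        cls: roc_auc(proba[:, i], (y_true == cls).astype(int), n_boot, seed)
        for i, cls in enumerate(classes)
    }


# ---------------------------------------------------------------------------
# agreement

@dataclass
class AgreementResult:
    """Cohen κ with its components: κ = (po - pe) / (1 - pe)."""

    kappa: float
    po: float
    pe: float
    n: int


def cohen_kappa(ratings_a, ratings_b) -> AgreementResult:
    """Unweighted Cohen κ between two raters.

    po is the observed agreement (cross-table trace fraction), pe the
    chance agreement from the marginal products.  When both raters are
    constant and identical (pe = 1, po = 1) κ is defined as 1.
    """
    a = np.asarray(ratings_a, dtype=object)
    b = np.asarray(ratings_b, dtype=object)
    if len(a) != len(b):
        raise ValueError("rating vectors must have equal length")
    if len(a) == 0:
        raise ValueError("rating vectors must be non-empty")
    levels = sorted(set(a) | set(b))
    idx = {v: i for i, v in enumerate(levels)}
    table = np.zeros((len(levels), len(levels)))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    n = table.sum()
    po = float(np.trace(table) / n)
    pe = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if pe == 1.0:
        return AgreementResult(1.0 if po == 1.0 else 0.0, po, pe, int(n))
    return AgreementResult((po - pe) / (1 - pe), po, pe, int(n))


def kappa_matrix(ratings: pd.DataFrame) -> tuple:
    """Pairwise κ matrix over readers (columns = readers, rows = items).

    Returns (matrix DataFrame, mean, SD) where mean/SD summarize the
    off-diagonal upper triangle.
    """
    readers = list(ratings.columns)
    if len(readers) < 2:
        raise ValueError("need at least 2 readers")
    k = len(readers)
    mat = np.ones((k, k))
    vals = []
    for i in range(k):
        for j in range(i + 1, k):
            kap = cohen_kappa(ratings[readers[i]], ratings[readers[j]]).kappa
            mat[i, j] = mat[j, i] = kap
            vals.append(kap)
    dfm = pd.DataFrame(mat, index=readers, columns=readers)
    return dfm, float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def paired_kappa_test(kappas_unaided, kappas_aided, paired: bool = True) -> tuple:
    """Two-tailed t test of per-reader κ, aided vs unaided.

    Paired by reader (df = n-1) by default; a two-sample variant is
    available behind the flag.  Returns (t, p, df); a zero-variance
    non-zero difference is degenerate and reported as (inf, 0, df) with a
    warning.
    """
    a = np.asarray(kappas_unaided, dtype=float)
    b = np.asarray(kappas_aided, dtype=float)
    if paired and len(a) != len(b):
        raise ValueError("paired test needs equal-length vectors")
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least 2 readers per condition")
    if paired:
        d = b - a
        df = len(d) - 1
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):
                return 0.0, 1.0, df
            warnings.warn("zero-variance non-zero differences; t degenerate", stacklevel=2)
            return math.copysign(math.inf, d.mean()), 0.0, df
        t, p = stats.ttest_rel(b, a)
        return float(t), float(p), df
    t, p = stats.ttest_ind(b, a)
    return float(t), float(p), len(a) + len(b) - 2


# ---------------------------------------------------------------------------
# calibration

@dataclass
class CalibrationResult:
    bin_mid: np.ndarray
    mean_pred: np.ndarray
    frac_pos: np.ndarray
    counts: np.ndarray
    ece: float
    skipped_bins: list = field(default_factory=list)


def calibration_curve(probs, labels, bins: int = 10) -> CalibrationResult:
    """Reliability diagram points and expected calibration error.

    Equal-width probability bins; ECE is the count-weighted mean absolute
    gap between mean predicted probability and observed event frequency.
    Empty bins are skipped and listed.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    which = np.clip(np.digitize(p, edges[1:-1]), 0, bins - 1)
    mids, mp, fp, cnt, skipped = [], [], [], [], []
    for b in range(bins):
        mask = which == b
        if not mask.any():
            skipped.append(b)
            continue
        mids.append((edges[b] + edges[b + 1]) / 2)
        mp.append(p[mask].mean())
        fp.append(y[mask].mean())
        cnt.append(int(mask.sum()))
    mp, fp, cnt = map(np.asarray, (mp, fp, cnt))
    ece = float(np.sum(cnt / cnt.sum() * np.abs(mp - fp)))
    return CalibrationResult(np.asarray(mids), mp, fp, cnt, ece, skipped)


def brier_score(proba, y_true, classes) -> float:
    """Multiclass Brier score (mean squared distance to the one-hot truth)."""
    proba = np.asarray(proba, dtype=float)
    onehot = np.array([[1.0 if t == c else 0.0 for c in classes] for t in y_true])
    return float(((proba - onehot) ** 2).sum(axis=1).mean())


def feed_score(prob_triplet) -> float:
    """Feed probability from a (satisfactory, malpositioned, bronchial) triplet.

    The probability of the satisfactory class is the only monotone scalar
    summary of "safe to feed"; the decision threshold lives with the caller
    (default 0.5 downstream).
    """
    p = np.asarray(prob_triplet, dtype=float)
    if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("expected a probability triplet summing to 1")
    return float(p[0])
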