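"""Concept-drift detection by a classifier two-sample test.

A deployed classifier's latent embeddings drift when acquisition conditions
change (new scanner, new department, different patient mix) even while the
code is frozen.  The detector asks a random forest to tell a reference
sample of embedding coordinates apart from a candidate batch: every point
receives an out-of-bag (OOB) probability of belonging to the candidate
side, and a two-sample Kolmogorov–Smirnov test compares the OOB probability
distributions of the two groups.  Under no drift the forest cannot separate
them and the P value is large; under drift the OOB distributions diverge
and P collapses.  OOB predictions make a held-out split unnecessary, and
the KS P value gives the monitor an interpretable per-batch score.

``monitor`` repeats the test over many resampled candidate batches and
summarizes the P-value distribution (median/quartiles plus a flag at the
configured alpha), which is the quantity a deployment dashboard would
track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from ._rng import child_seed, stream_rng
from .containers import EmbeddingSet
from .errors import ConfigurationError


@dataclass
class DriftConfig:
    """Detector parameters.

    n_trees must stay large enough that every point is out-of-bag for some
    trees (500 is comfortably stable); alpha is the monitoring threshold on
    the per-batch P value.
    """

    n_trees: int = 500
    min_batch: int = 50
    n_batches: int = 50
    batch_size: int = 100
    alpha: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 100:
            raise ConfigurationError("n_trees must be >= 100 for stable OOB estimates")
        if self.batch_size < self.min_batch:
            raise ConfigurationError("batch_size must be >= min_batch")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")


@dataclass
class DriftBatchResult:
    D: float
    p: float
    n_ref: int
    n_cand: int


@dataclass
class DriftMonitorResult:
    batches: list
    p_median: float
    p_q1: float
    p_q3: float
    drift: bool
    alpha: float
    outlier_scores: np.ndarray | None = None  # per-candidate-point OOB probabilities

    @property
    def p_values(self) -> np.ndarray:
        return np.asarray([b.p for b in self.batches])


def ks_2sample(a, b) -> tuple:
    """Two-sample Kolmogorov–Smirnov test.

    D is the supremum distance between the two empirical CDFs.  The
    two-sided P value is computed by exact enumeration of the label
    assignments when ``len(a) * len(b) <= 10000`` and the data are free of
    cross-sample ties, and by the asymptotic Kolmogorov distribution
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = a.size * b.size <= 10000 and np.unique(np.concatenate([a, b])).size == a.size + b.size
    res = stats.ks_2samp(a, b, method="exact" if exact else "asymp")
    return float(res.statistic), float(res.pvalue)


def _oob_candidate_probs(ref: np.ndarray, cand: np.ndarray, config: DriftConfig, seed: int):
    X = np.vstack([ref, cand])
    y = np.r_[np.zeros(len(ref), dtype=int), np.ones(len(cand), dtype=int)]
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    import warnings as _w

    with _w.catch_warnings():
        # sklearn warns (and yields NaN rows) when a point is never OOB;
        # we turn that into the actionable error below
        _w.simplefilter("ignore")
        rf.fit(X, y)
        oob = rf.oob_decision_function_
    if np.isnan(oob).any():
        raise ConfigurationError(
            "some points were never out-of-bag; increase DriftConfig.n_trees"
        )
    p_cand = oob[:, list(rf.classes_).index(1)]
    return p_cand[: len(ref)], p_cand[len(ref):]


def _drop_matched_duplicates(ref: np.ndarray, cand: np.ndarray):
    """Remove pairs of byte-identical rows matched across the two sides.

    A candidate row that exactly equals a reference row is uninformative
    about distributional change, but it badly biases out-of-bag scores:
    each point's OOB trees contain its oppositely-labeled twin at the very
    same coordinates, which drives the two groups' OOB distributions apart
    even when the samples are identical.  Matched pairs are therefore
    excluded one-for-one before the forest is trained.
    """
    from collections import Counter, defaultdict

    ref_keys = [r.tobytes() for r in np.ascontiguousarray(ref)]
    cand_keys = [c.tobytes() for c in np.ascontiguousarray(cand)]
    budget = Counter(ref_keys)
    drop_cand = []
    matched = Counter()
    for j, key in enumerate(cand_keys):
        if budget[key] - matched[key] > 0:
            matched[key] += 1
            drop_cand.append(j)
    if not drop_cand:
        return ref, cand, 0
    remaining = defaultdict(int, matched)
    keep_ref = []
    for i, key in enumerate(ref_keys):
        if remaining[key] > 0:
            remaining[key] -= 1
        else:
            keep_ref.append(i)
    keep_cand = [j for j in range(len(cand)) if j not in set(drop_cand)]
    return ref[keep_ref], cand[keep_cand], len(drop_cand)


def _coords(x) -> np.ndarray:
    if isinstance(x, EmbeddingSet):
        return x.X
    return np.asarray(x, dtype=float)


def score_batch(reference_coords, candidate_coords, config: DriftConfig | None = None) -> DriftBatchResult:
    """One classifier two-sample test of a candidate batch against reference.

    Trains a random forest to discriminate reference (label 0) from
    candidate (label 1) on the pooled coordinates, collects each point's
    out-of-bag probability of the candidate class, and returns the KS
    statistic and P value between the reference and candidate OOB
    probability distributions.
    """
    config = config or DriftConfig()
    config.validate()
    ref = _coords(reference_coords)
    cand = _coords(candidate_coords)
    if len(ref) < config.min_batch or len(cand) < config.min_batch:
        raise ValueError(
            f"need at least min_batch={config.min_batch} points per side "
            f"(got {len(ref)} reference, {len(cand)} candidate)"
        )
    return _score_prepared(ref, cand, config, child_seed(config.seed, "drift"))[0]


def _score_prepared(ref, cand, config, seed):
    ref2, cand2, _ = _drop_matched_duplicates(ref, cand)
    if len(ref2) == 0 or len(cand2) == 0:
        # every candidate point had an identical reference twin: the
        # samples are exchangeable and carry no evidence of drift
        return DriftBatchResult(D=0.0, p=1.0, n_ref=len(ref), n_cand=len(cand)), None
    p_ref, p_cand = _oob_candidate_probs(ref2, cand2, config, seed)
    D, p = ks_2sample(p_ref, p_cand)
    return DriftBatchResult(D=D, p=p, n_ref=len(ref2), n_cand=len(cand2)), p_cand


def monitor(reference_coords, candidate_pool, config: DriftConfig | None = None) -> DriftMonitorResult:
    """Repeated-batch drift monitoring.

    Draws ``n_batches`` candidate batches of ``batch_size`` from the pool
    (with replacement across batches), scores each against the reference,
    and reports the P-value distribution with a drift flag
    (median P < alpha).  Per-point OOB candidate probabilities of the last
    batch are kept as image-level outlier scores.
    """
    config = config or DriftConfig()
    config.validate()
    ref = _coords(reference_coords)
    pool = _coords(candidate_pool)
    if len(pool) < config.batch_size:
        raise ValueError(
            f"candidate pool ({len(pool)}) smaller than batch_size ({config.batch_size})"
        )
    rng = stream_rng(config.seed, "monitor")
    batches = []
    outliers = None
    for i in range(config.n_batches):
        idx = rng.choice(len(pool), size=config.batch_size, replace=False)
        res, p_cand = _score_prepared(ref, pool[idx], config,
                                      child_seed(config.seed, "drift", i))
        batches.append(res)
        if p_cand is not None:
            outliers = p_cand
    pvals = np.asarray([b.p for b in batches])
    q1, med, q3 = np.percentile(pvals, [25, 50, 75])
    return DriftMonitorResult(
        batches=batches,
        p_median=float(med),
        p_q1=float(q1),
        p_q3=float(q3),
        drift=bool(med < config.alpha),
        alpha=config.alpha,
        outlier_scores=outliers,
    )
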