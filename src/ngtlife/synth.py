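"""Synthetic cohorts, radiograph-like images and latent embeddings.

Real NGT (nasogastric tube) cohorts cannot be redistributed, so every
downstream module in this package is exercised on synthetic data that
emulates the statistical structure of a hospital chest-radiograph archive:

* three tube-position classes (``satisfactory``, ``malpositioned``,
  ``bronchial``) at a configurable prevalence, default 4100:2500:481;
* DICOM-style metadata (manufacturer, department, view, sex, study/birth
  dates) with a weak, calibrated association between manufacturer and class;
* pixel-level intensity offsets that depend on manufacturer, department and
  patient age, so that metadata leaves a detectable trace in the image (and
  hence in any learned latent embedding);
* injectable concept drift: mean-shifted embeddings, manufacturer/department
  swaps, and age-band filters.

Images are crude but geometrically faithful: a bright tube polyline descends
from the top edge, and its tip lands in a class-specific anatomical region
(stomach box, mid-esophagus band, or a lateral bronchial branch).  The
geometry is fixed by module constants; only intensity and noise are
configurable, which keeps the class signal learnable by a small CNN.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk

from ._rng import stream_rng
from .containers import CLASSES, EmbeddingSet
from .errors import ConfigurationError, EmptyCohortError

# ---------------------------------------------------------------------------
# configuration

#: default class priors: 4100 / 2500 / 481 of 7081
DEFAULT_PRIORS = (4100 / 7081, 2500 / 7081, 481 / 7081)

DEFAULT_MANUFACTURERS = (("Systemix", 0.0), ("Radion", 120.0), ("Portavue", 240.0))
DEFAULT_DEPARTMENTS = ("A&E", "Radiology", "Wards")

#: fixed pixel-level metadata effects (gray-levels on the 16-bit scale);
#: deliberately small relative to the tube signal so the class label, not
#: acquisition metadata, dominates any learned embedding
DEPARTMENT_OFFSET_STEP = 60.0
AGE_GRAY_PER_YEAR = 3.0
AGE_REFERENCE_YEARS = 65.0

#: tube drawing intensity added on top of the anatomy background; real NGTs
#: carry a radiopaque distal marker, rendered as a brighter blob at the tip
TUBE_GRAY = 20000.0
TIP_MARKER_GRAY = 30000.0

REPORT_TEMPLATES = {
    "satisfactory": (
        "Nasogastric tube in situ following insertion; tip projected below the "
        "diaphragm within the stomach. Satisfactory placement, safe to feed."
    ),
    "malpositioned": (
        "NG tube placement review: tube tip in the distal oesophagus, not within "
        "the stomach. Advancement recommended before feeding."
    ),
    "bronchial": (
        "Urgent: nasogastric tube insertion deviates at the carina into the right "
        "main bronchus. Do not feed; remove tube."
    ),
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort generator.

    ``class_priors`` follow the source-archive prevalence by default
    (4100 correctly placed : 2500 malpositioned : 481 bronchial).
    ``label_tag_r2`` is the target fraction of label variance carried by the
    manufacturer tag (weak confounding, default 0.07); the generator samples
    the class-linked manufacturer with probability ``sqrt(label_tag_r2)``
    and uniformly otherwise, an approximate one-parameter calibration.
    Intensity offsets are in gray-levels of the 16-bit pixel scale.
    """

    n_images: int = 1500
    class_priors: tuple = DEFAULT_PRIORS
    manufacturer_levels: tuple = DEFAULT_MANUFACTURERS
    department_levels: tuple = DEFAULT_DEPARTMENTS
    age_distribution: tuple = (66.5, 16.0, 16.0)  # mean, sd, min (years)
    label_tag_r2: float = 0.07
    noise_sd: float = 120.0
    image_size: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.n_images < 0:
            raise ConfigurationError("n_images must be >= 0")
        priors = np.asarray(self.class_priors, dtype=float)
        if priors.shape != (3,) or np.any(priors < 0) or abs(priors.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "class_priors must be 3 non-negative probabilities summing to 1"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.image_size < 16:
            raise ConfigurationError("image_size must be >= 16")
        if not 0.0 <= self.label_tag_r2 <= 1.0:
            raise ConfigurationError("label_tag_r2 must be in [0, 1]")
        if not self.manufacturer_levels or not self.department_levels:
            raise ConfigurationError("need at least one manufacturer and department")


@dataclass
class DriftSpec:
    """One drift scenario.

    kind:
        ``mean_shift``        — add ``magnitude`` x per-dimension SD to embeddings;
        ``manufacturer_swap`` — source every record from one single system:
        the level at index ``int(magnitude)`` of the frequency-sorted levels
        (default 0 = the rarest), emulating a sudden fleet change;
        ``department_swap``   — likewise for department;
        ``age_band``          — keep only records whose age (years) lies in
        ``magnitude = (low, high)``, low inclusive, high exclusive.
    """

    kind: str
    magnitude: float | tuple = 0.0

    def validate(self) -> None:
        kinds = {"mean_shift", "manufacturer_swap", "age_band", "department_swap"}
        if self.kind not in kinds:
            raise ConfigurationError(f"unknown drift kind {self.kind!r}; one of {sorted(kinds)}")
        if self.kind == "age_band":
            lo, hi = self.magnitude
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError("age_band limits must be finite and ordered")
        elif not np.isfinite(self.magnitude):
            raise ConfigurationError("magnitude must be finite")


@dataclass
class SynthImage:
    """A rendered radiograph stand-in: 16-bit pixels plus ground truth."""

    pixels: np.ndarray  # uint16, (size, size)
    tip_xy: tuple  # (row, col), 0-based
    label: str


# ---------------------------------------------------------------------------
# geometry constants (fractions of the image side); fixed by design

_ENTRY_COL = 0.46
_CARINA_ROW = 0.30

#: class tip regions as (row0, row1, col0, col1) fractions
TIP_REGIONS = {
    "satisfactory": (0.70, 0.90, 0.35, 0.58),  # lower-third "stomach" box
    "malpositioned": (0.36, 0.60, 0.42, 0.54),  # mid "esophagus" band
    "bronchial": (0.32, 0.50, 0.62, 0.84),  # lateral "bronchial" branch
}


def tip_region(label: str, size: int) -> tuple:
    """Pixel-coordinate bounding box (r0, r1, c0, c1) of the class tip region."""
    if label not in TIP_REGIONS:
        raise ValueError(f"unknown label {label!r}")
    r0, r1, c0, c1 = TIP_REGIONS[label]
    return (int(r0 * size), int(r1 * size), int(c0 * size), int(c1 * size))


# ---------------------------------------------------------------------------
# manifest

def generate_manifest(config: SynthConfig) -> pd.DataFrame:
    """Draw a synthetic cohort manifest (one row per image record).

    Reproducible: identical (config, seed) give identical tables.  Patients
    carry 1–3 records each; all records of a patient share patient_id, sex
    and birth date.
    """
    config.validate()
    n = config.n_images
    cols = [
        "record_id", "patient_id", "study_date", "birth_date", "sex", "view",
        "body_part", "width", "height", "manufacturer", "department",
        "report_text", "label", "rater1", "rater2", "rater3",
    ]
    if n == 0:
        return pd.DataFrame(columns=cols)

    rng = stream_rng(config.seed, "manifest")
    priors = np.asarray(config.class_priors, dtype=float)
    labels = rng.choice(len(CLASSES), size=n, p=priors)

    # patients: sizes 1-3, enough to cover n records
    sizes = rng.integers(1, 4, size=n)
    cum = np.cumsum(sizes)
    n_pat = int(np.searchsorted(cum, n) + 1)
    pat_of_record = np.repeat(np.arange(n_pat), sizes[:n_pat])[:n]

    # patient age is drawn at the archive midpoint; birth date is fixed per
    # patient, so age at any particular study varies with the study date
    mean_age, sd_age, min_age = config.age_distribution
    d0, d1 = date(2007, 6, 1), date(2019, 8, 31)
    span = (d1 - d0).days
    pat_age = np.maximum(rng.normal(mean_age, sd_age, size=n_pat), min_age + span / 2 / 365.25)
    pat_sex = rng.choice(["M", "F"], size=n_pat, p=[0.58, 0.42])
    pat_birth = [
        d0 + timedelta(days=span // 2) - timedelta(days=int(round(a * 365.25)))
        for a in pat_age
    ]
    study_offset = rng.integers(0, span + 1, size=n)

    # manufacturer: class-linked with probability w (calibrated association)
    w = float(np.sqrt(config.label_tag_r2))
    n_man = len(config.manufacturer_levels)
    man_names = [m[0] for m in config.manufacturer_levels]
    linked = labels % n_man
    uniform = rng.integers(0, n_man, size=n)
    man_idx = np.where(rng.random(n) < w, linked, uniform)

    dep_idx = rng.integers(0, len(config.department_levels), size=n)
    view = rng.choice(["AP", "PA"], size=n, p=[0.6, 0.4])
    width = rng.integers(1024, 4281, size=n)
    height = rng.integers(1024, 3521, size=n)

    # rater labels: true label, independently corrupted at 8 % per rater
    def rate(rater_i):
        out = []
        for i in range(n):
            lab = CLASSES[labels[i]]
            r = stream_rng(config.seed, "manifest", 1000 + rater_i * n + i)
            if r.random() < 0.08:
                others = [c for c in CLASSES if c != lab]
                lab = others[int(r.integers(0, 2))]
            out.append(lab)
        return out

    rows = {
        "record_id": [f"R{i:06d}" for i in range(n)],
        "patient_id": [f"P{p:05d}" for p in pat_of_record],
        "study_date": [(d0 + timedelta(days=int(o))).isoformat() for o in study_offset],
        "birth_date": [pat_birth[p].isoformat() for p in pat_of_record],
        "sex": pat_sex[pat_of_record],
        "view": view,
        "body_part": ["CHEST"] * n,
        "width": width,
        "height": height,
        "manufacturer": [man_names[i] for i in man_idx],
        "department": [config.department_levels[i] for i in dep_idx],
        "report_text": [REPORT_TEMPLATES[CLASSES[k]] for k in labels],
        "label": [CLASSES[k] for k in labels],
        "rater1": rate(0),
        "rater2": rate(1),
        "rater3": rate(2),
    }
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["provenance"] = [f"generate_manifest(seed={config.seed}, n={n})"]
    return df


# ---------------------------------------------------------------------------
# images

def _background(size: int) -> np.ndarray:
    """Fixed thorax-like background: body ellipse, dark lungs, bright mediastinum."""
    img = np.full((size, size), 1500.0)
    rr, cc = np.mgrid[0:size, 0:size]
    r, c = rr / size, cc / size
    body = ((r - 0.5) / 0.52) ** 2 + ((c - 0.5) / 0.46) ** 2 <= 1.0
    img[body] = 9000.0
    for lc in (0.30, 0.70):
        lung = ((r - 0.42) / 0.30) ** 2 + ((c - lc) / 0.15) ** 2 <= 1.0
        img[lung] = 3500.0
    medi = (np.abs(c - 0.5) <= 0.09) & (r >= 0.12) & (r <= 0.78) & body
    img[medi] = 14000.0
    return img


def _draw_polyline(img: np.ndarray, points, value: float, thickness: int) -> None:
    size = img.shape[0]
    for (r0, c0), (r1, c1) in zip(points[:-1], points[1:]):
        n_steps = int(max(abs(r1 - r0), abs(c1 - c0)) * 2) + 2
        for t in np.linspace(0.0, 1.0, n_steps):
            rr, cc = _disk(
                (r0 + t * (r1 - r0), c0 + t * (c1 - c0)), thickness, shape=(size, size)
            )
            img[rr, cc] = np.maximum(img[rr, cc], value)


def _age_years(record) -> float:
    b = pd.Timestamp(record["birth_date"])
    s = pd.Timestamp(record["study_date"])
    return (s - b).days / 365.25


def render_image(record, config: SynthConfig) -> SynthImage:
    """Render one record's radiograph stand-in.

    The tube polyline enters at the top edge, follows the mediastinum, and
    terminates in the class tip region; the tip location is drawn from the
    record's own sub-seed (keyed by the numeric part of ``record_id``), so a
    single image can be regenerated without replaying the whole cohort.
    Manufacturer/department/age intensity offsets are added uniformly, then
    Gaussian noise of ``config.noise_sd``.
    """
    label = record["label"]
    if label not in CLASSES:
        raise ValueError(f"unknown label {label!r}")
    size = config.image_size
    idx = int(str(record["record_id"]).lstrip("R").lstrip("0") or 0)
    rng = stream_rng(config.seed, "render", idx)

    r0, r1, c0, c1 = tip_region(label, size)
    tip = (int(rng.integers(r0, r1)), int(rng.integers(c0, c1)))

    img = _background(size)
    entry = (0, int(_ENTRY_COL * size))
    carina = (int(_CARINA_ROW * size), int((_ENTRY_COL + 0.02) * size))
    if label == "bronchial":
        points = [entry, carina, tip]
    else:
        mid = (int((carina[0] + tip[0]) / 2), int((carina[1] + tip[1]) / 2))
        points = [entry, carina, mid, tip]
    _draw_polyline(img, points, TUBE_GRAY, max(1, round(size / 48)))
    rr_m, cc_m = _disk(tip, max(2, round(size / 24)), shape=(size, size))
    img[rr_m, cc_m] = TIP_MARKER_GRAY

    man_offsets = dict(config.manufacturer_levels)
    offset = man_offsets.get(record["manufacturer"], 0.0)
    dep_levels = list(config.department_levels)
    if record["department"] in dep_levels:
        offset += DEPARTMENT_OFFSET_STEP * dep_levels.index(record["department"])
    offset += AGE_GRAY_PER_YEAR * (_age_years(record) - AGE_REFERENCE_YEARS)

    img = img + offset
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return SynthImage(pixels=img, tip_xy=tip, label=label)


def render_cohort(manifest: pd.DataFrame, config: SynthConfig) -> tuple:
    """Render every record; returns (pixel stack n x s x s float32, tips n x 2)."""
    n = len(manifest)
    out = np.empty((n, config.image_size, config.image_size), dtype=np.float32)
    tips = np.empty((n, 2), dtype=int)
    for i, (_, rec) in enumerate(manifest.iterrows()):
        im = render_image(rec, config)
        out[i] = im.pixels
        tips[i] = im.tip_xy
    return out, tips


# ---------------------------------------------------------------------------
# embeddings

def synth_embeddings(
    n_per_group,
    centers,
    tag_effects: dict | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> EmbeddingSet:
    """Draw latent vectors from a Gaussian mixture with planted tag effects.

    Parameters
    ----------
    n_per_group : sequence of int
        Rows per class; classes taken from :data:`CLASSES` in order (extra
        groups get generic names).
    centers : array (k, d)
        Per-class mean vectors (all sharing dimension d).
    tag_effects : dict, optional
        ``name -> vector (d,)`` plants a numeric tag ``z ~ N(0,1)`` with the
        offset ``z * vector``; ``name -> matrix (L, d)`` plants a categorical
        tag with L uniform levels, each adding its row.
    noise_sd : float
        Isotropic Gaussian noise SD around the composed mean.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2:
        raise ValueError("centers must be a (k, d) matrix")
    k, d = centers.shape
    n_per_group = [int(v) for v in n_per_group]
    if len(n_per_group) != k:
        raise ValueError("n_per_group length must match number of centers")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    names = [CLASSES[i] if i < len(CLASSES) else f"group{i}" for i in range(k)]

    rng = stream_rng(seed, "embed")
    n = sum(n_per_group)
    labels = np.repeat(names, n_per_group)
    X = np.repeat(centers, n_per_group, axis=0).astype(float)

    tags = {}
    for name, eff in (tag_effects or {}).items():
        eff = np.asarray(eff, dtype=float)
        if eff.ndim == 1:
            if eff.shape[0] != d:
                raise ValueError(f"tag {name!r}: effect vector must have length d={d}")
            z = rng.normal(size=n)
            X += z[:, None] * eff[None, :]
            tags[name] = z
        elif eff.ndim == 2:
            if eff.shape[1] != d:
                raise ValueError(f"tag {name!r}: effect rows must have length d={d}")
            lev = rng.integers(0, eff.shape[0], size=n)
            X += eff[lev]
            tags[name] = lev
        else:
            raise ValueError(f"tag {name!r}: effect must be 1-D or 2-D")

    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    return EmbeddingSet(
        X=X,
        record_id=np.array([f"E{i:06d}" for i in range(n)]),
        labels=labels,
        tags=pd.DataFrame(tags),
        provenance=[f"synth_embeddings(seed={seed}, n={n}, d={d})"],
    )


# ---------------------------------------------------------------------------
# drift injection

def apply_drift(data, spec: DriftSpec, seed: int = 0):
    """Return a drifted/filtered copy of a manifest or embedding set.

    The input is never mutated; the copy carries a provenance note.
    """
    spec.validate()
    if isinstance(data, EmbeddingSet):
        return _drift_embeddings(data, spec)
    if isinstance(data, pd.DataFrame):
        return _drift_manifest(data, spec)
    raise TypeError("apply_drift expects a manifest DataFrame or an EmbeddingSet")


def _drift_embeddings(es: EmbeddingSet, spec: DriftSpec) -> EmbeddingSet:
    out = es.copy()
    if spec.kind == "mean_shift":
        sd = out.X.std(axis=0, ddof=0)
        out.X = out.X + float(spec.magnitude) * sd[None, :]
    elif spec.kind == "age_band":
        if "age_years" not in out.tags.columns:
            raise ConfigurationError("age_band drift on embeddings needs an 'age_years' tag")
        lo, hi = spec.magnitude
        keep = (out.tags["age_years"].to_numpy() >= lo) & (out.tags["age_years"].to_numpy() < hi)
        if not keep.any():
            raise EmptyCohortError(f"age band [{lo}, {hi}) matches no records")
        out = out.take(np.flatnonzero(keep))
    else:
        raise ConfigurationError(f"drift kind {spec.kind!r} does not apply to embeddings")
    out.provenance.append(f"apply_drift({spec.kind}, magnitude={spec.magnitude})")
    return out


def _drift_manifest(df: pd.DataFrame, spec: DriftSpec) -> pd.DataFrame:
    out = df.copy()
    prov = list(df.attrs.get("provenance", []))
    if spec.kind in ("manufacturer_swap", "department_swap"):
        col = "manufacturer" if spec.kind == "manufacturer_swap" else "department"
        # a sudden acquisition change: every candidate image now comes from
        # one level (a relabeling that preserved the pooled level mix would
        # be invisible to any distributional monitor)
        levels = out[col].value_counts().index.tolist()[::-1]
        out[col] = levels[int(spec.magnitude) % len(levels)]
    elif spec.kind == "age_band":
        lo, hi = spec.magnitude
        age = (
            pd.to_datetime(out["study_date"]) - pd.to_datetime(out["birth_date"])
        ).dt.days / 365.25
        keep = (age >= lo) & (age < hi)
        if not keep.any():
            raise EmptyCohortError(f"age band [{lo}, {hi}) matches no records")
        out = out.loc[keep].reset_index(drop=True)
    else:
        raise ConfigurationError(f"drift kind {spec.kind!r} does not apply to a manifest")
    prov.append(f"apply_drift({spec.kind}, magnitude={spec.magnitude})")
    out.attrs["provenance"] = prov
    return out


def synth_reader_ratings(
    n_images: int = 335,
    n_readers: int = 5,
    hard_frac: float = 0.3,
    p_err_easy: float = 0.03,
    p_wrong_hard: float = 0.78,
    p_ai_correct_hard: float = 0.85,
    p_follow_ai: float = 0.85,
    prevalence_feed: float = 196 / 335,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy feed/do-not-feed reader-study ratings for the agreement suite.

    Emulates a two-phase reader study with shared item difficulty: a
    fraction of images is "deceptive" and junior readers independently give
    the wrong decision on them with high probability, so errors correlate
    across readers (inter-reader agreement exceeds agreement with the
    expert consensus, as real reader studies show).  In the aided phase a
    single model answer per image is shown to every reader, who follows it
    with probability ``p_follow_ai``; because the model is usually right on
    deceptive items, both inter-reader and reader-consensus agreement rise.
    Columns: record_id, reader, phase ('unaided'/'aided'), decision, and a
    repeated 'consensus' ground-truth column.
    """
    rng = stream_rng(seed, "ratings")
    truth = np.where(rng.random(n_images) < prevalence_feed, "feed", "do_not_feed")
    hard = rng.random(n_images) < hard_frac
    flip = {"feed": "do_not_feed", "do_not_feed": "feed"}
    wrong_of = np.array([flip[t] for t in truth])
    ai_wrong = rng.random(n_images) < np.where(hard, 1 - p_ai_correct_hard, p_err_easy)
    ai_answer = np.where(ai_wrong, wrong_of, truth)
    rows = []
    for phase in ("unaided", "aided"):
        for r in range(n_readers):
            p_err = np.where(hard, p_wrong_hard, p_err_easy)
            own_wrong = rng.random(n_images) < p_err
            dec = np.where(own_wrong, wrong_of, truth)
            if phase == "aided":
                follow = rng.random(n_images) < p_follow_ai
                dec = np.where(follow, ai_answer, dec)
            for i in range(n_images):
                rows.append(
                    (f"C{i:05d}", f"reader{r + 1}", phase, dec[i], truth[i])
                )
    return pd.DataFrame(
        rows, columns=["record_id", "reader", "phase", "decision", "consensus"]
    )
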