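"""Training recipe for the tube-position classifier ensemble.

The production-scale original is an ImageNet-initialized InceptionV3 pair at
764/1024 px trained on ~1.1M radiographs; that is not reproducible at desk
scale, so the backbone here is a small configurable conv-GAP-dense network
(:class:`ngtlife.nn.SmallCNN`) and the *recipe* is what this module
implements faithfully: bilinear resizing that ignores aspect ratio,
per-batch brightness/rotation/flip augmentation during training only, Adam
at 1e-3 on categorical cross-entropy in batches of 32, early stopping after
10 epochs without validation improvement with best-epoch weight restore,
Hyperband over dense width in [32, 512] and dropout in [0, 0.2], a
two-resolution ensemble that averages constituent probabilities, and
Grad-CAM saliency from the final convolutional layer.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.transform import resize as _sk_resize

from ._rng import child_seed, stream_rng
from .containers import CLASSES
from .errors import ConfigurationError, NotFittedError
from .nn import Adam, SmallCNN


@dataclass
class ClassifierConfig:
    """One constituent's training configuration.

    ``input_side`` pairs (48, 64) stand in for the production 764/1024
    resolutions at desk scale.  ``augment`` is (brightness fraction,
    rotation degrees, horizontal-flip probability); magnitudes are modest
    because the tube geometry, not texture, carries the class signal.
    """

    input_side: int = 64
    conv_widths: tuple = (8, 16, 32)
    dense_units: int = 64
    dropout_rate: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 32
    patience: int = 10
    max_epochs: int = 50
    augment: tuple = (0.10, 5.0, 0.5)
    seed: int = 0

    def validate(self) -> None:
        if not 32 <= self.dense_units <= 512:
            raise ConfigurationError("dense_units must lie in [32, 512]")
        if not 0.0 <= self.dropout_rate <= 0.2:
            raise ConfigurationError("dropout_rate must lie in [0, 0.2]")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if self.input_side < 16:
            raise ConfigurationError("input_side must be >= 16")


@dataclass
class Saliency:
    """A non-negative class-activation map at the query image's resolution."""

    map: np.ndarray
    target_class: str


def resize_images(images, side: int) -> np.ndarray:
    """Bilinear resize to (side, side), aspect ratio deliberately ignored."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    if images.shape[1:] == (side, side):
        return images.astype(np.float32)
    out = np.empty((len(images), side, side), dtype=np.float32)
    for i, im in enumerate(images):
        out[i] = _sk_resize(im, (side, side), order=1, preserve_range=True,
                            anti_aliasing=False)
    return out


def _augment_batch(batch: np.ndarray, augment, rng) -> np.ndarray:
    bright, rot, flip_p = augment
    out = batch.copy()
    for i in range(len(out)):
        if bright > 0:
            out[i] *= 1.0 + rng.uniform(-bright, bright)
        if rot > 0:
            angle = rng.uniform(-rot, rot)
            out[i] = ndi.rotate(out[i], angle, reshape=False, order=1, mode="nearest")
        if flip_p > 0 and rng.random() < flip_p:
            out[i] = out[i][:, ::-1]
    return out


class TrainedClassifier:
    """A fitted constituent: predict_proba, embed, Grad-CAM and history."""

    def __init__(self, net: SmallCNN, config: ClassifierConfig, classes: tuple,
                 norm: tuple, history: pd.DataFrame):
        self._net = net
        self.config = config
        self.classes = tuple(classes)
        self._norm = norm  # (mean, sd) on resized training intensities
        self.history = history
        self.embed_dim = net.embed_dim

    def _prepare(self, images) -> np.ndarray:
        x = resize_images(images, self.config.input_side)
        mean, sd = self._norm
        return (x - mean) / sd

    def predict_proba(self, images, batch: int = 256) -> np.ndarray:
        x = self._prepare(images)
        return np.vstack(
            [self._net.predict_proba(x[i:i + batch]) for i in range(0, len(x), batch)]
        )

    def embed(self, images, batch: int = 256) -> np.ndarray:
        x = self._prepare(images)
        return np.vstack(
            [self._net.embed(x[i:i + batch]) for i in range(0, len(x), batch)]
        )

    def grad_cam_raw(self, images, target_idx: int) -> np.ndarray:
        x = self._prepare(images)
        return self._net.gradcam(x, target_idx)

    # -- single-file container ----------------------------------------------

    def save(self, path) -> None:
        state = self._net.get_state()
        arrays = {}
        for i, layer_params in enumerate(state):
            for k, v in layer_params.items():
                arrays[f"layer{i}:{k}"] = v
        meta = json.dumps(
            {
                "config": asdict(self.config),
                "classes": list(self.classes),
                "norm": [float(self._norm[0]), float(self._norm[1])],
                "history": self.history.to_dict(orient="list"),
            }
        )
        with open(path, "wb") as fh:
            np.savez_compressed(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                                **arrays)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            arrays = {k: z[k] for k in z.files if k != "__meta__"}
        cfg_dict = meta["config"]
        for key in ("conv_widths", "augment"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = ClassifierConfig(**cfg_dict)
        net = SmallCNN(config.input_side, config.conv_widths, config.dense_units,
                       config.dropout_rate, len(meta["classes"]), seed=config.seed)
        state = net.get_state()
        for key, v in arrays.items():
            i, name = key.split(":")
            state[int(i.removeprefix("layer"))][name] = v
        net.set_state(state)
        return cls(net, config, tuple(meta["classes"]), tuple(meta["norm"]),
                   pd.DataFrame(meta["history"]))


def _onehot(labels, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)), dtype=np.float32)
    for i, lab in enumerate(labels):
        out[i, idx[lab]] = 1.0
    return out


def train_classifier(images, labels, val_images, val_labels,
                     config: ClassifierConfig | None = None,
                     classes: tuple | None = None) -> TrainedClassifier:
    """Fit one constituent with augmentation and early stopping.

    Training stops when the validation cross-entropy has not improved for
    ``config.patience`` consecutive epochs (or at ``max_epochs``) and the
    weights of the best validation epoch are restored.  Augmentation is
    applied per batch during training only; validation is deterministic.
    """
    config = config or ClassifierConfig()
    config.validate()
    labels = list(labels)
    if len(labels) == 0:
        raise ValueError("empty training set")
    if classes is None:
        uniq = set(labels) | set(val_labels)
        classes = CLASSES if uniq <= set(CLASSES) else tuple(sorted(uniq))
    if len(set(labels)) == 1:
        warnings.warn("single-class training set; the classifier will be degenerate",
                      stacklevel=2)

    x_train = resize_images(images, config.input_side)
    x_val = resize_images(val_images, config.input_side)
    mean, sd = float(x_train.mean()), float(x_train.std() or 1.0)
    y_train = _onehot(labels, classes)
    y_val = _onehot(list(val_labels), classes)

    net = SmallCNN(config.input_side, config.conv_widths, config.dense_units,
                   config.dropout_rate, len(classes),
                   seed=child_seed(config.seed, "train", 0))
    opt = Adam(net, lr=config.learning_rate)
    rng = stream_rng(config.seed, "train", 1)

    best_val = np.inf
    best_state = net.get_state()
    best_epoch = 0
    since_improve = 0
    hist = []
    n = len(x_train)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        running = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = _augment_batch(x_train[idx], config.augment, rng)
            batch = (batch - mean) / sd
            running.append(net.loss_and_grads(batch, y_train[idx], train=True))
            opt.step()
        val_loss = net.loss((x_val - mean) / sd, y_val)
        hist.append({"epoch": epoch, "train_loss": float(np.mean(running)),
                     "val_loss": val_loss})
        if val_loss < best_val - 1e-9:
            best_val, best_epoch = val_loss, epoch
            best_state = net.get_state()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break
    net.set_state(best_state)
    history = pd.DataFrame(hist)
    history.attrs["best_epoch"] = best_epoch
    history.attrs["best_val_loss"] = best_val
    return TrainedClassifier(net, config, classes, (mean, sd), history)


# ---------------------------------------------------------------------------
# ensemble, inference, saliency

def ensemble_proba(models, images) -> np.ndarray:
    """Arithmetic mean of constituent probabilities (each model resizes its
    own input); rows still sum to 1 by convexity."""
    models = list(models)
    if not models:
        raise ValueError("empty model list")
    classes = models[0].classes
    if any(m.classes != classes for m in models):
        raise ValueError("all ensemble constituents must share one class space")
    return np.mean([m.predict_proba(images) for m in models], axis=0)


def predict_proba(model: TrainedClassifier, images) -> np.ndarray:
    if not isinstance(model, TrainedClassifier):
        raise NotFittedError("predict_proba needs a TrainedClassifier")
    return model.predict_proba(images)


def extract_embeddings(models, images) -> np.ndarray:
    """GAP-layer embeddings; for several models the embeddings are
    concatenated column-wise (the combined latent space)."""
    if isinstance(models, TrainedClassifier):
        return models.embed(images)
    models = list(models)
    if not models:
        raise ValueError("empty model list")
    return np.hstack([m.embed(images) for m in models])


def grad_cam(model: TrainedClassifier, image, target_class) -> Saliency:
    """Grad-CAM of the final convolutional layer for one image.

    Channel weights are spatial means of d(class logit)/d(feature map);
    the rectified weighted sum is bilinearly upsampled to the query
    image's own resolution.
    """
    if isinstance(target_class, str):
        if target_class not in model.classes:
            raise ValueError(f"class {target_class!r} not in {model.classes}")
        t_idx, t_name = model.classes.index(target_class), target_class
    else:
        t_idx = int(target_class)
        if not 0 <= t_idx < len(model.classes):
            raise ValueError(f"target class index {t_idx} out of range")
        t_name = model.classes[t_idx]
    image = np.asarray(image, dtype=np.float32)
    cam = model.grad_cam_raw(image[None], t_idx)[0]
    up = _sk_resize(cam, image.shape, order=1, preserve_range=True, anti_aliasing=False)
    return Saliency(map=np.maximum(up, 0.0), target_class=t_name)


def ensemble_grad_cam(models, image, target_class) -> Saliency:
    """Ensemble saliency: the mean of the constituents' Grad-CAM maps,
    each upsampled to the query image's resolution."""
    models = list(models)
    if not models:
        raise ValueError("empty model list")
    sals = [grad_cam(m, image, target_class) for m in models]
    return Saliency(map=np.mean([s.map for s in sals], axis=0),
                    target_class=sals[0].target_class)


def train_ensemble(images, labels, val_images, val_labels, sides=(48, 64),
                   base_config: ClassifierConfig | None = None,
                   classes: tuple | None = None) -> list:
    """Train the multi-resolution ensemble (one constituent per input side)."""
    base = base_config or ClassifierConfig()
    models = []
    for i, side in enumerate(sides):
        cfg = ClassifierConfig(**{**asdict(base), "input_side": int(side),
                                  "seed": child_seed(base.seed, "train", 100 + i)})
        cfg.conv_widths = tuple(cfg.conv_widths)
        cfg.augment = tuple(cfg.augment)
        models.append(train_classifier(images, labels, val_images, val_labels, cfg,
                                       classes=classes))
    return models


# ---------------------------------------------------------------------------
# Hyperband

def hyperband_brackets(budget_epochs: int, eta: int = 3) -> list:
    """Hyperband bookkeeping: list of brackets, each a list of
    (n_configs, epochs) successive-halving rounds."""
    R = budget_epochs
    if R < 1:
        raise ValueError("budget must be >= 1 epoch")
    s_max = int(np.floor(np.log(R) / np.log(eta)))
    B = (s_max + 1) * R
    brackets = []
    for s in range(s_max, -1, -1):
        n = int(np.ceil(B / R * eta**s / (s + 1)))
        r = R * eta**-s
        rounds = []
        for i in range(s + 1):
            n_i = int(np.floor(n * eta**-i))
            r_i = int(round(r * eta**i))
            rounds.append((max(n_i, 1), max(r_i, 1)))
        brackets.append(rounds)
    return brackets


@dataclass
class TuneResult:
    best_config: ClassifierConfig
    best_val_loss: float
    trials: pd.DataFrame = field(repr=False, default=None)


def tune_hyperband(search_space: dict, images, labels, val_images, val_labels,
                   base_config: ClassifierConfig | None = None,
                   budget_epochs: int = 9, eta: int = 3, seed: int = 0,
                   classes: tuple | None = None) -> TuneResult:
    """Hyperband search over ClassifierConfig fields.

    ``search_space`` maps field names (e.g. ``dense_units``,
    ``dropout_rate``, ``learning_rate``) to candidate-value lists.  Each
    sampled configuration is trained from scratch at its round's epoch
    budget; survivors of each successive-halving round are the
    lowest-validation-loss third.  The winner is the configuration with the
    lowest validation loss over all trials; every trial is kept in the
    ledger.
    """
    base = base_config or ClassifierConfig()
    for key in search_space:
        if not hasattr(base, key):
            raise ConfigurationError(f"unknown search field {key!r}")
    rng = stream_rng(seed, "tune")

    def sample() -> dict:
        return {k: v[int(rng.integers(0, len(v)))] for k, v in search_space.items()}

    def make_cfg(over: dict, epochs: int, i: int) -> ClassifierConfig:
        cfg = ClassifierConfig(**{**asdict(base), **over,
                                  "max_epochs": int(epochs),
                                  "seed": child_seed(seed, "tune", i)})
        cfg.conv_widths = tuple(cfg.conv_widths)
        cfg.augment = tuple(cfg.augment)
        cfg.validate()
        return cfg

    trials = []
    best = (np.inf, None)
    trial_i = 0
    for b, rounds in enumerate(hyperband_brackets(budget_epochs, eta)):
        n0, _ = rounds[0]
        candidates = [sample() for _ in range(n0)]
        for round_i, (n_i, r_i) in enumerate(rounds):
            candidates = candidates[:n_i]
            scored = []
            for over in candidates:
                cfg = make_cfg(over, r_i, trial_i)
                trial_i += 1
                model = train_classifier(images, labels, val_images, val_labels, cfg,
                                         classes=classes)
                vl = float(model.history.attrs["best_val_loss"])
                scored.append((vl, over))
                trials.append({"bracket": b, "round": round_i, "epochs": r_i,
                               **over, "val_loss": vl})
                if vl < best[0]:
                    best = (vl, over)
            scored.sort(key=lambda t: t[0])
            candidates = [o for _, o in scored]
    best_cfg = ClassifierConfig(**{**asdict(base), **best[1]})
    best_cfg.conv_widths = tuple(best_cfg.conv_widths)
    best_cfg.augment = tuple(best_cfg.augment)
    return TuneResult(best_cfg, best[0], pd.DataFrame(trials))
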