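"""Parametric 2-D reduction of latent (GAP) embeddings.

Two backends share one interface:

* ``linear`` — projection onto the top-2 principal directions, fully
  deterministic, with an exact out-of-sample transform.  It exists so the
  downstream attribution and drift modules can be tested against
  closed-form oracles.
* ``triplet`` — a small numpy MLP trained with a margin triplet loss, the
  fidelity path: anchors are paired with one of their k nearest neighbors
  (positive) and a random non-neighbor (negative), mirroring
  neighbor-based twin-network reducers used for latent-space monitoring.
  Like any neural reducer it is only seed-deterministic, not canonical.

Both produce a pure out-of-sample ``transform`` after fitting, which is
what a live drift monitor needs: new images are embedded into the same 2-D
space as the fitted reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from ._rng import stream_rng
from .errors import ConfigurationError, NotFittedError


@dataclass
class ReducerConfig:
    backend: str = "triplet"  # "triplet" | "linear"
    out_dims: int = 2
    k_neighbors: int = 15
    margin: float = 1.0
    epochs: int = 30
    hidden: int = 32
    learning_rate: float = 1e-2
    batch_size: int = 128
    seed: int = 0

    def validate(self) -> None:
        if self.backend not in ("triplet", "linear"):
            raise ConfigurationError(f"unknown backend {self.backend!r}")
        if self.out_dims != 2:
            raise ConfigurationError("out_dims is fixed at 2")
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be >= 1")


class FittedReducer:
    """Fitted state; ``transform`` is a pure function of its input."""

    def __init__(self, config: ReducerConfig, state: dict, d_in: int,
                 fingerprint: tuple, loss_history=None):
        self.config = config
        self._state = state
        self.d_in = d_in
        self.fingerprint = fingerprint  # (n, d, checksum) of the fit data
        self.loss_history = loss_history

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.d_in:
            raise ValueError(f"expected (n, {self.d_in}) input, got {X.shape}")
        if self.config.backend == "linear":
            return (X - self._state["mean"]) @ self._state["components"].T
        s = self._state
        h = np.maximum((X - s["mu"]) / s["sd"] @ s["W1"] + s["b1"], 0.0)
        return h @ s["W2"] + s["b2"]

    # single-file container -------------------------------------------------

    def save(self, path) -> None:
        import json

        meta = json.dumps({"config": self.config.__dict__, "d_in": self.d_in,
                           "fingerprint": list(self.fingerprint)})
        with open(path, "wb") as fh:
            np.savez_compressed(
                fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **self._state
            )

    @classmethod
    def load(cls, path) -> "FittedReducer":
        import json

        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            state = {k: z[k] for k in z.files if k != "__meta__"}
        return cls(ReducerConfig(**meta["config"]), state, meta["d_in"],
                   tuple(meta["fingerprint"]))


def fit_reducer(X, config: ReducerConfig | None = None) -> FittedReducer:
    """Fit the configured backend on an (n, d) matrix."""
    config = config or ReducerConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be (n, d) with d >= 2")
    n, d = X.shape
    if n < config.k_neighbors + 2:
        raise ValueError(
            f"need n >= k_neighbors + 2 = {config.k_neighbors + 2} rows, got {n}"
        )
    fingerprint = (n, d, float(np.abs(X).sum()))
    if config.backend == "linear":
        return _fit_linear(X, config, fingerprint)
    return _fit_triplet(X, config, fingerprint)


def _fit_linear(X, config, fingerprint) -> FittedReducer:
    mean = X.mean(axis=0)
    Xc = X - mean
    # top-2 right singular vectors = top-2 principal directions
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    comps = vt[:2]
    # deterministic sign: largest-|.| loading positive per axis
    for i in range(2):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return FittedReducer(config, {"mean": mean, "components": comps}, X.shape[1],
                         fingerprint)


def _fit_triplet(X, config, fingerprint) -> FittedReducer:
    rng = stream_rng(config.seed, "reduce")
    n, d = X.shape
    # center and scale by one global factor: per-feature standardization
    # would flatten exactly the high-variance directions that carry the
    # cluster structure we want the map to preserve
    mu = X.mean(axis=0)
    scale = X.std() or 1.0
    sd = np.full(d, scale)
    Z = (X - mu) / sd

    nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(Z)
    neigh = nn.kneighbors(Z, return_distance=False)[:, 1:]  # drop self
    neigh_sets = [set(row) | {i} for i, row in enumerate(neigh)]

    h = config.hidden
    W1 = rng.normal(0, np.sqrt(2.0 / d), size=(d, h))
    b1 = rng.normal(0, 0.5, size=h)
    # warm start: read the top-2 principal coordinates out of the random
    # ReLU features by least squares, so triplet refinement starts from a
    # globally sensible layout instead of a random collapse
    _, _, vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    target = (Z - Z.mean(axis=0)) @ vt[:2].T
    H0 = np.maximum(Z @ W1 + b1, 0.0)
    H0a = np.column_stack([H0, np.ones(n)])
    sol, *_ = np.linalg.lstsq(H0a, target, rcond=None)
    W2, b2 = sol[:-1], sol[-1]
    params = [W1, b1, W2, b2]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    t = 0

    def fwd(idx):
        z = Z[idx]
        a = z @ W1 + b1
        hh = np.maximum(a, 0.0)
        return z, a, hh, hh @ W2 + b2

    losses = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = []
        for start in range(0, n, config.batch_size):
            anchors = order[start:start + config.batch_size]
            pos = np.array([neigh[i][rng.integers(0, neigh.shape[1])] for i in anchors])
            negs = []
            for i in anchors:
                while True:
                    cand = int(rng.integers(0, n))
                    if cand not in neigh_sets[i]:
                        negs.append(cand)
                        break
            neg = np.array(negs)

            za, aa, ha, fa = fwd(anchors)
            zp, ap, hp, fp = fwd(pos)
            zn, an, hn, fn = fwd(neg)
            d_ap = ((fa - fp) ** 2).sum(axis=1)
            d_an = ((fa - fn) ** 2).sum(axis=1)
            loss_vec = np.maximum(0.0, d_ap - d_an + config.margin)
            epoch_loss.append(float(loss_vec.mean()))
            active = loss_vec > 0
            if not active.any():
                continue
            k = active.sum()
            dfa = 2.0 * ((fn - fp) * active[:, None]) / k
            dfp = -2.0 * ((fa - fp) * active[:, None]) / k
            dfn = 2.0 * ((fa - fn) * active[:, None]) / k

            gW1 = np.zeros_like(W1); gb1 = np.zeros_like(b1)
            gW2 = np.zeros_like(W2); gb2 = np.zeros_like(b2)
            for z, a, hh, df in ((za, aa, ha, dfa), (zp, ap, hp, dfp), (zn, an, hn, dfn)):
                gW2 += hh.T @ df
                gb2 += df.sum(axis=0)
                dh = (df @ W2.T) * (a > 0)
                gW1 += z.T @ dh
                gb1 += dh.sum(axis=0)

            t += 1
            for p, g, m, v in zip(params, [gW1, gb1, gW2, gb2], m_t, v_t):
                m[...] = 0.9 * m + 0.1 * g
                v[...] = 0.999 * v + 0.001 * g * g
                p -= config.learning_rate * (m / (1 - 0.9**t)) / (
                    np.sqrt(v / (1 - 0.999**t)) + 1e-8
                )
        losses.append(float(np.mean(epoch_loss)))

    state = {"mu": mu, "sd": sd, "W1": W1, "b1": b1, "W2": W2, "b2": b2}
    return FittedReducer(config, state, d, fingerprint, loss_history=losses)


def transform(reducer: FittedReducer, X_new) -> np.ndarray:
    """Out-of-sample coordinates, rows aligned with the input."""
    if not isinstance(reducer, FittedReducer):
        raise NotFittedError("transform needs a FittedReducer")
    return reducer.transform(X_new)
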