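import numpy as np
import pytest

import ngtlife as ng


@pytest.fixture(scope="session")
def small_manifest():
    """A 60-record synthetic cohort used by curation and pipeline tests."""
    return ng.generate_manifest(ng.SynthConfig(n_images=60, seed=7))


def toy_quadrant_images(n: int, side: int = 32, seed: int = 0):
    """Linearly separable 2-class toy: class 'b' has a bright top-left quadrant."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, size=(n, side, side)).astype(np.float32)
    y = rng.integers(0, 2, size=n)
    half = side // 2
    for i in range(n):
        if y[i]:
            x[i, :half, :half] += 3.0
    return x, np.where(y, "b", "a")


@pytest.fixture(scope="session")
def toy_model():
    """A small trained 2-class classifier shared by inference-contract tests."""
    xtr, ytr = toy_quadrant_images(200, seed=0)
    xv, yv = toy_quadrant_images(60, seed=1)
    cfg = ng.ClassifierConfig(input_side=32, conv_widths=(4, 8), dense_units=32,
                              dropout_rate=0.0, max_epochs=15, patience=5, seed=0)
    return ng.train_classifier(xtr, ytr, xv, yv, cfg, classes=("a", "b"))
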