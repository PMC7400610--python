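import numpy as np
import pytest
from hypothesis import settings

from gazerec import Apparatus, SimConfig, build_histogram, simulate_study

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def apparatus():
    return Apparatus()


@pytest.fixture(scope="session")
def small_study():
    """5 subjects x 10 images at full rate: shared across read-only tests."""
    cfg = SimConfig(n_subjects=5, n_images=10, seed=11)
    trials, truths = simulate_study(cfg)
    return cfg, trials, truths


@pytest.fixture(scope="session")
def small_hists(small_study):
    _, trials, _ = small_study
    return [build_histogram(s) for s in trials]


def make_blob_hists(n_classes=5, per_class=20, G=24, n_subjects=None, seed=0):
    """Separable toy histograms: one Gaussian blob per class.

    Returns (X, y, subjects) with X of shape (n, G, G).
    """
    rng = np.random.default_rng(seed)
    X, y, subjects = [], [], []
    for c in range(n_classes):
        cx = 3 + (17 * c) % (G - 6)
        cy = 4 + (11 * c) % (G - 8)
        for r in range(per_class):
            h = np.zeros((G, G))
            ii = np.clip(np.round(rng.normal(cy, 1.5, 60)).astype(int), 0, G - 1)
            jj = np.clip(np.round(rng.normal(cx, 1.5, 60)).astype(int), 0, G - 1)
            np.add.at(h, (ii, jj), 1.0)
            X.append(h)
            y.append(f"c{c}")
            subjects.append(f"s{r % n_subjects}" if n_subjects else f"s{r}")
    return np.stack(X), np.array(y), np.array(subjects)
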