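import numpy as np
import pytest

from msdaelm import LabeledFeatureSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_set(rng, n=8, dim=2, offset=0.0, labels=True, domain="D"):
    X = rng.normal(size=(n, dim)) + offset
    y = rng.integers(0, 2, size=n) if labels else None
    return LabeledFeatureSet(X, y, domain_id=domain)


@pytest.fixture
def two_class_pair(rng):
    """Seeded labeled source/target pair with both classes on both sides."""
    def build(n=10, dim=3, offset=0.5):
        ys = np.array([0, 1] * (n // 2))
        Xs = rng.normal(size=(n, dim)) + ys[:, None]
        yt = np.array([0, 1] * (n // 2))
        Xt = rng.normal(size=(n, dim)) + yt[:, None] + offset
        return (LabeledFeatureSet(Xs, ys, domain_id="S"),
                LabeledFeatureSet(Xt, yt, domain_id="T"))
    return build
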