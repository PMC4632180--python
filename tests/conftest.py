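import numpy as np
import pytest

from cpemm.dataio import Dataset, FeatureMeta
from cpemm.synthgen import SyntheticSpec, generate


def make_dataset(X, y, classes=None, kinds=None, categories=None, names=None):
    """Small-matrix Dataset builder for hand-written examples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if classes is None:
        seen = []
        for v in y:
            if v not in seen:
                seen.append(v)
        classes = tuple(seen)
    d = X.shape[1]
    kinds = kinds or ["numeric"] * d
    names = names or [f"f{j}" for j in range(d)]
    feats = []
    for j in range(d):
        if kinds[j] == "nominal":
            feats.append(FeatureMeta(names[j], "nominal", categories=tuple(categories[j])))
        else:
            feats.append(FeatureMeta(names[j], "numeric"))
    return Dataset(X=X, y=y, classes=classes, features=feats).refresh_missing_fractions()


@pytest.fixture
def tiny_planted():
    """300 x 10 three-class set with 3 strong informative features, no missing."""
    spec = SyntheticSpec(class_counts=(("NL", 80), ("MCI", 160), ("AD", 60)),
                         n_informative=3, n_redundant=2, n_noise=5,
                         effect=2.5, missing_rate=0.0, seed=42)
    return generate(spec)


@pytest.fixture
def separable_two_class():
    """Two well-separated Gaussian classes on 2 of 4 features."""
    rng = np.random.default_rng(7)
    n = 60
    X = rng.normal(size=(2 * n, 4))
    X[:n, 0] += 6.0
    X[n:, 1] += 6.0
    y = np.array(["pos"] * n + ["neg"] * n, dtype=object)
    return make_dataset(X, y, classes=("pos", "neg"))
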