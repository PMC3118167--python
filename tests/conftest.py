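import numpy as np
import pandas as pd
import pytest

from hairpinnet import FeatureMatrix, build_graph, featurize_records, make_dataset

HAIRPIN9 = "(((...)))"


@pytest.fixture(scope="session")
def hairpin9_graph():
    return build_graph(HAIRPIN9)


@pytest.fixture(scope="session")
def small_records():
    """120 labelled synthetic records (60 per class), fixed seed."""
    return make_dataset(60, 60, seed=7)


@pytest.fixture(scope="session")
def small_features(small_records):
    return featurize_records(small_records)


def gaussian_design(n_per_class, shifts, n_noise, seed, names=None):
    """Two-class Gaussian feature matrix: shifted informative + pure noise.

    Positive-class rows are shifted by ``shifts[f]`` in informative
    feature f; noise features are N(0,1) in both classes.
    """
    rng = np.random.default_rng(seed)
    p = len(shifts) + n_noise
    X = rng.standard_normal((2 * n_per_class, p))
    for f, shift in enumerate(shifts):
        X[:n_per_class, f] += shift
    y = np.array(["positive"] * n_per_class + ["negative"] * n_per_class,
                 dtype=object)
    if names is None:
        names = [f"f{k:02d}" for k in range(p)]
    frame = pd.DataFrame(X, columns=names)
    ids = [f"r{k:04d}" for k in range(2 * n_per_class)]
    return FeatureMatrix(ids=ids, X=frame, y=y)
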