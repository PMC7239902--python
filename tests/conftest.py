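import numpy as np
import pandas as pd
import pytest

from stabselect import CohortSpec, FeatureMatrix
from stabselect.matrix import feature_universe, meta_for_ids


@pytest.fixture
def tiny_spec():
    """A fast cohort: 4+4 development, 2+2 test, 4 trials per condition."""
    return CohortSpec(n_per_group_dev=4, n_per_group_test=2,
                      trials_per_condition=4, seed=7)


@pytest.fixture
def null_spec():
    """No planted effects, no variability inflation."""
    return CohortSpec(planted_features=(), variability_inflation=1.0, seed=11)


def random_matrix(n_per_group=8, n_features=20, seed=0, shift=None):
    """Ad-hoc two-class matrix with generic feature ids (not the cohort layout)."""
    rng = np.random.default_rng(seed)
    ids = [f"kinematic:general:direct:duration:mean"] if False else None
    fids = feature_universe(("general",))[:n_features]
    X = rng.standard_normal((2 * n_per_group, n_features))
    if shift is not None:
        X[:n_per_group, :len(shift)] += shift
    samples = [f"A{i}" for i in range(n_per_group)] + [f"N{i}" for i in range(n_per_group)]
    labels = pd.Series(["autistic"] * n_per_group + ["non-autistic"] * n_per_group,
                       index=samples)
    values = pd.DataFrame(X, index=samples, columns=fids)
    return FeatureMatrix(values, labels, meta_for_ids(fids))


@pytest.fixture
def small_matrix():
    return random_matrix(n_per_group=8, n_features=20, seed=3)
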