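import numpy as np
import pytest

from hurstfmri.features import FeatureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(
    n_mci=10,
    n_hc=10,
    n_features=6,
    effect=0.0,
    affected=(),
    noise=1.0,
    seed=0,
) -> FeatureMatrix:
    """Gaussian feature matrix with an additive group shift on chosen columns."""
    r = np.random.default_rng(seed)
    n = n_mci + n_hc
    values = r.standard_normal((n, n_features)) * noise
    values[:n_mci, list(affected)] += effect
    return FeatureMatrix(
        values=values,
        subject_ids=[f"sub-{i:03d}" for i in range(n)],
        groups=["MCI"] * n_mci + ["HC"] * n_hc,
        roi_labels=list(range(1, n_features + 1)),
    )


@pytest.fixture
def separable_matrix():
    """Two distant clusters: any mid-grid SVM should classify perfectly."""
    return make_matrix(
        n_mci=8, n_hc=8, n_features=2, effect=8.0, affected=(0, 1), noise=0.5, seed=7
    )
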