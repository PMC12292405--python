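import numpy as np
import pytest

from evoslide.synthetic import (
    SyntheticFeatureSpec,
    SyntheticSlideSpec,
    gen_feature_set,
    gen_slide,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lowvar_feature_set():
    """Class signal on one low-variance axis, high-variance nuisance elsewhere."""
    spec = SyntheticFeatureSpec(
        n_per_class=200, dim=20, signal_axes=(0,), separation_delta=6.0,
        signal_sd=0.5, nuisance_sd=5.0, seed=7,
    )
    fm, labels = gen_feature_set(spec)
    return fm.values, labels


@pytest.fixture(scope="session")
def blob_slide():
    return gen_slide(SyntheticSlideSpec(class_label=0, seed=11))


@pytest.fixture(scope="session")
def stripe_slide():
    return gen_slide(SyntheticSlideSpec(class_label=1, seed=12))
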