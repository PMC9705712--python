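import numpy as np
import pytest

from seedtax import synthetic as syn
from seedtax import preprocess as pp


@pytest.fixture(scope="session")
def library():
    return syn.make_phenotype_library(12, 1.0, 7)


@pytest.fixture(scope="session")
def quiet_scene():
    return syn.SyntheticScene(noise_sd=0.0, n_debris=0, metadata_bar_height=0)


@pytest.fixture(scope="session")
def default_image(library):
    """One rendered frame with the default busy scene."""
    return syn.render_seed_image(library[0], syn.SyntheticScene(), rng_seed=123)


@pytest.fixture(scope="session")
def standard_image(default_image):
    result = pp.preprocess_image(default_image.pixels)
    assert isinstance(result, pp.StandardImage)
    return result


@pytest.fixture(scope="session")
def small_table():
    """Well-separated 6-class feature table for quick harness runs."""
    spec = syn.equal_covariance_feature_spec(n_classes=6, separation=4.0, rng_seed=5)
    return syn.sample_feature_table(spec, n_per_class=40, rng_seed=5)
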