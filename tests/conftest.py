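import dataclasses

import numpy as np
import pytest

import samaradisp as sd
from samaradisp import fixtures as fx


@pytest.fixture(scope="session")
def table2_truth() -> sd.ModelParameters:
    """Published point estimates used as generating truth throughout."""
    return fx.table2_parameters()


@pytest.fixture(scope="session")
def study_config():
    """Generator at the study conditions: 13 species, Table-1 counts."""
    return fx.default_generator_config(rng_seed=11)


@pytest.fixture(scope="session")
def study_dataset(study_config):
    df, truth = sd.generate_releases(study_config)
    return df


@pytest.fixture(scope="session")
def small_config(study_config):
    """Same panel, 12 fruit per species: cheap fits, dense-oracle friendly."""
    profiles = tuple(
        dataclasses.replace(p, n_fruit=12) for p in study_config.species_profiles
    )
    return dataclasses.replace(study_config, species_profiles=profiles, rng_seed=5)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    df, _ = sd.generate_releases(small_config)
    return df


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    y, X, g, _ = sd.design_from_frame(small_dataset)
    return sd.fit_lmm(y, X, g), X, g


@pytest.fixture(scope="session")
def small_boot(small_fit):
    fit, X, g = small_fit
    return sd.bootstrap(fit, X, g, B=80, base_seed=17)
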