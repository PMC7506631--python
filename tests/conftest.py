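"""Shared fixtures: one seeded sensor array and its derived datasets.

Session-scoped because simulation + DWT of 424-point traces is the
costly part of the suite; all tests treat these objects as read-only.
"""

import warnings
from dataclasses import replace

import pytest

import etongue as et

warnings.filterwarnings("ignore", message="dropping .* degenerate feature")


@pytest.fixture(scope="session")
def wavelet():
    return et.WaveletSpec()


@pytest.fixture(scope="session")
def array_specs():
    """Default 8-sensor array (4 informative, 2 redundant, 2 noisy)."""
    return et.default_array_specs(4, 2, 2, seed=0)


@pytest.fixture(scope="session")
def selection_ds(array_specs):
    specs, _roles = array_specs
    return et.simulate_selection_dataset(specs, seed=7)


@pytest.fixture(scope="session")
def selection_fb(selection_ds, wavelet):
    return et.build_feature_blocks(selection_ds, wavelet)


@pytest.fixture(scope="session")
def informative_specs(array_specs):
    specs, roles = array_specs
    return [s for s in specs if roles[s.sensor_id] == "informative"]


@pytest.fixture(scope="session")
def noise_free_specs(informative_specs):
    """Informative sensors with noise and drift switched off."""
    return [
        replace(s, noise_sd_uA=0.0, drift_per_sample_uA=0.0)
        for s in informative_specs
    ]


@pytest.fixture(scope="session")
def mixture_fbs(noise_free_specs, wavelet):
    """Noise-free (train, test) feature blocks for the default design."""
    design = et.DesignSpec()
    train = et.simulate_mixture_dataset(
        noise_free_specs, et.tilted_factorial(design),
        analytes=design.analytes, seed=2,
    )
    test = et.simulate_mixture_dataset(
        noise_free_specs, et.random_test_points(design),
        analytes=design.analytes, seed=3,
    )
    return (
        et.build_feature_blocks(train, wavelet),
        et.build_feature_blocks(test, wavelet),
    )
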