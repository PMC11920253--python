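"""Shared fixtures: compact phantoms sized for fast unit tests.

The small phantom uses a 256 x 256 matrix with the same pixel spacing and
window sizes as the full-size default, so all window-to-structure size
relations of the segmentation are preserved.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fatseg import autoseg, phantom

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_spec(**overrides) -> phantom.PhantomSpec:
    """A compact phantom: same pixel size, smaller matrix and body."""
    kwargs = dict(
        matrix=(256, 256),
        body_semiaxes_mm=(120.0, 95.0),
        sat_inner_semiaxes_mm=(92.0, 70.0),
        n_blobs=4,
        blob_radius_mm=(6.0, 10.0),
        n_slices=2,
        seed=11,
    )
    kwargs.update(overrides)
    return phantom.PhantomSpec(**kwargs)


def small_noise_free_spec(**overrides) -> phantom.PhantomSpec:
    kwargs = dict(lean_sd=0.0, fat_sd=0.0, noise_sd=0.0, bias_amplitude=0.0)
    kwargs.update(overrides)
    return small_spec(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    """(series, truth) for the default compact phantom."""
    return phantom.generate_phantom(small_spec())


@pytest.fixture(scope="session")
def small_noise_free_phantom():
    return phantom.generate_phantom(small_noise_free_spec())


@pytest.fixture(scope="session")
def segmented_small(small_phantom):
    series, truth = small_phantom
    return series, truth, autoseg.segment_series(series)


@pytest.fixture(scope="session")
def segmented_small_noise_free(small_noise_free_phantom):
    series, truth = small_noise_free_phantom
    return series, truth, autoseg.segment_series(series)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
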