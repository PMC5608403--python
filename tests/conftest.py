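import numpy as np
import pytest

from cyclemap import simdata


@pytest.fixture(scope="session")
def small_config():
    return simdata.SimConfig(n_cells=40, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simdata.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_renderer(small_cohort):
    return simdata.MovieRenderer(small_cohort)


def disk_image(shape, centers, radius, value, background=0.0):
    """Hard-edged disks on a constant background."""
    img = np.full(shape, background, dtype=float)
    rr, cc = np.indices(shape)
    for (r, c) in centers:
        img[(rr - r) ** 2 + (cc - c) ** 2 <= radius ** 2] += value
    return img


def disk_mask(shape, center, radius):
    rr, cc = np.indices(shape)
    return ((rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2)
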