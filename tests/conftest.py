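import numpy as np
import pytest

from metacomm.core_io import CommunityMatrix, SiteGeometry
from metacomm.synthetic_data import fixture_small


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_world():
    """Deterministic 8-site, 10-species synthetic miniature."""
    return fixture_small(seed=7)


@pytest.fixture
def toy_cm():
    """3 sites x 4 species with hand-chosen counts."""
    values = np.array([
        [2, 0, 1, 0],
        [1, 3, 0, 0],
        [0, 1, 1, 5],
    ], dtype=float)
    return CommunityMatrix(("a", "b", "c"), ("w", "x", "y", "z"), values)


@pytest.fixture
def toy_geom():
    return SiteGeometry(("a", "b", "c"), np.array([45.0, 45.5, 46.0]),
                        np.array([87.0, 87.2, 86.8]))


def random_geometry(rng, n, lat0=44.0, lon0=85.0, spread=3.0):
    lat = lat0 + rng.uniform(0, spread, n)
    lon = lon0 + rng.uniform(0, spread, n)
    ids = tuple(f"s{i}" for i in range(n))
    return SiteGeometry(ids, lat, lon)


def random_community(rng, n_sites, n_species, density=0.4, counts=False):
    """Random community with no empty sites and no all-absent species."""
    while True:
        inc = (rng.random((n_sites, n_species)) < density).astype(float)
        if inc.sum(axis=1).all() and inc.sum(axis=0).all():
            break
    if counts:
        inc *= rng.integers(1, 6, size=inc.shape)
    ids = tuple(f"s{i}" for i in range(n_sites))
    sps = tuple(f"sp{k}" for k in range(n_species))
    return CommunityMatrix(ids, sps, inc)
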