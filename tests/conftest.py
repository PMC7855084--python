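"""Shared fixtures: phantom cohorts are expensive, so each cohort is
generated once per session and reused by the estimator, classification and
acceptance tests."""

import numpy as np
import pytest

from osteomorph.pipeline import analyse_cylinder_cohort, analyse_ellipsoid_cohort

#: fixed session seed for cohort fixtures
SEED = 77003

ASPECTS = (1.0, 1.25, 1.5, 3.0)


@pytest.fixture(scope="session")
def cylinder_cohorts():
    """Four aspect-ratio cohorts of 100 randomly rotated cylinders,
    half-scale domain (length 200, edge 250, diameter 10 voxels)."""
    return {
        aspect: analyse_cylinder_cohort(
            aspect, n=100, seed=SEED + 1000 * k, length=200.0, domain_edge=250)
        for k, aspect in enumerate(ASPECTS)
    }


@pytest.fixture(scope="session")
def ellipsoid_cohorts():
    """Lacuna cohorts (100 each) per alignment mode and voxel size."""
    out = {}
    k = 0
    for mode in ("woven", "parallel_fibred"):
        for voxel_size in (1.6, 0.8, 0.33):
            out[(mode, voxel_size)] = analyse_ellipsoid_cohort(
                voxel_size, mode, n=100, seed=SEED + 50000 + 1000 * k)
            k += 1
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
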