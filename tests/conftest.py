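"""Shared fixtures: small synthetic cohorts and run factories.

Everything is generated at test time; grids and volume counts are scaled
down from the study defaults so unit tests stay fast, while acceptance
properties use the full default conditions.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rsmvpa.preprocess import BoldRun
from rsmvpa.synthetic_cohort import RegionSpec, SyntheticConfig, ellipsoid_mask, generate_cohort

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


def small_config(**overrides) -> SyntheticConfig:
    """A fast cohort: 8 subjects, 12^3 grid, 65 acquired volumes."""
    defaults = dict(
        n_subjects=8,
        n_remitted=4,
        grid_shape=(12, 12, 12),
        n_volumes=65,
        alff_effect_regions=(RegionSpec(center=(4, 6, 6), radius=2.0, remitted=2.0, persistent=1.0),),
        hub_effect_regions=(RegionSpec(center=(8, 6, 6), radius=2.0, remitted=1.2, persistent=0.2),),
        seed=7,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_mask():
    return ellipsoid_mask((12, 12, 12))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_run(data: np.ndarray, tr_s: float = 2.0, **kw) -> BoldRun:
    return BoldRun(data=np.asarray(data, dtype=np.float64), tr_s=tr_s, **kw)


def run_from_series(series: np.ndarray, tr_s: float = 2.0) -> tuple[BoldRun, np.ndarray]:
    """Wrap an (n_voxels, t) series block as a 1-voxel-thick run + full mask."""
    series = np.atleast_2d(series)
    n, t = series.shape
    data = series.reshape(n, 1, 1, t)
    mask = np.ones((n, 1, 1), dtype=bool)
    return make_run(data, tr_s), mask
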