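"""Shared fixtures: small seeded synthetic cohorts and their spectrum tables."""

import numpy as np
import pytest

from spectropath.annotation import extract_spectra
from spectropath.cube_io import WavelengthGrid, crop_spectral
from spectropath.synthetic import CohortConfig, simulate_cohort

USABLE_RANGE_NM = (500.0, 750.0)

#: compact study conditions for unit tests: fewer patients and smaller fields
#: than the default cohort, same spectral physics
SMALL_COHORT_CONFIG = CohortConfig(n_patients=6, cube_height=48, cube_width=48,
                                   roi_radius=2.5, rng_seed=0)


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return WavelengthGrid()


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL_COHORT_CONFIG)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    """Annotated pixel spectra of the small cohort, cropped to 500-750 nm."""
    cubes = [crop_spectral(c, *USABLE_RANGE_NM) for c in small_cohort.cubes]
    return extract_spectra(cubes, small_cohort.rois, small_cohort.patients)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
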