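"""Shared fixtures: desk-scale synthetic cohorts and images.

Study-condition constants for the heavier end-to-end tests live here so
every test draws the same cohorts.  Simulation sizes are reduced relative
to a real acquisition (hundreds rather than thousands of spectra per
lesion); docs/methods.md records the problem sizes used.
"""

import numpy as np
import pytest
from hypothesis import settings

from oedftir import SimConfig, simulate_cohort, simulate_image

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")

#: Desk-scale cohort conditions used by the end-to-end evaluation tests:
#: the study's 10 T + 7 NT design with reduced spectra per lesion.
DESK_SPECTRA_RANGE = (120, 160)
DESK_N_PER_SAMPLE = 100


@pytest.fixture(scope="session")
def default_axis():
    from oedftir import make_axis

    return make_axis()


@pytest.fixture(scope="session")
def small_cohort():
    """10 T + 7 NT desk-scale cohort at the calibrated defaults (seed 1)."""
    return simulate_cohort(SimConfig(spectra_per_lesion=DESK_SPECTRA_RANGE, seed=1))


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 T + 3 NT cohort for cheap CV mechanics tests."""
    return simulate_cohort(
        SimConfig(n_T=3, n_NT=3, spectra_per_lesion=(40, 50), seed=2)
    )


@pytest.fixture(scope="session")
def layered_image():
    return simulate_image(SimConfig(seed=3), shape=(40, 40))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
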