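import numpy as np
import pytest
from hypothesis import settings

import megpls as m

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


# A small three-group, four-feature brain matrix with two subjects per
# group, used wherever a hand-checkable mean-centered decomposition is
# needed.  Values are exact binary fractions so group means are exact.
TOY_X = np.array(
    [
        [0.50, 0.25, 0.125, 0.750],
        [0.25, 0.50, 0.375, 0.500],
        [0.75, 0.75, 0.250, 0.250],
        [1.00, 0.50, 0.500, 0.125],
        [0.25, 1.00, 0.625, 0.875],
        [0.50, 0.75, 0.875, 0.625],
    ]
)
TOY_GROUPS = np.array(["ELGA", "ELGA", "VLGA", "VLGA", "Term", "Term"])


@pytest.fixture(scope="session")
def toy_brain():
    return TOY_X.copy(), TOY_GROUPS.copy()


@pytest.fixture(scope="session")
def small_leadfield():
    return m.make_toy_leadfield(grid_spacing_mm=40.0, n_sensors=40, sphere_radius_mm=90.0)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the generator's default study conditions."""
    cfg = m.SyntheticCohortConfig(seed=1234)
    return m.generate_power_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Planted-slowing cohort at 20/20/20 with 50 sources."""
    cfg = m.SyntheticCohortConfig(
        seed=77, n_per_group=(20, 20, 20), n_sources=50, contrast_effect=1.0
    )
    return m.generate_power_cohort(cfg)
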