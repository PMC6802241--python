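import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from edsim.calibration import default_anchor_targets
from edsim.parameters import table1_bounds, table1_means
from edsim.synthetic_data import (
    SyntheticDesign,
    default_incidence_bounds,
    default_shapes,
    synthetic_life_table,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=30, database=None,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return SyntheticDesign()


@pytest.fixture(scope="session")
def life_table(design):
    return synthetic_life_table(design)


@pytest.fixture(scope="session")
def shapes(design):
    return default_shapes(design)


@pytest.fixture(scope="session")
def full_bounds(shapes, life_table):
    """All 80 scalar parameters free at their printed prior bounds."""
    return table1_bounds(shapes, life_table,
                         incidence_bounds=default_incidence_bounds())


@pytest.fixture(scope="session")
def anchor_bounds(shapes, life_table):
    """Only the 8 incidence multipliers free; all else at printed means."""
    return table1_bounds(shapes, life_table,
                         incidence_bounds=default_incidence_bounds(),
                         fixed=table1_means())


@pytest.fixture(scope="session")
def anchor_targets():
    return default_anchor_targets()


@pytest.fixture(scope="session")
def ps_means(anchor_bounds):
    """Printed calibrated means with mid-bound incidence multipliers."""
    mid = (anchor_bounds.lower() + anchor_bounds.upper()) / 2
    return anchor_bounds.build(mid)


@pytest.fixture(scope="session")
def ps_sampled(full_bounds):
    """One valid draw from the full printed priors."""
    from edsim.parameters import sample_valid_parameter_set

    ps, _ = sample_valid_parameter_set(full_bounds, np.random.default_rng(1234))
    return ps


@pytest.fixture(scope="session")
def small_cohort(ps_means):
    from edsim.microsim import BASELINE, simulate_cohort

    return simulate_cohort(ps_means, BASELINE, 10_000, 42)
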