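import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import qluc10d as q

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_spec():
    """Exhaustively enumerable attribute space: 2 binary QoL dimensions
    plus a 2-level duration."""
    return q.AttributeSpec(
        dimensions=("mobility", "mood"), n_levels=2, duration_levels=(1, 2)
    )


@pytest.fixture(scope="session")
def small_design():
    return q.generate_design(n_sets=60, overlap=4, n_iter=80, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_design):
    """Medium synthetic cohort on the small design, published truth."""
    plans = q.allocate(small_design, 300, 12, seed=12)
    return q.simulate_choices(plans, small_design, seed=13)


@pytest.fixture(scope="session")
def full_design():
    """Study-scale design: 960 sets, overlap 4."""
    return q.generate_design(n_sets=960, overlap=4, n_iter=300, seed=101)


@pytest.fixture(scope="session")
def full_cohort(full_design):
    """Study-scale cohort: 2,435 respondents x 16 pairs, published truth."""
    plans = q.allocate(full_design, 2435, 16, seed=102)
    return q.simulate_choices(plans, full_design, seed=103)


@pytest.fixture(scope="session")
def full_fit(full_cohort):
    return q.fit(full_cohort)
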