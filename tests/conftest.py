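import numpy as np
import pytest

from telosim import ErrorModel, GroupSpec, ScenarioSpec, simulate_cohort


def random_small_cohort(seed, n_per_group=15, cv=5.0, baseline_diff=141.0,
                        delta_diff=0.0, follow_up_years=10.0):
    """A small random cohort for property checks, parameters jittered by seed."""
    rng = np.random.default_rng(seed)
    b0 = 7500.0 + rng.uniform(-200, 200)
    spec = ScenarioSpec(
        label="custom",
        exposed=GroupSpec(b0 - baseline_diff, 777.0, -41.0 - delta_diff / 2, 46.0),
        unexposed=GroupSpec(b0, 777.0, -41.0 + delta_diff / 2, 46.0),
        follow_up_years=follow_up_years,
        n_exposed=n_per_group,
        n_unexposed=n_per_group,
    )
    err = ErrorModel.none() if cv == 0 else ErrorModel.proportional(cv)
    return simulate_cohort(spec, err, int(rng.integers(0, 2**31 - 1)))


@pytest.fixture
def small_cohort():
    return random_small_cohort(seed=123, n_per_group=20, cv=4.0)
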