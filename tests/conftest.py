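import pytest
from hypothesis import HealthCheck, settings

import limbwear as lw

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> lw.CohortConfig:
    """Two participants × two days: enough structure for fused analyses."""
    return lw.CohortConfig(n_participants=2, n_days=2, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Truth schedules with rendered wrist and thigh streams."""
    out = []
    for truth in lw.simulate_truth(small_config):
        out.append(
            (
                truth,
                lw.render_wrist(truth, small_config),
                lw.render_thigh(truth, small_config),
            )
        )
    return out


@pytest.fixture(scope="session")
def small_results(small_cohort):
    """Full pipeline products for the small cohort."""
    return [
        (truth, lw.run_participant(wrist, thigh))
        for truth, wrist, thigh in small_cohort
    ]
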