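import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (29 lines, 1500 loci) shared across test modules."""
    from evopool.simulate import CohortConfig, generate_cohort

    cfg = CohortConfig(
        master_seed=7,
        group_sizes={"Low": 8, "Medium": 8, "High": 8, "OB": 5},
        n_loci=1500,
    )
    return generate_cohort(cfg)
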