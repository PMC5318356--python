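import pytest
from hypothesis import settings

from migranet import (
    ENDPOINTS,
    NMAConfig,
    SimulationScenario,
    fit_nma,
    simulate_network,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


TRIANGLE = {
    ("placebo", "topiramate"): 10,
    ("placebo", "propranolol"): 10,
    ("topiramate", "propranolol"): 10,
}


@pytest.fixture(scope="session")
def triangle_scenario():
    """Consistent 3-treatment binary network with known truth."""
    return SimulationScenario(
        treatments=("placebo", "topiramate", "propranolol"),
        true_d={"topiramate": -0.5, "propranolol": -1.0},
        tau=0.1,
        trials_per_comparison=TRIANGLE,
        n_per_arm=200,
        endpoint=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def triangle_sim(triangle_scenario):
    return simulate_network(triangle_scenario)


@pytest.fixture(scope="session")
def quick_config():
    """MCMC settings small enough for unit tests, large enough to mix."""
    return NMAConfig(chains=4, iterations=8_000, burnin=2_000, thin=3, seed=1)


@pytest.fixture(scope="session")
def triangle_post(triangle_sim, quick_config):
    return fit_nma(triangle_sim.arms, 4, quick_config)


def make_arm(study="S1", treat="placebo", ep=4, n=100, events=20, mean=None,
             sd=None, design="parallel", year=2000):
    from migranet import ArmRecord, endpoint, treatment

    return ArmRecord(
        study_id=study,
        year=year,
        design=design,
        blinding="double",
        endpoint=endpoint(ep),
        treatment=treatment(treat),
        n=n,
        events=events if ENDPOINTS[ep if isinstance(ep, int) else ep.code].is_binary else None,
        mean=mean,
        sd=sd,
    )
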