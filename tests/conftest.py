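import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_dataset():
    """One modest planted simulation shared across tests (seed fixed)."""
    from assocnet import SimulationConfig, make_binary_dataset, simulate

    cfg = SimulationConfig(
        n_samples=120, n_molecules=40, n_microbes=25, n_planted_pairs=6,
        n_duplicate_clusters=2, seed=11,
    )
    microbial, molecular, truth = simulate(cfg)
    dataset = make_binary_dataset(microbial, molecular, 0, 0)
    return cfg, microbial, molecular, dataset, truth
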