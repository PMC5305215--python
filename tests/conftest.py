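import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_simulation():
    """A small seeded simulation shared across tests (2 receptors, 400 proteins)."""
    from silac_cargo.synthetic import SimulationConfig, generate

    cfg = SimulationConfig(n_proteins=400, n_receptors=2, seed=7)
    runs, truth, annotations = generate(cfg)
    return cfg, runs, truth, annotations
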