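import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from dynafba.toy import default_config, default_initial_state, make_toy_network  # noqa: E402


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_network()


@pytest.fixture(scope="session")
def benchmark_run(toy_model):
    """The benchmark fermentation: 28 degC, 300 mg N/L, 233 g/L sugars."""
    from dynafba.simulate import simulate

    config = default_config()
    traj = simulate(default_initial_state(), toy_model, config)
    return traj, config


def run_variant(toy_model, **overrides):
    from dynafba.simulate import simulate

    config = default_config(**overrides)
    return simulate(default_initial_state(), toy_model, config), config
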