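import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aeifnet as an

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_params() -> an.NeuronParams:
    """Reference excitatory neuron constants."""
    return an.NeuronParams()


def exc_only_config(**overrides) -> an.NetworkConfig:
    """Excitatory-only network at desk scale (no inhibitory classes)."""
    base = dict(P_exc=1.0, p_i=0.0, p_ei=0.0, p_ie=0.0)
    base.update(overrides)
    return an.desk_config(**base)


def inh_only_config(**overrides) -> an.NetworkConfig:
    base = dict(P_exc=0.0, p_e=0.0, p_ei=0.0, p_ie=0.0)
    base.update(overrides)
    return an.desk_config(**base)


@pytest.fixture(scope="session")
def tiny_coupled_run():
    """A short 5-neuron coupled run shared across tests (compiles the
    kernel once per session)."""
    cfg = exc_only_config(
        N=5, p_e=0.6, p_e_aut=0.4, g_e=0.2, g_e_aut=5.0,
        T_total=1000.0, t_ini=200.0, t_fin=1000.0, seed=7,
    )
    return an.run_simulation(cfg)
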