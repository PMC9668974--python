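import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pulselock.experiments import DEFAULT_STDP, two_neuron_convergence  # noqa: E402


@pytest.fixture(scope="session")
def stdp_default():
    return DEFAULT_STDP


@pytest.fixture(scope="session")
def slow_pacemaker_run():
    """Converged two-neuron run in the slow-pacemaker (mode i) basin."""
    return two_neuron_convergence("slow-pacemaker")


@pytest.fixture(scope="session")
def fast_pacemaker_run():
    """Converged two-neuron run in the fast-pacemaker (mode ii) basin."""
    return two_neuron_convergence("fast-pacemaker")


@pytest.fixture(scope="session")
def decoupling_run():
    """Two-neuron run whose synapses both die (mode iii)."""
    return two_neuron_convergence("decoupled")


@pytest.fixture(scope="session")
def ml_prc_curve():
    """Morris-Lecar PRC on a reduced grid (shared: extraction is costly)."""
    from pulselock.biophys import MlParams, compute_prc

    return compute_prc(MlParams(), n_phases=64, t_max=4000.0)


@pytest.fixture(scope="session")
def wb_prc_curve():
    """Wang-Buzsaki PRC at the 500 ms tuning, reduced grid (shared)."""
    from pulselock.biophys import WbParams, compute_prc

    return compute_prc(WbParams(), n_phases=72)
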