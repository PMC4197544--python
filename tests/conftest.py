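import pytest

from axiswitch import rma
from axiswitch.simulate import SimulationConfig, simulate_probe_intensities


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully structured simulated experiment with its truth."""
    cfg = SimulationConfig(n_probesets=400, probes_per_probeset=4, seed=11)
    pim, truth = simulate_probe_intensities(cfg)
    expr = rma.rma(pim)
    return cfg, pim, truth, expr
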