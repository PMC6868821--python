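import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_refs():
    from circacost import make_reference_waveforms
    tp = np.arange(18.0, 65.0, 2.0)
    return make_reference_waveforms(tp, periods=(24.0,), phase_step=2.0)


@pytest.fixture(scope="session")
def small_dataset():
    """One standard-condition simulated organ, reused across read-only tests."""
    from circacost import SimulationConfig, detect_rhythms, generate_expression
    cfg = SimulationConfig(n_genes=1000, seed=11)
    matrix, truth = generate_expression(cfg)
    rhythms = detect_rhythms(matrix)
    return cfg, matrix, truth, rhythms
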