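import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ephysdecomp import (
    NeuronModel,
    current_step_protocol,
    simulate_neuron,
    voltage_step_protocol,
)
from ephysdecomp.model import apply_pharmacology

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# short synthetic event traces intentionally trip the minimum-duration
# warning in several tests
warnings.filterwarnings(
    "ignore", message="recording shorter than", category=UserWarning
)


@pytest.fixture(scope="session")
def model():
    return NeuronModel()


@pytest.fixture(scope="session")
def step_protocol():
    return current_step_protocol(tail_ms=200.0)


@pytest.fixture(scope="session")
def step_family(model, step_protocol):
    """Noisy current-step family (full -200..400 pA grid)."""
    return simulate_neuron(model, step_protocol, noise_sd=0.2, seed=42)


@pytest.fixture(scope="session")
def step_family_clean(model, step_protocol):
    """Noise-free current-step family with ground truth."""
    return simulate_neuron(model, step_protocol, noise_sd=0.0, seed=42)


@pytest.fixture(scope="session")
def vstep_protocol():
    return voltage_step_protocol()


@pytest.fixture(scope="session")
def kv_families(model, vstep_protocol):
    """Simulated pharmacological K+-current isolation: the TTx family
    (total K+) and the TTx + 4-AP family (DR only), with ground truth."""
    ttx = apply_pharmacology(model, "TTx", 1.0)
    dr_only = apply_pharmacology(ttx, "4AP", 1.0)
    total, total_gt = simulate_neuron(ttx, vstep_protocol, noise_sd=5.0, seed=21)
    dr, dr_gt = simulate_neuron(dr_only, vstep_protocol, noise_sd=5.0, seed=22)
    return {"total": total, "total_gt": total_gt, "dr": dr, "dr_gt": dr_gt}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
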