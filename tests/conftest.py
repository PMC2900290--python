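import numpy as np
import pytest

import threshkit as tk
from threshkit.cli_io import calibrate_threshold_params


@pytest.fixture(scope="session")
def destexhe():
    """Packaged point-conductance model and its synaptic background."""
    return tk.destexhe_2001()


@pytest.fixture(scope="session")
def params(destexhe):
    """Threshold parameters calibrated on the model's Na activation curve."""
    model, _ = destexhe
    return calibrate_threshold_params(model)


@pytest.fixture(scope="session")
def eif_params():
    """EIF parameters matching the point-conductance model's scales."""
    return tk.ThresholdParams(
        V_a=-30.4, k_a=3.7, g_Na=16625.0, g_L=15.6, E_Na=50.0, C=346.0, E_L=-80.0
    )


@pytest.fixture(scope="session")
def fluctuating_trace(destexhe):
    """A 2 s fluctuating-conductance trace with a handful of spikes."""
    model, bg = destexhe
    return tk.simulate_membrane(model, background=bg, duration=2000.0, seed=7)


@pytest.fixture(scope="session")
def spiking_setup(destexhe):
    """High-variability configuration (hyperpolarized inactivation, 3x g_Na,
    doubled synaptic noise) and a 5 s trace with dozens of spikes."""
    model, bg = destexhe
    m, b = tk.apply_modifications(
        model, shift_Vi=-20.0, scale_gNa=3.0, scale_sigma=2.0, background=bg
    )
    trace = tk.simulate_membrane(m, background=b, duration=5000.0, seed=11)
    return m, b, trace
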