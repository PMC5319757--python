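"""Shared fixtures: synthetic recordings and model parameter sets."""

import numpy as np
import pytest

from neuroloop.synthetic_signals import (
    CoupledLFPSpec,
    generate_model_params,
    synthesize_coupled_lfp,
)


@pytest.fixture(scope="session")
def coupled_lfp():
    """Strongly coupled surrogate at 20 dB SNR (the detection target)."""
    return synthesize_coupled_lfp(CoupledLFPSpec(seed=1))


@pytest.fixture(scope="session")
def uncoupled_lfp():
    """Same conditions without any beta-phase to HFO-amplitude coupling."""
    return synthesize_coupled_lfp(CoupledLFPSpec(coupling_strength=0.0, seed=1))


@pytest.fixture(scope="session")
def pd_params():
    return generate_model_params("pd_bursting", seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
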