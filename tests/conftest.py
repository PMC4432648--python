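import numpy as np
import pytest

from digrow import ModelParams


@pytest.fixture
def stripe_params() -> ModelParams:
    """Reference striped-pattern regime: b_X = s_X = s_M = 1, l_X = 2.5."""
    return ModelParams(b_X=1.0, s_X=1.0, s_M=1.0, l_X=2.5, h=16)


@pytest.fixture
def near_threshold_params() -> ModelParams:
    """Regime just above the mixed-state admissibility threshold, where the
    Turing bifurcation sits at h_T close to 8."""
    return ModelParams(b_X=1.0, s_X=1.0, s_M=1.0, l_X=1.0193, h=8, a=1.0)


@pytest.fixture
def general_params() -> ModelParams:
    """A parameter set with every process active (irreducible chain)."""
    return ModelParams(b_X=0.8, b_M=0.3, d_X=0.2, d_M=0.15, s_X=1.1, s_M=0.9,
                       l_X=1.7, h=2)
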