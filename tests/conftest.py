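import numpy as np
import pytest

from aidsim import IVPParameters, MealEvent, RBFNetwork
from aidsim.simulate import SimulationTrace


@pytest.fixture
def nominal_params() -> IVPParameters:
    """Population-mean virtual patient."""
    return IVPParameters()


@pytest.fixture
def network() -> RBFNetwork:
    """Default 11-neuron network with zero weights."""
    return RBFNetwork()


def make_trace(t: np.ndarray, g: np.ndarray, u: np.ndarray | None = None,
               **metadata) -> SimulationTrace:
    """Synthetic trace with the given glucose (and optional insulin) series."""
    n = t.shape[0]
    zeros = np.zeros(n)
    return SimulationTrace(
        t=np.asarray(t, float), G=np.asarray(g, float),
        I_SC=zeros.copy(), I=zeros.copy(), I_EFF=zeros.copy(),
        u=np.asarray(u, float) if u is not None else zeros.copy(),
        d_hat=zeros.copy(), w_norm=zeros.copy(), RA=zeros.copy(),
        meals=[], params=IVPParameters(), metadata=metadata,
    )
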