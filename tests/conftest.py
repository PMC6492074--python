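import numpy as np
import pytest

from cipasim.models import (
    ApTrace,
    CURRENT_IDS,
    DrugExposure,
    HergDynamicParams,
    PacingProtocol,
    run_to_steady_state,
)


@pytest.fixture(scope="session")
def toy_protocol():
    return PacingProtocol(n_beats=3)


@pytest.fixture(scope="session")
def toy_trace(toy_protocol):
    """Drug-free toy beat at paced steady state."""
    return run_to_steady_state("toy", toy_protocol)


@pytest.fixture(scope="session")
def ord_trace():
    """Drug-free myocyte beat continuing from the stored paced steady state."""
    return run_to_steady_state("cipaordv1.0", PacingProtocol(n_beats=2))


@pytest.fixture(scope="session")
def potent_herg_binder():
    """A hERG binder with graded occupancy over 0-10 nM (occupancy ~0.3
    at 1 nM, ~0.5 at 3 nM) and no block of other currents."""
    return HergDynamicParams(kmax=40.0, ku=1e-3, n=1.0, halfmax=100.0,
                             vhalf=-1.0)


@pytest.fixture(scope="session")
def ord_bound_trace(potent_herg_binder):
    """Myocyte beat with substantial drug occupancy of hERG."""
    exposure = DrugExposure(concentration_nM=3.0, herg=potent_herg_binder)
    return run_to_steady_state("cipaordv1.0", PacingProtocol(n_beats=5),
                               exposure)


def make_trace(time_ms, v_mV, currents=None, cai=None, cl=None):
    """Assemble an ApTrace from partial series; absent currents are zero."""
    time_ms = np.asarray(time_ms, dtype=float)
    zeros = np.zeros_like(time_ms)
    cur = {c: zeros.copy() for c in CURRENT_IDS}
    if currents:
        for k, v in currents.items():
            cur[k] = np.asarray(v, dtype=float)
    return ApTrace(
        time_ms=time_ms,
        v_mV=np.asarray(v_mV, dtype=float),
        currents=cur,
        cai_mM=zeros.copy() if cai is None else np.asarray(cai, dtype=float),
        cycle_length_ms=float(time_ms[-1] - time_ms[0]) if cl is None else cl,
    )
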