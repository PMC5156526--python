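import numpy as np
import pytest

from mitodyn import FAST_TRACKING, SLOW_TRACKING, preset
from mitodyn.synthetic import simulate_slow_tracking_dwells, simulate_two_state_tracks


@pytest.fixture(scope="session")
def interphase_tracks():
    """A moderate fast-tracking dataset with the interphase kinetics preset."""
    return simulate_two_state_tracks(preset("interphase"), FAST_TRACKING,
                                     n_particles=20000, seed=101)


@pytest.fixture(scope="session")
def mixture_dwells():
    """Slow-tracking dwell sample from the canonical two-component mixture."""
    return simulate_slow_tracking_dwells(
        f_ns=0.7, k_ns=2.0, k_s=0.08, k_photobleach=0.05,
        acq=SLOW_TRACKING, n_events=5000, seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
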