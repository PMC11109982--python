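import warnings

import numpy as np
import pytest

from condenskit import simulate as sim


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="two-component rates degenerate"
        )
        yield


@pytest.fixture(scope="session")
def two_state_tracks():
    """Two-state trajectory set at acceptance-study conditions (cached)."""
    params = sim.SmtSimParams(
        n_molecules=5000,
        states=((0.01, 0.46), (2.0, 0.54)),
        loc_error_sd=0.03,
        frame_interval=0.02,
        seed=7,
    )
    return sim.simulate_trajectories(params)


@pytest.fixture(scope="session")
def default_stack():
    """Noiseless 20-condensate stack with ground truth (cached)."""
    return sim.simulate_stack(sim.StackSimParams(seed=2))


def ball_mask(radius: int, pad: int = 5) -> np.ndarray:
    n = 2 * radius + 2 * pad + 1
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    c = (n - 1) / 2
    return ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= radius**2
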