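import numpy as np
import pytest

from phtrace import (
    SimulationParams,
    culture_protocol,
    normalize_dff,
    simulate_trace_phenomenological,
    standard_protocol,
    subtract_background,
)


@pytest.fixture(scope="session")
def protocol():
    """Green-reporter in-vivo protocol: 5 fps, 10 s baseline, 10 s stimulus,
    90 s total."""
    return standard_protocol()


@pytest.fixture(scope="session")
def rf_protocol():
    """Cultured-neuron protocol with an NH4Cl phase covering 85-90 s."""
    return culture_protocol()


@pytest.fixture
def clean_params():
    """Noiseless, bleach-free wild-type-like parameters."""
    return SimulationParams(noise_sd_au=0.0, bleach_rate_per_s=0.0, seed=0)


@pytest.fixture
def clean_normalized(protocol, clean_params):
    """Noiseless normalized trace plus its ground truth."""
    raw, truth = simulate_trace_phenomenological(clean_params, protocol)
    return normalize_dff(subtract_background(raw)), truth


def grid_search_tau(t, y, f0, plateau, rising, lo, hi, n_grid=10_000):
    """Independent exhaustive-search oracle for the 1-D tau fit.

    Evaluates the sum of squared residuals of the plateau-constrained
    exponential on a dense log-spaced tau grid and returns (best tau, grid).
    Computed directly from the model formula; shares no code with the
    package optimizer.
    """
    taus = np.geomspace(lo, hi, n_grid)
    tt = np.asarray(t)[:, None] / taus[None, :]
    if rising:
        pred = f0 + (plateau - f0) * (1.0 - np.exp(-tt))
    else:
        pred = (f0 - plateau) * np.exp(-tt) + plateau
    sse = ((np.asarray(y)[:, None] - pred) ** 2).sum(axis=0)
    return taus[int(np.argmin(sse))], taus
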