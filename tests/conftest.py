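import numpy as np
import pytest

from vacudry import (
    DEFAULT_RATE_CONSTANTS,
    GeneratorSpec,
    generate_grid,
    moisture_ratio_series,
)

# study grid temperatures (K) at 40/50/60 degC
TEMPS_K = (313.15, 323.15, 333.15)


@pytest.fixture(scope="session")
def noiseless_grid():
    """The 3x3 condition grid generated without weighing noise."""
    spec = GeneratorSpec(noise_sd_g=0.0)
    curves, manifest = generate_grid(spec)
    return curves, manifest


@pytest.fixture(scope="session")
def mr_grid(noiseless_grid):
    """Noiseless grid with equilibrium-anchored moisture-ratio traces."""
    curves, manifest = noiseless_grid
    return [moisture_ratio_series(c, use_equilibrium=True) for c in curves], manifest


@pytest.fixture(scope="session")
def rate_constants():
    """True drying constants per (temperature_C, pressure_kPa)."""
    return dict(DEFAULT_RATE_CONSTANTS)
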