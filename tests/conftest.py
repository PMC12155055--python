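import numpy as np
import pytest

from torreya_nirs import SpectraMatrix, SyntheticConfig, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """One default granule dataset shared by read-only tests."""
    return simulate(SyntheticConfig(seed=7))


@pytest.fixture()
def tiny_spectra():
    """Five hand-sized spectra over a short axis for operator tests."""
    wl = np.arange(1000.0, 1010.0)
    rng = np.random.default_rng(42)
    base = np.sin(wl / 3.0) + 2.0
    rows = np.array([base * (1 + 0.1 * i) + 0.05 * i + rng.normal(0, 0.01, wl.size)
                     for i in range(5)])
    return SpectraMatrix(wl, rows, np.arange(1, 6))


def quiet_config(**overrides) -> SyntheticConfig:
    """Distortion-free generator config for exactness tests."""
    defaults = dict(
        scatter_slope_sd=0.0,
        scatter_offset_sd=0.0,
        baseline_drift_amplitude=0.0,
        noise_sd=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)
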