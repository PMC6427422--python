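import numpy as np
import pytest

from seednir import SimulationConfig, SpectraSet


@pytest.fixture
def tiny_set():
    """3 samples x 5 wavenumbers, hand-made."""
    return SpectraSet(
        wavenumbers=np.array([4000.0, 4004.0, 4008.0, 4012.0, 4016.0]),
        absorbance=np.array([
            [0.1, 0.2, 0.3, 0.4, 0.5],
            [1.0, 0.9, 0.8, 0.7, 0.6],
            [0.5, 0.1, 0.9, 0.3, 0.7],
        ]),
        sample_ids=np.array(["a", "b", "c"], dtype=object),
        variety=np.array(["V1", "V2", "V3"], dtype=object),
        label=np.array(["viable", "nonviable", "unknown"], dtype=object),
    )


@pytest.fixture
def quiet_config():
    """Simulation config with every dispersion silenced: deterministic
    band structure only (used for exact construction checks)."""
    return SimulationConfig(
        scatter_slope_sd=0.0, scatter_offset_sd=0.0, drift_slope_sd=0.0,
        wander_amplitude=0.0, band_amplitude_sd=0.0,
        noise_sd_base=0.0, noise_sd_tail=0.0,
    )


def rng(seed=0):
    return np.random.default_rng(seed)
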