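import numpy as np
import pytest

from sonoscape import simulate as sim
from sonoscape.audio import Waveform

RATE = 22_050


@pytest.fixture(scope="session")
def pool():
    return sim.build_species_pool(40, seed=11, rate=RATE)


@pytest.fixture(scope="session")
def plots():
    return sim.make_plots(12, seed=11)


@pytest.fixture(scope="session")
def truth(pool, plots):
    return sim.sample_communities(pool, plots, n_visits=10, seed=11)


@pytest.fixture(scope="session")
def rendered(pool, plots, truth):
    """One 30-second mid-gradient recording shared across tests."""
    return sim.render_recording(plots[6], truth.iloc[6], pool,
                                start_time=6 * 3600, duration=30.0,
                                rate=RATE, noise_db=-45.0, seed=11)


@pytest.fixture()
def sine():
    """Full-scale sine at an exact FFT-bin centre (bin 23 of 512 @ 22.05 kHz)."""
    freq = 23 * RATE / 512
    t = np.arange(int(RATE * 5)) / RATE
    return Waveform(np.sin(2 * np.pi * freq * t), RATE), freq


@pytest.fixture()
def white_noise():
    rng = np.random.default_rng(42)
    x = rng.standard_normal(RATE * 10)
    return Waveform(0.5 * x / np.abs(x).max(), RATE)


@pytest.fixture()
def silence():
    return Waveform(np.zeros(RATE * 5), RATE)
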