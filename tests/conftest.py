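import numpy as np
import pytest

from swdscore import Recording, SimulationConfig, simulate


def tone(freq: float, duration_s: float = 10.0, fs: float = 400.0,
         amplitude: float = 1.0, n_channels: int = 1) -> Recording:
    """Pure sinusoid test recording."""
    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t)
    return Recording(np.tile(x, (n_channels, 1)), fs)


@pytest.fixture(scope="session")
def short_recording():
    """~5 min synthetic recording with 3 SWDs and 1 micro-arousal."""
    schedule = [("AW", 50), ("BS", 60), ("SWD", 5), ("BS", 40), ("MA", 8),
                ("BS", 40), ("AW", 45), ("BS", 30), ("SWD", 4), ("BS", 30),
                ("SWD", 3), ("BS", 25)]
    return simulate(SimulationConfig(schedule=schedule, seed=7))


@pytest.fixture(scope="session")
def swd_free_recording():
    """Stationary alternating wake/sleep background, no seizures."""
    schedule = [("AW", 60), ("BS", 90), ("AW", 60), ("BS", 90)]
    return simulate(SimulationConfig(schedule=schedule, seed=11))
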