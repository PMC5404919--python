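import numpy as np
import pytest

from ripplestats import LfpRecording, SynthLfpConfig, generate_lfp


@pytest.fixture
def fs() -> float:
    return 10_000.0


@pytest.fixture
def noise_recording() -> LfpRecording:
    """60 s of event-free 1/f background at 10 kHz."""
    rec, _ = generate_lfp(SynthLfpConfig(duration_s=60.0, swr_rate_hz=0.0, seed=101))
    return rec


def tone(freq_hz: float, duration_s: float = 1.0, fs: float = 10_000.0, amplitude: float = 1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return LfpRecording(amplitude * np.sin(2 * np.pi * freq_hz * t), fs)
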