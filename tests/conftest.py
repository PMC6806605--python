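import numpy as np
import pytest

from tremorkit import GyroRecording, TremorTrace

RATE = 1.0 / 0.015  # 66.67 Hz sampling used throughout


def make_recording(omega, rate=RATE, patient_id="test"):
    n = len(omega)
    return GyroRecording(
        timestamps=np.arange(n) / rate, omega=np.asarray(omega, float),
        patient_id=patient_id,
    )


def tone_trace(freq, duration=8.0, rate=RATE, amp=1.0, phase=0.0):
    t = np.arange(int(duration * rate)) / rate
    return TremorTrace(samples=amp * np.sin(2 * np.pi * freq * t + phase), rate=rate)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone5hz():
    return tone_trace(5.0)
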