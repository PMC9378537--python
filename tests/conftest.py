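"""Shared fixtures and helpers for the syllaqc test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.io import wavfile

from syllaqc import AudioSignal


def make_sine(freq_hz: float = 150.0, amp: float = 0.8, dur_s: float = 1.0,
              rate: int = 16000) -> AudioSignal:
    t = np.arange(int(dur_s * rate)) / rate
    return AudioSignal(samples=amp * np.sin(2 * np.pi * freq_hz * t), rate=rate)


def write_wav(path, signal: AudioSignal) -> None:
    wavfile.write(str(path), signal.rate, (signal.samples * 32767).astype(np.int16))


def dipped_tone(dip_db: float, dur_s: float = 1.0, f0: float = 150.0,
                rate: int = 16000) -> AudioSignal:
    """Continuous voiced tone whose amplitude dips by ``dip_db`` mid-signal,
    producing two intensity peaks separated by a dip of known depth."""
    n = int(dur_s * rate)
    t = np.arange(n) / rate
    x = np.zeros(n)
    for h in range(1, 6):
        x += np.sin(2 * np.pi * h * f0 * t) / h
    x = x / np.max(np.abs(x)) * 0.7
    env = np.ones(n)
    third = n // 3
    depth = 1.0 - 10.0 ** (-dip_db / 20.0)
    env[third : 2 * third] = 1.0 - depth * np.sin(np.linspace(0, np.pi, third))
    ramp = int(0.01 * rate)
    w = np.ones(n)
    w[:ramp] = np.linspace(0, 1, ramp)
    w[-ramp:] = np.linspace(1, 0, ramp)
    sig = np.concatenate([np.zeros(rate // 2), x * env * w, np.zeros(rate // 2)])
    return AudioSignal(samples=sig, rate=rate)


@pytest.fixture
def sine150() -> AudioSignal:
    return make_sine(150.0)


@pytest.fixture
def silence() -> AudioSignal:
    return AudioSignal(samples=np.zeros(32000), rate=16000)
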