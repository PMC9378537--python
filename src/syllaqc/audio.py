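"""Audio ingestion and low-level acoustic features.

This module provides the raw material for syllable-nucleus detection: a
normalized mono waveform (:class:`AudioSignal`), a frame-wise intensity
contour in dB relative to digital full scale, and a pitch/voicedness track
from normalized autocorrelation.

Intensity is referenced to full scale (0 dB = full-scale RMS) rather than
an absolute acoustic pressure, because file amplitudes carry no calibration;
every downstream threshold is relative to the contour maximum, so the
reference cancels out.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile

from .exceptions import EmptyAudioError, ShortSignalError

__all__ = [
    "AudioSignal",
    "IntensityContour",
    "PitchTrack",
    "read_audio",
    "intensity_contour",
    "pitch_track",
    "FLOOR_DB",
    "RMS_FLOOR",
]

#: dB value assigned to frames whose RMS is below the numerical floor.
FLOOR_DB = -200.0
#: RMS below this is treated as digital silence (avoids log of zero).
RMS_FLOOR = 1e-10


@dataclass(frozen=True)
class AudioSignal:
    """A mono sampled waveform.

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence, float64, normalized to [-1, 1].
    rate : int
        Sampling frequency in Hz.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioSignal requires a 1-D sample array")
        if samples.size < 1:
            raise EmptyAudioError("empty audio: zero-length sample stream")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("audio samples must be finite")
        if np.max(np.abs(samples)) > 1.0 + 1e-9:
            raise ValueError("audio samples must lie within [-1, 1]")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Signal duration in seconds (= sample count / rate)."""
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class IntensityContour:
    """Frame-wise signal level in dB re full scale.

    ``times`` are frame centers in seconds (strictly increasing), ``values``
    the per-frame RMS in dB; silent frames carry ``floor_db``.
    """

    times: np.ndarray
    values: np.ndarray
    step: float
    floor_db: float = FLOOR_DB

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        values = np.asarray(self.values, dtype=np.float64)
        if times.shape != values.shape:
            raise ValueError("times and values must have equal length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class PitchTrack:
    """Frame-wise fundamental-frequency estimates with voicing decisions.

    ``f0`` is defined (finite) only on frames where ``voiced`` is True; on
    unvoiced frames it is NaN.
    """

    times: np.ndarray
    f0: np.ndarray
    voiced: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "f0"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        object.__setattr__(self, "voiced", np.asarray(self.voiced, dtype=bool))
        if not (self.times.shape == self.f0.shape == self.voiced.shape):
            raise ValueError("times, f0 and voiced must have equal length")

    def __len__(self) -> int:
        return self.times.size


def read_audio(path: str | Path) -> AudioSignal:
    """Read a PCM WAV file into a normalized mono :class:`AudioSignal`.

    Multichannel audio is downmixed by the channel mean; integer PCM is
    scaled to [-1, 1] by its dtype's full-scale value. The sampling rate is
    preserved (no resampling).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"could not read {path} as PCM WAV: {exc}") from exc
    if data.size == 0:
        raise EmptyAudioError(f"empty audio: {path} holds a zero-length stream")

    data = np.atleast_1d(data)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if info.min < 0:  # signed PCM (16/24/32-bit)
            samples = data.astype(np.float64) / float(-info.min)
        else:  # 8-bit WAV is unsigned, midpoint 128
            mid = (info.max + 1) / 2.0
            samples = (data.astype(np.float64) - mid) / mid
    else:
        samples = np.clip(data.astype(np.float64), -1.0, 1.0)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples=samples, rate=int(rate))


def _frame(signal: AudioSignal, window_s: float, step_s: float) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Slice a signal into overlapping frames.

    Returns (frames matrix, frame-center times in seconds, window length,
    hop length). Raises :class:`ShortSignalError` if the signal is shorter
    than one window.
    """
    if not (window_s >= step_s > 0):
        raise ValueError("require window_s >= step_s > 0")
    win = int(round(window_s * signal.rate))
    hop = int(round(step_s * signal.rate))
    win = max(win, 1)
    hop = max(hop, 1)
    if signal.samples.size < win:
        raise ShortSignalError(
            f"signal of {signal.duration:.4f} s is shorter than one "
            f"{window_s:.4f} s analysis window"
        )
    frames = sliding_window_view(signal.samples, win)[::hop]
    starts = np.arange(frames.shape[0]) * hop
    times = (starts + win / 2.0) / signal.rate
    return frames, times, win, hop


def intensity_contour(
    signal: AudioSignal, window_s: float = 0.064, step_s: float = 0.016
) -> IntensityContour:
    """Frame-wise RMS level in dB re full scale.

    Each frame's RMS is converted as ``20*log10(rms)``; frames whose RMS
    falls below the numerical floor get :data:`FLOOR_DB`.
    """
    frames, times, _, _ = _frame(signal, window_s, step_s)
    rms = np.sqrt(np.mean(frames.astype(np.float64) ** 2, axis=1))
    values = np.full(rms.shape, FLOOR_DB)
    live = rms >= RMS_FLOOR
    values[live] = 20.0 * np.log10(rms[live])
    return IntensityContour(times=times, values=values, step=step_s, floor_db=FLOOR_DB)


def pitch_track(
    signal: AudioSignal,
    floor_hz: float = 75.0,
    ceil_hz: float = 600.0,
    voicing_threshold: float = 0.45,
    window_s: float = 0.04,
    step_s: float = 0.01,
) -> PitchTrack:
    """Normalized-autocorrelation pitch track with voicing decisions.

    A frame is voiced when the length-corrected normalized autocorrelation
    peak inside the candidate lag band [rate/ceil_hz, rate/floor_hz] exceeds
    ``voicing_threshold`` and the frame carries energy above the silence
    floor. On voiced frames f0 is the rate over the (parabolically refined)
    best lag.
    """
    if not (0 < floor_hz < ceil_hz):
        raise ValueError(f"require 0 < floor_hz < ceil_hz, got {floor_hz}, {ceil_hz}")
    if ceil_hz >= signal.rate / 2:
        raise ValueError(f"ceil_hz {ceil_hz} must be below Nyquist {signal.rate / 2}")

    frames, times, win, _ = _frame(signal, window_s, step_s)
    lag_min = max(2, int(np.floor(signal.rate / ceil_hz)))
    lag_max = int(np.ceil(signal.rate / floor_hz))
    if lag_max >= win:
        raise ValueError(
            f"pitch floor {floor_hz} Hz needs lags up to {lag_max} samples "
            f"but the {window_s} s window holds only {win}"
        )

    x = frames - frames.mean(axis=1, keepdims=True)
    nfft = 1 << int(np.ceil(np.log2(2 * win)))
    spec = np.fft.rfft(x, n=nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, :win]
    r0 = ac[:, 0]

    lags = np.arange(lag_min, lag_max + 1)
    # unbiased length correction so a perfect periodic frame scores ~1 at
    # its period regardless of lag
    corr = win / (win - lags).astype(np.float64)
    energy_ok = r0 > win * RMS_FLOOR**2
    safe_r0 = np.where(energy_ok, r0, 1.0)
    r_norm = ac[:, lag_min : lag_max + 1] / safe_r0[:, None] * corr[None, :]

    # a perfectly periodic frame scores ~1 at its period and at every
    # multiple; a small octave cost favors the shortest candidate lag so
    # subharmonics do not halve f0
    octave_cost = 0.01
    score = r_norm - octave_cost * np.log2(lags * floor_hz / signal.rate)[None, :]
    best = np.argmax(score, axis=1)
    best_val = r_norm[np.arange(len(best)), best]
    voiced = energy_ok & (best_val > voicing_threshold)

    f0 = np.full(len(frames), np.nan)
    if voiced.any():
        idx = np.where(voiced)[0]
        lag_best = lags[best[idx]].astype(np.float64)
        # parabolic refinement around the peak where neighbors exist
        for k, fr in zip(range(len(idx)), idx):
            b = best[fr]
            if 0 < b < len(lags) - 1:
                y0, y1, y2 = r_norm[fr, b - 1], r_norm[fr, b], r_norm[fr, b + 1]
                denom = y0 - 2 * y1 + y2
                if denom < 0:
                    lag_best[k] += 0.5 * (y0 - y2) / denom
        f0[idx] = signal.rate / lag_best
    return PitchTrack(times=times, f0=f0, voiced=voiced)
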