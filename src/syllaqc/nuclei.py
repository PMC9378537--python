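"""Syllable-nucleus detection from intensity peaks during voiced speech.

The detector follows the classic intensity/voicedness recipe: find local
maxima of the intensity contour that rise above a speech threshold set
relative to the contour maximum, merge peaks that are not separated by a
sufficient intensity dip, and keep only peaks that coincide with voiced
frames of the pitch track. Each surviving peak counts as one spoken
syllable; the per-recording count is the basis of the missing-syllable
statistic.

Because the speech threshold is relative to the contour maximum and voicing
is amplitude-normalized, the count is invariant to global gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import AudioSignal, intensity_contour, pitch_track

__all__ = [
    "NucleiParams",
    "SyllableEvent",
    "NucleiResult",
    "detect_nuclei",
    "count_spoken_syllables",
    "compare_with_praat_script",
]


@dataclass(frozen=True)
class NucleiParams:
    """Detection parameters.

    silence_offset_db
        dB below the contour maximum defining the speech threshold.
    min_dip_db
        Minimum intensity dip required between two retained peaks.
    window_s, step_s
        Intensity analysis framing.
    pitch_floor_hz, pitch_ceil_hz, voicing_threshold, pitch_window_s, pitch_step_s
        Passed through to the pitch/voicedness tracker.

    The defaults are the canonical values of the widely used Praat
    syllable-nuclei script for conversational speech.
    """

    silence_offset_db: float = 25.0
    min_dip_db: float = 2.0
    window_s: float = 0.064
    step_s: float = 0.016
    pitch_floor_hz: float = 75.0
    pitch_ceil_hz: float = 600.0
    voicing_threshold: float = 0.45
    pitch_window_s: float = 0.04
    pitch_step_s: float = 0.01

    def __post_init__(self) -> None:
        if self.silence_offset_db <= 0:
            raise ValueError("silence_offset_db must be positive")
        if self.min_dip_db <= 0:
            raise ValueError("min_dip_db must be positive")


@dataclass(frozen=True)
class SyllableEvent:
    """One detected nucleus: peak time in seconds and its intensity in dB."""

    time: float
    peak_db: float


@dataclass(frozen=True)
class NucleiResult:
    """Ordered nucleus events, their count c, and the parameters used."""

    events: tuple[SyllableEvent, ...]
    params: NucleiParams

    @property
    def count(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events])


def _candidate_peaks(values: np.ndarray, threshold: float) -> list[int]:
    """Indices of local maxima strictly above ``threshold``.

    Contour endpoints count as peaks when strictly greater than their single
    neighbor.
    """
    n = len(values)
    peaks: list[int] = []
    for i in range(n):
        if values[i] <= threshold:
            continue
        left_ok = i == 0 or values[i] > values[i - 1]
        right_ok = i == n - 1 or values[i] > values[i + 1]
        if n == 1:
            peaks.append(i)
        elif left_ok and right_ok:
            peaks.append(i)
    return peaks


def _merge_by_dip(values: np.ndarray, peaks: list[int], min_dip_db: float) -> list[int]:
    """Discard the lower of two peaks not separated by a deep enough dip.

    Between consecutive retained peaks the contour must dip at least
    ``min_dip_db`` below the lower peak; a stack makes the rule transitive
    when a discarded peak exposes an earlier neighbor.
    """
    retained: list[int] = []
    for j in peaks:
        keep_current = True
        while retained:
            i = retained[-1]
            lower = min(values[i], values[j])
            between = values[i + 1 : j]
            dip = between.min() if between.size else lower
            if lower - dip >= min_dip_db:
                break
            if values[i] <= values[j]:
                retained.pop()  # previous peak is the lower one; recheck j
            else:
                keep_current = False
                break
        if keep_current:
            retained.append(j)
    return retained


def detect_nuclei(signal: AudioSignal, params: NucleiParams | None = None) -> NucleiResult:
    """Detect syllable nuclei in ``signal``.

    Pipeline: intensity contour -> speech threshold at
    ``max - silence_offset_db`` (clamped above the silence floor) ->
    candidate local maxima -> dip-based merging -> voicedness gate (the
    pitch frame nearest each peak must be voiced, ties to the earlier
    frame).

    An all-silence signal yields zero events; a signal shorter than one
    analysis window raises :class:`~syllaqc.exceptions.ShortSignalError`.
    """
    params = params or NucleiParams()
    contour = intensity_contour(signal, params.window_s, params.step_s)
    values = contour.values

    vmax = float(values.max())
    if vmax <= contour.floor_db:  # pure digital silence
        return NucleiResult(events=(), params=params)
    threshold = max(vmax - params.silence_offset_db, contour.floor_db)

    peaks = _candidate_peaks(values, threshold)
    peaks = _merge_by_dip(values, peaks, params.min_dip_db)
    if not peaks:
        return NucleiResult(events=(), params=params)

    track = pitch_track(
        signal,
        floor_hz=params.pitch_floor_hz,
        ceil_hz=params.pitch_ceil_hz,
        voicing_threshold=params.voicing_threshold,
        window_s=params.pitch_window_s,
        step_s=params.pitch_step_s,
    )
    events = []
    for i in peaks:
        t = contour.times[i]
        # argmin returns the first minimizer, i.e. the earlier frame on ties
        nearest = int(np.argmin(np.abs(track.times - t)))
        if track.voiced[nearest]:
            events.append(SyllableEvent(time=float(t), peak_db=float(values[i])))
    return NucleiResult(events=tuple(events), params=params)


def count_spoken_syllables(signal: AudioSignal, params: NucleiParams | None = None) -> int:
    """Spoken-syllable count c: convenience wrapper over :func:`detect_nuclei`."""
    return detect_nuclei(signal, params).count


def compare_with_praat_script(signal: AudioSignal, params: NucleiParams | None = None):
    """Cross-check hook against the original Praat syllable-nuclei script.

    Requires the optional ``praat-parselmouth`` package; the core detector
    has no Praat dependency. Returns (our count, Praat-side count).
    """
    try:
        import parselmouth  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "praat-parselmouth is not installed; the cross-check hook is "
            "optional and the core detector does not require it"
        ) from exc
    raise NotImplementedError(
        "wire this hook to a local copy of the Praat syllable-nuclei script"
    )  # pragma: no cover
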