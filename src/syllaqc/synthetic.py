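"""Synthetic audio and transcript generators with known ground truth.

No clinical recordings ship with the package, so every stage is exercised
on synthetic material whose truth is known by construction:

* :func:`gen_syllable_audio` — a train of k voiced harmonic bursts
  separated by silence (optionally mixed with white noise at a chosen SNR),
  standing in for a recording with exactly k syllable nuclei;
* :func:`gen_transcript_pair` — a reference transcript and a corrupted
  hypothesis with controlled per-word deletion/substitution/insertion
  probabilities, emulating the omission/substitution/intrusion structure of
  ASR errors;
* :func:`gen_qc_dataset` — QC records whose WER follows a known line in the
  proportion of missing syllables plus Gaussian noise, for estimator
  parameter-recovery tests.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentCounts
from .audio import AudioSignal
from .qc import QCRecord
from .textsyll import Transcript, transcript_from_tokens
from .wordlists import LEXICON

__all__ = [
    "BurstSpec",
    "ErrorSpec",
    "gen_syllable_audio",
    "gen_transcript_pair",
    "gen_qc_dataset",
    "gen_error_corpus",
]

# Bursts must be separated by at least two intensity hops of the default
# analysis framing, or neighboring bursts could merge into one peak.
_MIN_GAP_S = 2 * 0.016


@dataclass(frozen=True)
class BurstSpec:
    """Recipe for a burst-train audio signal.

    A burst is a harmonic tone (fundamental ``f0_hz`` with ``n_harmonics``
    partials at 1/h amplitude weights) of ``burst_dur_s`` seconds with
    10 ms raised-cosine on/off ramps, scaled to ``level_dbfs`` RMS. Bursts
    are separated (and the signal book-ended) by ``gap_dur_s`` of silence.
    ``snr_db``, if set, mixes in white Gaussian noise at that SNR relative
    to burst RMS.
    """

    n_bursts: int
    burst_dur_s: float = 0.2
    gap_dur_s: float = 0.3
    f0_hz: float = 150.0
    level_dbfs: float = -6.0
    n_harmonics: int = 5
    snr_db: float | None = None
    seed: int = 0
    rate: int = 16000

    def __post_init__(self) -> None:
        if self.n_bursts < 0:
            raise ValueError("n_bursts must be >= 0")
        if self.burst_dur_s <= 0 or self.gap_dur_s <= 0:
            raise ValueError("burst and gap durations must be positive")
        if self.gap_dur_s < _MIN_GAP_S:
            raise ValueError(
                f"infeasible spec: gap {self.gap_dur_s} s is shorter than "
                f"{_MIN_GAP_S} s; neighboring bursts could merge"
            )


def _burst(spec: BurstSpec) -> np.ndarray:
    n = int(round(spec.burst_dur_s * spec.rate))
    t = np.arange(n) / spec.rate
    x = np.zeros(n)
    for h in range(1, spec.n_harmonics + 1):
        x += np.sin(2 * np.pi * h * spec.f0_hz * t) / h
    target_rms = 10.0 ** (spec.level_dbfs / 20.0)
    x *= target_rms / np.sqrt(np.mean(x**2))
    ramp_n = min(int(round(0.010 * spec.rate)), n // 2)
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        x[:ramp_n] *= ramp
        x[-ramp_n:] *= ramp[::-1]
    return x


def gen_syllable_audio(spec: BurstSpec) -> tuple[AudioSignal, list[float]]:
    """Generate burst-train audio; returns (signal, exact burst-center times).

    With ``n_bursts = 0`` the output is pure silence (or pure noise when
    ``snr_db`` is set). If the assembled waveform would clip, a single
    global gain brings the peak just inside full scale; all detector
    thresholds are relative, so counts are unaffected.
    """
    rate = spec.rate
    gap = np.zeros(int(round(spec.gap_dur_s * rate)))
    burst = _burst(spec) if spec.n_bursts > 0 else np.zeros(0)

    pieces = [gap]
    truth: list[float] = []
    cursor = gap.size
    for _ in range(spec.n_bursts):
        truth.append((cursor + burst.size / 2) / rate)
        pieces.append(burst)
        cursor += burst.size
        pieces.append(gap)
        cursor += gap.size
    x = np.concatenate(pieces)

    if spec.snr_db is not None:
        rng = np.random.default_rng(spec.seed)
        burst_rms = 10.0 ** (spec.level_dbfs / 20.0)
        noise_rms = burst_rms * 10.0 ** (-spec.snr_db / 20.0)
        x = x + rng.standard_normal(x.size) * noise_rms

    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak > 1.0:
        x *= 0.99 / peak
    return AudioSignal(samples=x, rate=rate), truth


@dataclass(frozen=True)
class ErrorSpec:
    """Recipe for a reference/hypothesis transcript pair.

    Each reference word is deleted with probability ``p_del``, replaced by
    a different lexicon word with probability ``p_sub``, otherwise copied;
    after every position (including position 0, i.e. before the first
    word) a random word is inserted with probability ``p_ins`` — so
    insertions can outnumber reference words, reproducing WER > 100%.
    """

    n_words: int
    p_del: float = 0.0
    p_sub: float = 0.0
    p_ins: float = 0.0
    lexicon: tuple[str, ...] = field(default_factory=lambda: tuple(sorted(LEXICON)))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_del", "p_sub", "p_ins"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_del + self.p_sub > 1.0:
            raise ValueError("p_del + p_sub must not exceed 1")
        if not self.lexicon:
            raise ValueError("lexicon must be nonempty")
        if self.n_words < 1:
            raise ValueError("n_words must be >= 1")


def gen_transcript_pair(spec: ErrorSpec) -> tuple[Transcript, Transcript, AlignmentCounts]:
    """Generate (reference, hypothesis, generative truth counts).

    The truth counts record the operations actually applied; the DP
    aligner may find an equally cheap or cheaper alignment, so its distance
    is bounded above by the generative operation count.
    """
    rng = np.random.default_rng(spec.seed)
    lex = np.array(spec.lexicon)
    ref = list(rng.choice(lex, size=spec.n_words))

    hyp: list[str] = []
    dels = subs = ins = hits = 0
    if rng.random() < spec.p_ins:  # insertion point before the first word
        hyp.append(str(rng.choice(lex)))
        ins += 1
    for word in ref:
        u = rng.random()
        if u < spec.p_del:
            dels += 1
        elif u < spec.p_del + spec.p_sub:
            sub = str(rng.choice(lex))
            while sub == word and len(lex) > 1:
                sub = str(rng.choice(lex))
            hyp.append(sub)
            subs += 1
        else:
            hyp.append(str(word))
            hits += 1
        if rng.random() < spec.p_ins:
            hyp.append(str(rng.choice(lex)))
            ins += 1

    truth = AlignmentCounts(n_ref=spec.n_words, hits=hits, subs=subs, dels=dels, ins=ins)
    return transcript_from_tokens(ref), transcript_from_tokens(hyp), truth


def gen_error_corpus(
    n_samples: int = 120,
    mode: str = "omission",
    max_rate: float = 0.6,
    detector_noise_sd: float = 0.03,
    n_words_range: tuple[int, int] = (80, 300),
    seed: int = 0,
) -> list[QCRecord]:
    """A corpus of QC records with a controlled dominant ASR error type.

    Each sample draws an error probability uniform on [0, ``max_rate``] and
    applies it as per-word deletions (``mode="omission"``) or substitutions
    (``mode="substitution"``) — the two corpora therefore have matched mean
    WER by construction. The spoken-syllable count c is the reference
    transcript's syllable total perturbed by multiplicative Gaussian
    detector noise (sd ``detector_noise_sd``), standing in for nucleus
    detection on real audio; b is the hypothesis transcript's written
    syllable total; WER and its components come from the token aligner.

    Omissions remove written syllables, so prop_missing tracks WER; same-
    lexicon substitutions leave the syllable total nearly unchanged, so at
    matched WER the proportion loses its signal — the mechanism behind the
    audio-quality-dependent usefulness of the statistic.
    """
    from .alignment import align, error_rates
    from .qc import proportion_missing
    from .textsyll import count_transcript_syllables

    if mode not in ("omission", "substitution"):
        raise ValueError("mode must be 'omission' or 'substitution'")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_samples):
        p = float(rng.uniform(0.0, max_rate))
        n_words = int(rng.integers(*n_words_range))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = ErrorSpec(
            n_words=n_words,
            p_del=p if mode == "omission" else 0.0,
            p_sub=p if mode == "substitution" else 0.0,
            seed=sub_seed,
        )
        ref, hyp, _ = gen_transcript_pair(spec)
        counts = align(ref, hyp)
        rates = error_rates(counts)
        syll_ref = count_transcript_syllables(ref)
        c = max(1, int(round(syll_ref * (1.0 + detector_noise_sd * rng.standard_normal()))))
        b = count_transcript_syllables(hyp)
        records.append(
            QCRecord(
                sample_id=f"{mode[:3]}{i:04d}",
                duration_s=float(n_words) / 2.5,  # ~150 words/min speech
                spoken_syllables=c,
                written_syllables=b,
                prop_missing=proportion_missing(b, c),
                ref_word_count=counts.n_ref,
                wer_pct=rates.wer_pct,
                del_pct=rates.del_pct,
                sub_pct=rates.sub_pct,
                ins_pct=rates.ins_pct,
            )
        )
    return records


def gen_qc_dataset(
    n_samples: int = 200,
    slope: float = 80.0,
    intercept: float = 10.0,
    noise_sd: float = 5.0,
    prop_range: tuple[float, float] = (0.0, 1.0),
    seed: int = 0,
) -> list[QCRecord]:
    """QC records whose WER% follows a known line in prop_missing.

    prop_missing is uniform on ``prop_range``; wer_pct is
    slope*prop + intercept + N(0, noise_sd), truncated at 0. Spoken and
    written syllable counts are filled consistently with the drawn
    proportion (c = 200, b rounded), and ref_word_count is set safely above
    the short-response exclusion threshold.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    rng = np.random.default_rng(seed)
    lo, hi = prop_range
    props = rng.uniform(lo, hi, size=n_samples)
    wers = np.maximum(slope * props + intercept + rng.normal(0.0, noise_sd, n_samples), 0.0)

    records = []
    c = 200
    for i, (prop, wer) in enumerate(zip(props, wers)):
        b = int(round(c * (1.0 - prop)))
        records.append(
            QCRecord(
                sample_id=f"sim{i:04d}",
                duration_s=30.0,
                spoken_syllables=c,
                written_syllables=b,
                prop_missing=float(prop),
                ref_word_count=100,
                wer_pct=float(wer),
            )
        )
    return records
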