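# Methods

This note documents the models, algorithms, parameter choices and
limitations behind `syllaqc`, in the order data flows through the toolkit.

## Audio features

**Signal model.** Input is mono PCM WAV of a single speaker; multichannel
files are downmixed by the channel mean (clinical recordings are
phase-coherent, so the mean preserves level ordering). Integer PCM is
scaled to [-1, 1] by the dtype's full-scale value; no resampling,
denoising or channel equalization is performed.

**Intensity.** Per-frame RMS converted to dB *re digital full scale*
(`20*log10(rms)`, 0 dB = full-scale RMS), framed with a 64 ms window and
16 ms hop by default. File amplitudes carry no absolute acoustic
calibration, so an SPL reference would be arbitrary; every downstream
threshold is relative to the contour maximum, which makes the reference
choice cancel and the whole pipeline invariant to global gain (a tested
property). Frames with RMS below 1e-10 are pinned to a floor of -200 dB to
avoid log(0).

**Voicedness.** Normalized autocorrelation on 40 ms frames with a 10 ms
hop. For each frame the autocorrelation (computed via FFT, mean removed)
is normalized by lag-0 energy and corrected for window shortening
(`N/(N-lag)`), so a perfectly periodic frame scores ~1 at its period. A
frame is voiced when the peak inside the candidate-lag band — 75–600 Hz by
default, covering conversational speech — exceeds 0.45. A small octave
cost (0.01 per octave of lag) breaks the tie between a period and its
multiples, preventing halved f0; the peak lag is refined parabolically.
White-noise frames score well below the threshold (measured unvoiced
fraction 1.00 over 100 simulated -20 dBFS noise signals), and silent
frames are unvoiced by an energy gate.

## Syllable-nucleus detection

The detector implements the classic intensity/voicedness recipe, with the
canonical parameter values of the widely used Praat syllable-nuclei script
as defaults:

1. intensity contour (64 ms / 16 ms);
2. speech threshold = contour maximum - 25 dB (`silence_offset_db`),
   clamped above the silence floor;
3. candidate peaks = local intensity maxima above the threshold (contour
   endpoints qualify when strictly above their single neighbor);
4. dip rule: between two retained peaks the contour must dip at least 2 dB
   (`min_dip_db`) below the lower of the two, else the lower peak is
   discarded — applied with a stack so that discarding a peak re-exposes
   its predecessor;
5. voicedness gate: a peak survives only if the pitch frame nearest its
   time (ties to the earlier frame) is voiced.

The count of surviving peaks is the spoken-syllable count `c`. All-silence
audio gives `c = 0` (not an error); audio shorter than one analysis window
is an error. Because the threshold is relative and voicing is
amplitude-normalized, the count is gain-invariant, and raising
`min_dip_db` can only merge peaks, never create them (both tested).

The detector is language-agnostic — it sees sonority, not orthography.
Parameters are exposed because appropriate values depend on recording
conditions; on real clinical audio the absolute counts will differ from
any particular published run of nucleus-counting software.

## Written-syllable counting

English transcripts are lowercased, punctuation-stripped (keeping
intra-word apostrophes and hyphens), and whitespace-tokenized. Syllables
per word are counted heuristically: maximal vowel groups (a e i o u y,
with y consonantal word-initially), minus a silent final "e" when it forms
its own group — unless the word ends in consonant+"le" ("table",
"little") — clamped at one syllable per word. Hyphenated words are summed
part by part; apostrophes are dropped before counting. A small shipped
exceptions table (16 entries, e.g. "queue", "science", "idea") overrides
the heuristic so behavior is deterministic and documented. Tokens
containing digits count as one syllable: spoken-form expansion of numerals
is out of scope, and any constant choice preserves comparability of the
proportion across samples.

The heuristic is validated against a frozen 200-word reference list whose
counts come from a standard pronunciation dictionary (vowel phones of the
primary pronunciation); measured agreement is 94.5%, above the 90%
design target. Known systematic misses are compressed pronunciations
("camera", "different", "evening") and vowel-group splits the heuristic
cannot see ("radio", "period"). Word-level errors largely average out in
transcript totals, and the proportion statistic depends only on totals.

## Alignment and WER decomposition

Reference and hypothesis token sequences are aligned by the Wagner–Fischer
dynamic program with unit costs for substitution, deletion and insertion —
the WER standard. The backtrace decomposes the distance into deletions
(omissions), substitutions, and insertions (intrusions); ties are resolved
match > substitution > deletion > insertion, making the reported counts
deterministic. With reference length N:

    WER% = (S + D + I) / N * 100,   del% = D/N*100,  etc.

`wer_pct` is computed as the *sum* of its components, so the decomposition
identity holds to machine precision rather than up to independent
rounding. WER exceeds 100% when insertions are numerous — the case the
exclusion screen removes. Both transcripts pass through the same
tokenizer, so WER and syllable counts see identical tokens. The aligner is
verified against two independent oracles (exhaustive recursion and the
edlib library) on random instances.

## QC statistic, filters and estimator

**Proportion of missing syllables.** `1 - b/c`, computed per sample and
undefined (flagged `no_speech`) when `c = 0`. Note the sign convention:
negative values mean the transcript out-counts the audio, which happens
for complete transcripts of clean speech because the nucleus detector is
conservative.

**Exclusion screen.** A record is excluded with the first matching reason
in a fixed, auditable order: WER > 100 (in percent), proportion < -1,
reference word count < 10 (short responses make the proportion unstable).
All boundaries are strict: WER 100.0, proportion -1.0 and 10 reference
words are kept. Subjective "poor quality" exclusions are deliberately not
automated; `apply_filters` accepts an explicit manual-exclusion id list
instead, which is the auditable equivalent.

**Estimator.** `WerEstimator` (built from filtered records) fits ordinary
least squares of WER% on the proportion; its `fit()` returns an
`EstimatorReport` with slope, intercept, slope standard error, Pearson r
with a two-sided t-test p-value, and out-of-fold r²/RMSE from
seed-shuffled 5-fold cross-validation (scikit-learn folds). The global fit
supplies the line; the folds measure predictive skill, and out-of-fold r²
may legitimately be negative. Predictions are clamped below at 0 (a
negative WER estimate is meaningless). Regression direction is WER as
response: the use case is estimating WER where no reference exists. The
estimator requires a labeled subset to calibrate — it does not estimate
WER from audio alone.

## Synthetic data: what it emulates and what it does not

No clinical recordings ship with the package; generators provide inputs
with exact ground truth.

* **Burst audio** (`gen_syllable_audio`): k harmonic bursts (f0 150 Hz, 5
  partials at 1/h weights — harmonic rather than pure tones so the
  voicedness detector sees realistic periodicity) of 200 ms at -6 dBFS
  RMS, with 10 ms raised-cosine ramps, separated by 300 ms silence,
  optionally mixed with white noise at a chosen SNR. Burst/gap durations
  sit in the natural syllable/pause range and guarantee separability under
  the default framing (gaps must exceed two intensity hops). If the
  waveform would clip, one global gain rescales it — counts are unaffected
  since the pipeline is gain-invariant.
* **Transcript pairs** (`gen_transcript_pair`): per-word deletion /
  substitution / copy, plus insertions at every gap including before the
  first word, so insertions can exceed the reference length and WER > 100%
  is reachable. Words are drawn from a 100-word lexicon with known
  syllable counts. The generative operation counts are recorded as truth;
  the aligner may legitimately find a cheaper path, so tests assert
  distance ≤ generated operations.
* **QC datasets** (`gen_qc_dataset`): proportions uniform on [0, 1],
  WER = 80·prop + 10 + N(0, 5) truncated at 0 by default — slope,
  intercept and noise chosen so simulated WERs span the realistic 10–90%
  range with scatter comparable to reported cross-validation RMSE.
* **Error-dominated corpora** (`gen_error_corpus`): per-sample error rate
  uniform on [0, 0.6] applied as deletions or as substitutions (matched
  mean WER by construction); the spoken count c is the reference's
  syllable total with 3% multiplicative Gaussian detector noise. This
  reproduces the mechanism of interest: omission-dominated corpora show
  corr(prop, WER) ≈ 0.99, substitution-dominated corpora ≈ 0.

What the generators do *not* emulate: coarticulation and syllable-level
intensity variation, telephone-channel filtering, reverberation,
multi-speaker audio, disfluencies, and real ASR error correlations.
Passing tests therefore demonstrate correctness of the algorithms and the
qualitative error-type mechanism, not field performance on clinical audio;
absolute detector accuracy on real recordings depends on conditions and
parameters.

## Numerical choices and problem sizes

* Intensity floor -200 dB at RMS < 1e-10; speech threshold clamped at the
  floor.
* Plateaus in the intensity contour produce no peak (strict local maxima);
  irrelevant above threshold in practice.
* Voicing threshold 0.45, octave cost 0.01, parabolic lag refinement;
  pitch bounds must satisfy 0 < floor < ceiling < Nyquist.
* Degenerate inputs raise typed errors rather than returning sentinel
  values: empty audio, signal shorter than a window, c = 0, empty
  reference, zero-variance predictor or correlation input.
* Test and acceptance problem sizes: 20 burst counts × 50 seeds clean,
  200 noisy simulations at 10 dB SNR, 200 random alignment instances,
  200-record estimator datasets, 120-sample corpora per error mode —
  large enough for the binomial/regression tolerances used, and the full
  suite runs in about a minute.

## Known limitations

* The written-syllable counter is English-only; the nucleus counter is not.
* Sample-level agreement between `c` and true syllables on real speech is
  approximate; the method's value is in the *proportion*'s correlation
  with WER under omission-dominated errors, which vanishes by design when
  errors are substitution-dominated (high-quality audio).
* The WER estimator transfers only to samples from conditions similar to
  its calibration set.
* Audio-quality scoring (predicting when the method is applicable) is out
  of scope.
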