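"""QC statistic, exclusion filters, correlation, estimator, and pipeline
orchestration tests."""

from __future__ import annotations

import numpy as np
import pytest

from syllaqc import (
    DegenerateInputError,
    NoSpeechError,
    QCRecord,
    WerEstimator,
    apply_filters,
    fit_wer_estimator,
    pearson,
    predict_wer,
    proportion_missing,
    qc_report,
)
from syllaqc.qc import records_from_frame
from syllaqc.synthetic import BurstSpec, ErrorSpec, gen_error_corpus, gen_qc_dataset, gen_syllable_audio, gen_transcript_pair


def record(sample_id="s", prop=0.3, wer=50.0, ref_words=100, **kw) -> QCRecord:
    return QCRecord(
        sample_id=sample_id,
        duration_s=30.0,
        spoken_syllables=100,
        written_syllables=70,
        prop_missing=prop,
        ref_word_count=ref_words,
        wer_pct=wer,
        **kw,
    )


class TestProportionMissing:
    @pytest.mark.parametrize(
        "b, c, expected",
        [(50, 100, 0.5), (80, 80, 0.0), (80, 76, 1 - 80 / 76), (0, 10, 1.0)],
    )
    def test_values(self, b, c, expected):
        assert proportion_missing(b, c) == pytest.approx(expected)

    def test_negative_when_transcript_longer(self):
        # more written syllables than detected nuclei -> negative, as for
        # clean complete recordings
        assert proportion_missing(80, 76) < 0

    def test_no_speech_error(self):
        with pytest.raises(NoSpeechError):
            proportion_missing(10, 0)


class TestFilters:
    def test_wer_boundary_strict(self):
        kept, _ = apply_filters([record(wer=100.0)])
        assert len(kept) == 1
        _, excluded = apply_filters([record(wer=100.01)])
        assert excluded[0][1] == "wer>100"

    def test_prop_boundary_strict(self):
        kept, _ = apply_filters([record(prop=-1.0)])
        assert len(kept) == 1
        _, excluded = apply_filters([record(prop=-1.01)])
        assert excluded[0][1] == "prop<-1"

    def test_ref_words_boundary_strict(self):
        kept, _ = apply_filters([record(ref_words=10)])
        assert len(kept) == 1
        _, excluded = apply_filters([record(ref_words=9)])
        assert excluded[0][1] == "ref_words<10"

    def test_first_matching_reason_wins(self):
        # violates every rule; the WER rule is checked first
        _, excluded = apply_filters([record(wer=150.0, prop=-2.0, ref_words=3)])
        assert excluded[0][1] == "wer>100"

    def test_missing_fields_are_exempt(self):
        rec = QCRecord(
            sample_id="x",
            duration_s=5.0,
            spoken_syllables=50,
            written_syllables=40,
            prop_missing=0.2,
        )  # no wer, no ref count
        kept, _ = apply_filters([rec])
        assert kept == [rec]

    def test_manual_exclusion_list(self):
        _, excluded = apply_filters([record(sample_id="bad")], manual_exclusions=["bad"])
        assert excluded[0][1] == "manual"

    def test_conservation_and_single_reason(self):
        records = gen_qc_dataset(n_samples=100, seed=5) + [
            record(wer=120.0), record(prop=-1.5), record(ref_words=2)
        ]
        kept, excluded = apply_filters(records)
        assert len(kept) + len(excluded) == len(records)
        assert all(isinstance(reason, str) and reason for _, reason in excluded)


class TestPearson:
    def test_perfect_positive_line(self):
        x = [1.0, 2.0, 5.0, 9.0]
        r, p = pearson(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 3.0]
        r, _ = pearson(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        # sum(dx*dy)/sqrt(sum dx^2 * sum dy^2) = 3/5
        r, p = pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        assert 0 < p < 1

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestWerEstimator:
    def test_noiseless_line_recovered_exactly(self):
        records = gen_qc_dataset(n_samples=50, slope=80, intercept=10, noise_sd=0, seed=3)
        report = fit_wer_estimator(records, folds=5, seed=0)
        assert report.slope == pytest.approx(80.0, abs=1e-9)
        assert report.intercept == pytest.approx(10.0, abs=1e-9)
        assert all(r2 == pytest.approx(1.0) for r2 in report.r2_folds)
        assert all(rmse == pytest.approx(0.0, abs=1e-9) for rmse in report.rmse_folds)

    def test_parameter_recovery_within_2se(self):
        records = gen_qc_dataset(n_samples=200, slope=80, intercept=10, noise_sd=5, seed=1)
        report = fit_wer_estimator(records, folds=5, seed=1)
        assert abs(report.slope - 80.0) <= 2 * report.slope_stderr

    def test_constant_predictor_raises(self):
        records = [record(sample_id=f"s{i}", prop=0.4, wer=30.0 + i) for i in range(10)]
        with pytest.raises(DegenerateInputError):
            fit_wer_estimator(records)

    def test_too_few_records_raises(self):
        with pytest.raises(ValueError):
            fit_wer_estimator([record(sample_id=f"s{i}", prop=0.1 * i) for i in range(3)])

    def test_filtering_feeds_the_fit(self):
        good = gen_qc_dataset(n_samples=50, seed=2)
        noisy = [record(sample_id="w", wer=150.0), record(sample_id="p", prop=-3.0)]
        report = fit_wer_estimator(good + noisy, folds=5, seed=0)
        assert report.n_used == 50
        assert report.n_excluded == 2

    def test_model_results_roundtrip_json(self, tmp_path):
        records = gen_qc_dataset(n_samples=60, seed=4)
        report = WerEstimator.from_records(records).fit(folds=5, seed=7)
        path = tmp_path / "model.json"
        report.to_json(path)
        from syllaqc import EstimatorReport

        loaded = EstimatorReport.from_json(path)
        assert loaded == report

    def test_summary_mentions_key_quantities(self):
        report = fit_wer_estimator(gen_qc_dataset(n_samples=60, seed=4))
        text = report.summary()
        for needle in ("slope", "intercept", "pearson r", "CV"):
            assert needle in text


class TestPredict:
    def test_line_and_clamp(self):
        records = gen_qc_dataset(n_samples=50, slope=80, intercept=10, noise_sd=0, seed=3)
        report = fit_wer_estimator(records)
        assert predict_wer(report, 0.0) == pytest.approx(10.0)
        assert predict_wer(report, 0.5) == pytest.approx(50.0)
        assert predict_wer(report, -0.2) == 0.0  # clamped from -6


class TestQCReport:
    def test_complete_transcript_round_trip(self):
        sig, _ = gen_syllable_audio(BurstSpec(n_bursts=10))
        words = "the cat sat on the mat with one big dog"  # 10 monosyllables
        rec = qc_report(sig, words, words, sample_id="clean")
        assert rec.spoken_syllables == 10
        assert rec.written_syllables == 10
        assert rec.prop_missing == pytest.approx(0.0)
        assert rec.wer_pct == 0.0
        assert rec.flag is None or not rec.flag.startswith("excluded")

    def test_half_missing_transcript(self):
        sig, _ = gen_syllable_audio(BurstSpec(n_bursts=10))
        ref = "the cat sat on the mat with one big dog"
        asr = "the cat sat on the"  # 5 of 10 words
        rec = qc_report(sig, asr, ref, sample_id="half")
        assert rec.prop_missing == pytest.approx(0.5)
        assert rec.del_pct == pytest.approx(50.0)

    def test_silence_flags_no_speech(self, silence):
        rec = qc_report(silence, "some words here")
        assert rec.flag == "no_speech"
        assert rec.prop_missing is None

    def test_exclusion_flag_attached(self):
        sig, _ = gen_syllable_audio(BurstSpec(n_bursts=10))
        rec = qc_report(sig, "the cat", "the cat", sample_id="short")
        assert rec.flag == "excluded:ref_words<10"

    def test_hyp_deletions_monotone_in_prop_and_del(self):
        sig, _ = gen_syllable_audio(BurstSpec(n_bursts=10))
        ref = "the cat sat on the mat with one big dog"
        words = ref.split()
        last_prop, last_del = -np.inf, -np.inf
        for n_kept in range(10, 4, -1):
            rec = qc_report(sig, " ".join(words[:n_kept]), ref)
            assert rec.prop_missing >= last_prop
            assert rec.del_pct >= last_del
            last_prop, last_del = rec.prop_missing, rec.del_pct


class TestCorrelationStructure:
    def test_omission_dominated_corr_exceeds_substitution_dominated(self):
        om = gen_error_corpus(n_samples=100, mode="omission", seed=11)
        sub = gen_error_corpus(n_samples=100, mode="substitution", seed=11)
        r_om, _ = pearson([r.prop_missing for r in om], [r.wer_pct for r in om])
        r_sub, _ = pearson([r.prop_missing for r in sub], [r.wer_pct for r in sub])
        assert r_om > 0.9
        assert r_sub < r_om

    def test_prop_tracks_omissions_more_than_substitutions(self):
        # mixed corpus with independently varying deletion and substitution
        # rates: the proportion statistic should track omissions specifically
        from syllaqc import align, error_rates
        from syllaqc.textsyll import count_transcript_syllables

        rng = np.random.default_rng(21)
        props, dels, subs = [], [], []
        for i in range(80):
            spec = ErrorSpec(
                n_words=int(rng.integers(80, 200)),
                p_del=float(rng.uniform(0, 0.4)),
                p_sub=float(rng.uniform(0, 0.4)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            ref, hyp, _ = gen_transcript_pair(spec)
            rates = error_rates(align(ref, hyp))
            c = count_transcript_syllables(ref)
            b = count_transcript_syllables(hyp)
            props.append(proportion_missing(b, c))
            dels.append(rates.del_pct)
            subs.append(rates.sub_pct)
        r_del, _ = pearson(props, dels)
        r_sub, _ = pearson(props, subs)
        assert r_del > r_sub


class TestRecordsFromFrame:
    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        records = gen_qc_dataset(n_samples=20, seed=9)
        df = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in records],
                "prop_missing": [r.prop_missing for r in records],
                "wer_pct": [r.wer_pct for r in records],
                "ref_word_count": [r.ref_word_count for r in records],
            }
        )
        path = tmp_path / "records.csv"
        df.to_csv(path, index=False)
        rebuilt = records_from_frame(pd.read_csv(path))
        assert [r.prop_missing for r in rebuilt] == pytest.approx(
            [r.prop_missing for r in records]
        )
        assert [r.wer_pct for r in rebuilt] == pytest.approx([r.wer_pct for r in records])
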