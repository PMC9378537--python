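"""Transcript-completeness QC: the missing-syllable statistic and the
cross-validated linear WER estimator.

The core quantity is the proportion of missing syllables

    prop_missing = 1 - b / c

where b is the written-syllable count of the ASR transcript and c the
spoken-syllable count detected in the audio. It is near 0 for a complete
transcript, approaches 1 when most speech is missing, and goes negative
when the transcript holds more written syllables than detected nuclei
(common for clean, complete recordings where the nucleus detector slightly
undercounts).

When reference transcripts exist for a labeled subset, an ordinary
least-squares line of WER% on prop_missing — validated by seed-shuffled
five-fold cross-validation (out-of-fold r² and RMSE) — turns the proportion
into a WER estimate for unlabeled recordings. Records are screened first by
the standard exclusion rules: WER over 100%, proportion under -1, or fewer
than 10 reference words (very short responses make the proportion unstable).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import align, error_rates
from .audio import AudioSignal
from .exceptions import DegenerateInputError, NoSpeechError
from .nuclei import NucleiParams, count_spoken_syllables
from .textsyll import Transcript, count_transcript_syllables, tokenize

__all__ = [
    "QCRecord",
    "FilterConfig",
    "EstimatorReport",
    "WerEstimator",
    "proportion_missing",
    "apply_filters",
    "pearson",
    "fit_wer_estimator",
    "predict_wer",
    "qc_report",
    "batch_qc",
    "records_from_frame",
]


def proportion_missing(written: int, spoken: int) -> float:
    """Proportion of missing syllables 1 - b/c.

    Requires at least one detected spoken syllable (c >= 1); with c == 0
    the statistic is undefined and the record should be flagged instead.
    """
    if spoken < 1:
        raise NoSpeechError("no detected speech: proportion undefined at c = 0")
    if written < 0:
        raise ValueError("written-syllable count must be non-negative")
    return 1.0 - written / spoken


@dataclass(frozen=True)
class QCRecord:
    """One recording's QC measurements.

    Fields without a reference transcript (wer and component rates,
    ref_word_count) are None. ``flag`` carries a data-quality note such as
    "no_speech" when the proportion could not be formed.
    """

    sample_id: str
    duration_s: float
    spoken_syllables: int
    written_syllables: int
    prop_missing: float | None
    ref_word_count: int | None = None
    wer_pct: float | None = None
    del_pct: float | None = None
    sub_pct: float | None = None
    ins_pct: float | None = None
    flag: str | None = None

    def __post_init__(self) -> None:
        if self.prop_missing is not None and self.prop_missing > 1.0 + 1e-12:
            raise ValueError("prop_missing cannot exceed 1")


@dataclass(frozen=True)
class FilterConfig:
    """Exclusion thresholds for QC records (all strict inequalities).

    Defaults follow the standard screen: WER over 100%, proportion of
    missing syllables under -1, reference word count under 10. Subjective
    poor-quality exclusions are not automated; pass explicit sample ids via
    ``manual_exclusions`` of :func:`apply_filters`.
    """

    max_wer_pct: float = 100.0
    min_prop_missing: float = -1.0
    min_ref_words: int = 10

    def __post_init__(self) -> None:
        if self.max_wer_pct <= 0:
            raise ValueError("max_wer_pct must be positive")
        if self.min_ref_words < 0:
            raise ValueError("min_ref_words must be non-negative")


def exclusion_reason(
    record: QCRecord, cfg: FilterConfig, manual_exclusions: Iterable[str] = ()
) -> str | None:
    """First matching exclusion reason in fixed order, or None if kept.

    Order: manual list, WER rule, proportion rule, reference-length rule.
    Records lacking a field are exempt from that field's rule.
    """
    if record.sample_id in set(manual_exclusions):
        return "manual"
    if record.wer_pct is not None and record.wer_pct > cfg.max_wer_pct:
        return f"wer>{cfg.max_wer_pct:g}"
    if record.prop_missing is not None and record.prop_missing < cfg.min_prop_missing:
        return f"prop<{cfg.min_prop_missing:g}"
    if record.ref_word_count is not None and record.ref_word_count < cfg.min_ref_words:
        return f"ref_words<{cfg.min_ref_words:g}"
    return None


def apply_filters(
    records: Sequence[QCRecord],
    cfg: FilterConfig | None = None,
    manual_exclusions: Iterable[str] = (),
) -> tuple[list[QCRecord], list[tuple[QCRecord, str]]]:
    """Partition records into (kept, excluded-with-reason).

    Each excluded record carries exactly one reason (the first matching
    rule); kept + excluded counts always equal the input count.
    """
    cfg = cfg or FilterConfig()
    manual = set(manual_exclusions)
    kept: list[QCRecord] = []
    excluded: list[tuple[QCRecord, str]] = []
    for rec in records:
        reason = exclusion_reason(rec, cfg, manual)
        if reason is None:
            kept.append(rec)
        else:
            excluded.append((rec, reason))
    return kept, excluded


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p from the t distribution
    (n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("pearson requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("degenerate input: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class EstimatorReport:
    """Fitted WER-from-proportion line with cross-validated skill.

    slope/intercept come from the global OLS fit of wer_pct on
    prop_missing; r2_folds and rmse_folds are out-of-fold scores from
    seed-shuffled k-fold cross-validation (out-of-fold r² may be negative
    when the line predicts worse than the fold mean).
    """

    slope: float
    intercept: float
    slope_stderr: float
    pearson_r: float
    p_value: float
    r2_folds: tuple[float, ...]
    rmse_folds: tuple[float, ...]
    n_used: int
    n_excluded: int
    folds: int
    seed: int

    def predict(self, prop: float | np.ndarray) -> float | np.ndarray:
        """Estimated WER% at a given proportion, clamped below at 0."""
        out = np.maximum(self.slope * np.asarray(prop, dtype=float) + self.intercept, 0.0)
        return float(out) if out.ndim == 0 else out

    @property
    def r2_range(self) -> tuple[float, float]:
        return (min(self.r2_folds), max(self.r2_folds))

    @property
    def rmse_range(self) -> tuple[float, float]:
        return (min(self.rmse_folds), max(self.rmse_folds))

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = [
            "WER estimator: wer_pct ~ prop_missing (OLS)",
            "=" * 46,
            f"records used        {self.n_used:>10d}",
            f"records excluded    {self.n_excluded:>10d}",
            f"slope               {self.slope:>10.3f}  (se {self.slope_stderr:.3f})",
            f"intercept           {self.intercept:>10.3f}",
            f"pearson r           {self.pearson_r:>10.3f}  (p = {self.p_value:.3g})",
            f"{self.folds}-fold CV r2        "
            f"{self.r2_range[0]:>10.2f} .. {self.r2_range[1]:.2f}",
            f"{self.folds}-fold CV RMSE      "
            f"{self.rmse_range[0]:>10.2f} .. {self.rmse_range[1]:.2f}  (WER pts)",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_stderr": self.slope_stderr,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "r2_folds": list(self.r2_folds),
            "rmse_folds": list(self.rmse_folds),
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "folds": self.folds,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EstimatorReport":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        d = json.loads(text)
        d["r2_folds"] = tuple(d["r2_folds"])
        d["rmse_folds"] = tuple(d["rmse_folds"])
        return cls(**d)


class WerEstimator:
    """Linear model of WER% as a function of the proportion of missing
    syllables, built from filtered QC records.

    Use :meth:`from_records` to construct from QC records (applying the
    exclusion rules), then :meth:`fit` to obtain an
    :class:`EstimatorReport`.
    """

    def __init__(self, prop: np.ndarray, wer: np.ndarray, n_excluded: int = 0):
        prop = np.asarray(prop, dtype=float)
        wer = np.asarray(wer, dtype=float)
        if prop.shape != wer.shape or prop.ndim != 1:
            raise ValueError("prop and wer must be 1-D and of equal length")
        self.prop = prop
        self.wer = wer
        self.n_excluded = int(n_excluded)

    @classmethod
    def from_records(
        cls,
        records: Sequence[QCRecord],
        cfg: FilterConfig | None = None,
        manual_exclusions: Iterable[str] = (),
    ) -> "WerEstimator":
        """Build the model from QC records after the exclusion screen.

        Only kept records carrying both prop_missing and wer_pct enter the
        design; records missing either field count as excluded for
        reporting purposes.
        """
        kept, excluded = apply_filters(records, cfg, manual_exclusions)
        usable = [r for r in kept if r.prop_missing is not None and r.wer_pct is not None]
        n_excluded = len(records) - len(usable)
        prop = np.array([r.prop_missing for r in usable])
        wer = np.array([r.wer_pct for r in usable])
        return cls(prop, wer, n_excluded=n_excluded)

    def fit(self, folds: int = 5, seed: int = 0) -> EstimatorReport:
        """OLS fit plus seed-shuffled k-fold cross-validation.

        The reported slope/intercept/correlation come from the fit on all
        records; the per-fold out-of-fold r² and RMSE measure predictive
        skill.
        """
        n = self.prop.size
        if n < folds:
            raise ValueError(f"need at least {folds} usable records, have {n}")
        if np.ptp(self.prop) == 0:
            raise DegenerateInputError("degenerate fit: predictor has zero variance")

        ols = stats.linregress(self.prop, self.wer)
        r, p = pearson(self.prop, self.wer)

        from sklearn.linear_model import LinearRegression
        from sklearn.model_selection import KFold

        X = self.prop[:, None]
        r2s: list[float] = []
        rmses: list[float] = []
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        for train, test in kf.split(X):
            lm = LinearRegression().fit(X[train], self.wer[train])
            pred = lm.predict(X[test])
            resid = self.wer[test] - pred
            ss_res = float(np.sum(resid**2))
            ss_tot = float(np.sum((self.wer[test] - self.wer[test].mean()) ** 2))
            if ss_tot == 0.0:
                r2s.append(1.0 if ss_res == 0.0 else -math.inf)
            else:
                r2s.append(1.0 - ss_res / ss_tot)
            rmses.append(float(np.sqrt(np.mean(resid**2))))

        return EstimatorReport(
            slope=float(ols.slope),
            intercept=float(ols.intercept),
            slope_stderr=float(ols.stderr),
            pearson_r=r,
            p_value=p,
            r2_folds=tuple(r2s),
            rmse_folds=tuple(rmses),
            n_used=n,
            n_excluded=self.n_excluded,
            folds=folds,
            seed=seed,
        )


def fit_wer_estimator(
    records: Sequence[QCRecord],
    cfg: FilterConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    manual_exclusions: Iterable[str] = (),
) -> EstimatorReport:
    """Filter records, fit the WER line, cross-validate; functional wrapper
    around :class:`WerEstimator`."""
    model = WerEstimator.from_records(records, cfg, manual_exclusions)
    return model.fit(folds=folds, seed=seed)


def predict_wer(report: EstimatorReport, prop: float) -> float:
    """Estimated WER% at ``prop`` (slope*prop + intercept, clamped at 0)."""
    return float(report.predict(prop))


def qc_report(
    audio: AudioSignal,
    asr_text: Transcript | str,
    ref_text: Transcript | str | None = None,
    params: NucleiParams | None = None,
    cfg: FilterConfig | None = None,
    sample_id: str = "sample",
) -> QCRecord:
    """Run the full QC pipeline on one recording.

    Counts spoken syllables in the audio and written syllables in the ASR
    transcript, forms the proportion of missing syllables, and — when a
    reference transcript is supplied — aligns the transcripts and attaches
    WER and its decomposition. The record's ``flag`` notes "no_speech"
    (proportion undefined) or the exclusion rule it trips.
    """
    cfg = cfg or FilterConfig()
    asr = tokenize(asr_text) if isinstance(asr_text, str) else asr_text
    try:
        c = count_spoken_syllables(audio, params)
    except Exception as exc:
        raise type(exc)(f"[{sample_id}] {exc}") from exc
    b = count_transcript_syllables(asr)

    prop = proportion_missing(b, c) if c >= 1 else None
    flag = None if c >= 1 else "no_speech"

    wer = dp = sp = ip = None
    n_ref = None
    if ref_text is not None:
        ref = tokenize(ref_text) if isinstance(ref_text, str) else ref_text
        counts = align(ref, asr)
        rates = error_rates(counts)
        wer, dp, sp, ip = rates.wer_pct, rates.del_pct, rates.sub_pct, rates.ins_pct
        n_ref = counts.n_ref

    record = QCRecord(
        sample_id=sample_id,
        duration_s=audio.duration,
        spoken_syllables=c,
        written_syllables=b,
        prop_missing=prop,
        ref_word_count=n_ref,
        wer_pct=wer,
        del_pct=dp,
        sub_pct=sp,
        ins_pct=ip,
        flag=flag,
    )
    if flag is None:
        reason = exclusion_reason(record, cfg)
        if reason is not None:
            record = replace(record, flag=f"excluded:{reason}")
    return record


def records_from_frame(df: pd.DataFrame) -> list[QCRecord]:
    """Rebuild QCRecords from a batch-QC style DataFrame/CSV.

    Requires prop_missing and wer_pct columns (the estimator's inputs);
    other columns are optional and default sensibly.
    """

    def _get(row, name, default=None):
        v = row.get(name, default)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return default
        return v

    records = []
    for i, row in enumerate(df.to_dict(orient="records")):
        wer = _get(row, "wer_pct")
        ref_n = _get(row, "ref_word_count")
        records.append(
            QCRecord(
                sample_id=str(_get(row, "sample_id", f"row{i}")),
                duration_s=float(_get(row, "duration_s", 0.0)),
                spoken_syllables=int(_get(row, "spoken_syllables", 0)),
                written_syllables=int(_get(row, "written_syllables", 0)),
                prop_missing=(lambda v: None if v is None else float(v))(_get(row, "prop_missing")),
                ref_word_count=None if ref_n is None else int(ref_n),
                wer_pct=None if wer is None else float(wer),
                flag=_get(row, "flag"),
            )
        )
    return records


def batch_qc(
    table: pd.DataFrame | str | Path,
    params: NucleiParams | None = None,
    cfg: FilterConfig | None = None,
) -> pd.DataFrame:
    """Run :func:`qc_report` over a batch table.

    ``table`` is a DataFrame or CSV path with columns sample_id,
    audio_path, asr_path and optional ref_path. Returns one row per record
    with counts, proportion, error rates and the kept/excluded flag.
    """
    from .audio import read_audio

    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    required = {"sample_id", "audio_path", "asr_path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"batch table lacks columns: {sorted(missing)}")

    rows = []
    for rec in table.itertuples(index=False):
        audio = read_audio(rec.audio_path)
        asr = Path(rec.asr_path).read_text(encoding="utf-8")
        ref = None
        ref_path = getattr(rec, "ref_path", None)
        if isinstance(ref_path, str) and ref_path:
            ref = Path(ref_path).read_text(encoding="utf-8")
        out = qc_report(audio, asr, ref, params=params, cfg=cfg, sample_id=str(rec.sample_id))
        rows.append(
            {
                "sample_id": out.sample_id,
                "duration_s": out.duration_s,
                "spoken_syllables": out.spoken_syllables,
                "written_syllables": out.written_syllables,
                "prop_missing": out.prop_missing,
                "ref_word_count": out.ref_word_count,
                "wer_pct": out.wer_pct,
                "del_pct": out.del_pct,
                "sub_pct": out.sub_pct,
                "ins_pct": out.ins_pct,
                "flag": out.flag,
            }
        )
    return pd.DataFrame(rows)
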