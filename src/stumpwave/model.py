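"""Model/Results objects tying the pipeline together.

:class:`PulseWaveAnalysis` is the single-recording model: construct it from
a :class:`~stumpwave.io.PressureTrace` (or a CSV export), call
:meth:`~PulseWaveAnalysis.fit`, and read the morphometric panel off the
returned :class:`PulseWaveResults`. :class:`CohortAnalysis` is the cohort
model: construct it from records or a flat DataFrame and ``fit()`` runs the
statistical battery.

Example
-------
>>> from stumpwave import simulate, PulseWaveAnalysis
>>> params = simulate.BeatModelParams(noise_sd=0, drift_amplitude=0,
...                                   artifact_rate=0, tau=1.5)
>>> trace, truth = simulate.generate_trace(params, duration=60)
>>> model = PulseWaveAnalysis(
...     trace, tau_asymptote=simulate.derived_asymptote(params))
>>> round(model.fit().features.tau, 2)
1.5
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import pandas as pd

from . import io as sio
from .beats import BeatSegment, EnsembleBeat, ensemble_average, segment_beats
from .exceptions import InsufficientBeatsError
from .metrics import (
    WaveformFeatures,
    detect_dicrotic_notch,
    extract_features,
)
from .preprocess import FilterSettings, condition_trace
from .stats import CohortRecord, StatsReport, build_cohort_report, records_to_frame

__all__ = ["PulseWaveAnalysis", "PulseWaveResults", "CohortAnalysis", "CohortResults"]


class PulseWaveAnalysis:
    """Pulse-waveform analysis of one continuous pressure recording.

    Parameters
    ----------
    trace : PressureTrace
        Raw recording (typically 60 s at 100 Hz).
    settings : FilterSettings, optional
        Conditioning parameters (10 Hz low-pass, SG order 2 / 50 ms by
        default).
    r_threshold : float
        Correlation gate for beat retention (default 0.95).
    min_beats : int
        Minimum retained beats for a valid ensemble (default 5).
    tau_asymptote : float or "fit"
        Asymptote convention for the area-method decay constant (default
        0 mmHg, the zero-asymptote reading of the two-element Windkessel).
        Pass the known asymptote when the decay target is known, or "fit"
        to estimate it jointly (poorly identified for long tau).
    notch_guard_s, tail_guard_s : float
        Dead times after the notch and before cycle end bounding the tau
        integration window (defaults 40 ms and 100 ms, matching the ringing
        width of the conditioning filters).
    """

    def __init__(
        self,
        trace: sio.PressureTrace,
        settings: Optional[FilterSettings] = None,
        r_threshold: float = 0.95,
        min_beats: int = 5,
        tau_asymptote: Union[float, str] = 0.0,
        notch_guard_s: float = 0.04,
        tail_guard_s: float = 0.10,
        pre_margin_s: float = 0.1,
    ):
        self.trace = trace
        self.settings = settings or FilterSettings()
        self.r_threshold = r_threshold
        self.min_beats = min_beats
        self.tau_asymptote = tau_asymptote
        self.notch_guard_s = notch_guard_s
        self.tail_guard_s = tail_guard_s
        self.pre_margin_s = pre_margin_s

    @classmethod
    def from_csv(cls, path, sampling_rate: Optional[float] = None, **kwargs):
        return cls(sio.read_trace(path, sampling_rate=sampling_rate), **kwargs)

    def fit(self) -> "PulseWaveResults":
        """Run conditioning, cycle mapping, gated averaging and morphometrics."""
        conditioned = condition_trace(self.trace, self.settings)
        segments = segment_beats(conditioned)
        if not segments:
            raise InsufficientBeatsError("no cardiac cycles detected")
        ensemble = ensemble_average(
            segments,
            r_threshold=self.r_threshold,
            min_beats=self.min_beats,
            trace=conditioned,
            pre_margin_s=self.pre_margin_s,
        )
        notch = detect_dicrotic_notch(ensemble)
        features = extract_features(
            ensemble,
            notch_index=notch,
            tau_asymptote=self.tau_asymptote,
            tau_guard_s=self.notch_guard_s,
            tau_tail_guard_s=self.tail_guard_s,
        )
        return PulseWaveResults(
            model=self,
            conditioned=conditioned,
            segments=segments,
            ensemble=ensemble,
            notch_index=notch,
            features=features,
        )


@dataclass
class PulseWaveResults:
    """Fitted results of :class:`PulseWaveAnalysis`."""

    model: PulseWaveAnalysis
    conditioned: sio.PressureTrace
    segments: List[BeatSegment]
    ensemble: EnsembleBeat
    notch_index: Optional[int]
    features: WaveformFeatures

    def beat_diagnostics(self) -> pd.DataFrame:
        """Per-beat retention diagnostics (correlation vs the raw average)."""
        e = self.ensemble
        return pd.DataFrame(
            {
                "start_index": [s.start_index for s in self.segments],
                "end_index": [s.end_index for s in self.segments],
                "fiducial_index": [s.fiducial_index for s in self.segments],
                "duration_s": [s.duration for s in self.segments],
                "correlation": e.correlations,
                "retained": e.retained_flags,
            }
        )

    def summary(self) -> str:
        f = self.features
        e = self.ensemble
        lines = [
            "Pulse waveform analysis",
            "=" * 60,
            f"channel: {self.conditioned.channel.value}   "
            f"subject: {self.conditioned.subject_id or '-'}",
            f"duration: {self.conditioned.duration:.1f} s at "
            f"{self.conditioned.sampling_rate:.0f} Hz",
            f"beats detected: {e.n_detected}   retained (r > "
            f"{self.model.r_threshold}): {e.n_retained}",
            f"heart rate: {f.heart_rate:.1f} /min",
            "-" * 60,
            f"SBP  {f.sbp:7.1f} mmHg    DBP  {f.dbp:7.1f} mmHg    "
            f"PP {f.pp:6.1f} mmHg",
            f"MBP  {f.mbp:7.1f} mmHg    incBP{f.inc_bp:7.1f} mmHg",
            f"t_sys{f.t_sys:7.3f} s       t_dia{f.t_dia:7.3f} s",
            f"areas (mmHg*s): total {f.area_total:.2f} = systolic "
            f"{f.area_sys:.2f} + diastolic {f.area_dia:.2f}",
            f"diastolic decay constant tau: {f.tau:.3f} s",
        ]
        if f.flags:
            lines.append("flags: " + "; ".join(f.flags))
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plotting import plot_representative

        return plot_representative(self, ax=ax)


class CohortAnalysis:
    """Cohort-level statistics across circle-of-Willis morphology groups."""

    def __init__(self, records: Sequence[CohortRecord], alpha: float = 0.05):
        self.records = list(records)
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, alpha: float = 0.05):
        """Build from a flat per-subject table (see ``records_to_frame``)."""
        from .metrics import PressureRatios
        from .stats import CHANNEL_FEATURES, RATIO_FEATURES

        records = []
        for _, row in df.iterrows():
            def panel(prefix):
                cols = {f"{prefix}_{n}": n for n in CHANNEL_FEATURES}
                present = {n: row[c] for c, n in cols.items() if c in row}
                return WaveformFeatures(**present) if present else None

            ratios = None
            if all(n in row for n in RATIO_FEATURES):
                ratios = PressureRatios(**{n: row[n] for n in RATIO_FEATURES})
            records.append(
                CohortRecord(
                    subject_id=str(row.get("subject_id", "")),
                    cow_group=int(row["cow_group"]),
                    backflow_grade=int(row["backflow_grade"]),
                    contralateral_stenosis=float(row["contralateral_stenosis"]),
                    ica_features=panel("ica"),
                    radial_features=panel("radial"),
                    ratios=ratios,
                )
            )
        return cls(records, alpha=alpha)

    @classmethod
    def from_csv(cls, path, alpha: float = 0.05):
        return cls.from_dataframe(pd.read_csv(path), alpha=alpha)

    def to_dataframe(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def fit(self, features: Optional[Sequence[str]] = None) -> "CohortResults":
        report = build_cohort_report(self.records, alpha=self.alpha, features=features)
        return CohortResults(model=self, report=report)


@dataclass
class CohortResults:
    """Fitted cohort statistics."""

    model: CohortAnalysis
    report: StatsReport

    @property
    def anova(self) -> pd.DataFrame:
        return self.report.anova

    @property
    def tukey(self):
        return self.report.tukey

    def summary(self) -> str:
        return self.report.summary()

    def to_json(self, path=None) -> str:
        return self.report.to_json(path)
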