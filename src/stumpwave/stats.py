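"""Cohort assembly and the statistical battery.

One record per subject: circle-of-Willis morphology group (1-5), surgeon's
backflow grade (1-3), contralateral stenosis percent, and the waveform
feature panels of the ICA-stump and radial channels plus their ratios.

The battery mirrors common practice for this kind of cohort: one-way ANOVA
of each waveform variable across CoW groups followed by pairwise Tukey HSD,
Pearson correlation of contralateral stenosis against each variable,
Spearman rank correlation of backflow grade against CoW group (both
ordinal), and chi-square / Fisher exact tests for categorical tables
(Fisher when a 2x2 table has any expected count of 5 or less, per
Cochran's rule applied strictly; larger sparse tables fall back to
chi-square with a warning). Alpha defaults to 0.05 and
no correction is applied across features (Tukey adjusts within its own
family only).
"""
from __future__ import annotations

import enum
import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import StumpwaveError, ValidationError
from .metrics import PressureRatios, WaveformFeatures

__all__ = [
    "CorrelationMethod",
    "CohortRecord",
    "AnovaResult",
    "TukeyResult",
    "CategoricalTestResult",
    "StatsReport",
    "anova_oneway",
    "tukey_hsd",
    "correlate",
    "categorical_test",
    "records_to_frame",
    "build_cohort_report",
]

#: Waveform variables analysed per channel.
CHANNEL_FEATURES = ("sbp", "dbp", "pp", "mbp", "inc_bp", "t_sys", "t_dia",
                    "area_total", "area_sys", "area_dia", "tau", "heart_rate")
RATIO_FEATURES = ("sbp_ratio", "dbp_ratio", "pp_ratio", "mbp_ratio", "inc_ratio")


class CorrelationMethod(str, enum.Enum):
    PEARSON = "PEARSON"
    SPEARMAN = "SPEARMAN"


@dataclass
class CohortRecord:
    """One subject of the cohort."""

    subject_id: str
    cow_group: int
    backflow_grade: int
    contralateral_stenosis: float
    ica_features: Optional[WaveformFeatures] = None
    radial_features: Optional[WaveformFeatures] = None
    ratios: Optional[PressureRatios] = None
    cow_segments: Optional[dict] = None
    ica_trace: object = None
    radial_trace: object = None

    def __post_init__(self):
        if self.cow_group not in (1, 2, 3, 4, 5):
            raise ValidationError(f"cow_group must be 1..5, got {self.cow_group}")
        if self.backflow_grade not in (1, 2, 3):
            raise ValidationError(
                f"backflow_grade must be 1..3, got {self.backflow_grade}"
            )
        if not 0.0 <= self.contralateral_stenosis <= 100.0:
            raise ValidationError("contralateral_stenosis must be in [0, 100]")
        if self.cow_segments is not None:
            from .cow import classify_cow

            implied = classify_cow(self.cow_segments)
            if implied != self.cow_group:
                raise ValidationError(
                    f"cow_group {self.cow_group} inconsistent with segment "
                    f"states (classify to {implied})"
                )


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    excluded_groups: Tuple = ()


@dataclass(frozen=True)
class TukeyResult:
    """Pairwise Tukey HSD adjusted p-values, keyed by group-label pairs."""

    pvalues: Dict[Tuple, float]
    alpha: float = 0.05


@dataclass(frozen=True)
class CategoricalTestResult:
    statistic: float
    p: float
    test_used: str


def _clean_groups(groups: Sequence[np.ndarray], labels=None):
    if labels is None:
        labels = list(range(1, len(groups) + 1))
    cleaned, kept_labels, excluded = [], [], []
    for g, lab in zip(groups, labels):
        arr = np.asarray(g, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size >= 2:
            cleaned.append(arr)
            kept_labels.append(lab)
        else:
            excluded.append(lab)
    if excluded:
        warnings.warn(
            f"group(s) {excluded} excluded (fewer than 2 observations)",
            stacklevel=3,
        )
    if len(cleaned) < 2:
        raise ValidationError("need at least 2 groups with >= 2 observations")
    return cleaned, kept_labels, tuple(excluded)


def anova_oneway(groups: Sequence[np.ndarray], labels=None) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Groups with fewer than 2 finite observations are excluded with a
    warning; fewer than 2 usable groups raises :class:`ValidationError`.
    """
    cleaned, _, excluded = _clean_groups(groups, labels)
    F, p = sps.f_oneway(*cleaned)
    k = len(cleaned)
    n = sum(g.size for g in cleaned)
    return AnovaResult(F=float(F), df1=k - 1, df2=n - k, p=float(p),
                       excluded_groups=excluded)


def tukey_hsd(groups: Sequence[np.ndarray], alpha: float = 0.05, labels=None) -> TukeyResult:
    """Tukey honest-significant-difference pairwise comparisons.

    Adjusted p-values come from the studentized range distribution; every
    pair of usable groups is reported.
    """
    cleaned, kept_labels, _ = _clean_groups(groups, labels)
    res = sps.tukey_hsd(*cleaned)
    pvals = {}
    for i, j in itertools.combinations(range(len(cleaned)), 2):
        pvals[(kept_labels[i], kept_labels[j])] = float(res.pvalue[i, j])
    return TukeyResult(pvalues=pvals, alpha=alpha)


def correlate(x, y, method: CorrelationMethod | str = CorrelationMethod.PEARSON):
    """Pearson or Spearman correlation with a two-sided p-value.

    Spearman uses mid-ranks for ties. Zero variance in either vector raises
    :class:`ValidationError` (the coefficient is undefined).
    """
    method = CorrelationMethod(method)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size != y.size or x.size < 3:
        raise ValidationError("correlate needs equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    if method is CorrelationMethod.PEARSON:
        r, p = sps.pearsonr(x, y)
    else:
        r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def categorical_test(table) -> CategoricalTestResult:
    """Chi-square or Fisher's exact test on a contingency table.

    Chi-square when every expected count exceeds 5. Otherwise Fisher's
    exact for 2x2 tables; larger sparse tables use chi-square with a
    warning (the exact test is restricted to 2x2).
    """
    table = np.asarray(table)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table != np.round(table)) or np.any(table < 0):
            raise ValidationError("counts must be non-negative integers")
        table = table.astype(int)
    if table.sum() == 0:
        raise ValidationError("contingency table is all zero")

    expected = sps.contingency.expected_freq(table)
    if np.all(expected > 5):
        chi2, p, _, _ = sps.chi2_contingency(table)
        return CategoricalTestResult(float(chi2), float(p), "chi-square")
    if table.shape == (2, 2):
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return CategoricalTestResult(float(odds), float(p), "fisher-exact")
    warnings.warn(
        "expected counts < 5 in a table larger than 2x2; using chi-square",
        stacklevel=2,
    )
    chi2, p, _, _ = sps.chi2_contingency(table)
    return CategoricalTestResult(float(chi2), float(p), "chi-square")


def records_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Flatten cohort records into one analysis row per subject."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "cow_group": r.cow_group,
            "backflow_grade": r.backflow_grade,
            "contralateral_stenosis": r.contralateral_stenosis,
        }
        for prefix, feats in (("ica", r.ica_features), ("radial", r.radial_features)):
            if feats is not None:
                for name in CHANNEL_FEATURES:
                    row[f"{prefix}_{name}"] = getattr(feats, name)
        if r.ratios is not None:
            for name in RATIO_FEATURES:
                row[name] = getattr(r.ratios, name)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StatsReport:
    """Full statistical report for a cohort."""

    anova: pd.DataFrame
    tukey: Dict[str, TukeyResult]
    pearson_stenosis: pd.DataFrame
    spearman_backflow_cow: Tuple[float, float]
    backflow_by_cow: CategoricalTestResult
    group_summary: pd.DataFrame
    alpha: float = 0.05
    n_subjects: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "alpha": self.alpha,
            "n_subjects": self.n_subjects,
            "anova": self.anova.to_dict(orient="records"),
            "tukey": {
                feat: {f"{a}-{b}": p for (a, b), p in res.pvalues.items()}
                for feat, res in self.tukey.items()
            },
            "pearson_stenosis": self.pearson_stenosis.to_dict(orient="records"),
            "spearman_backflow_cow": {
                "rho": self.spearman_backflow_cow[0],
                "p": self.spearman_backflow_cow[1],
            },
            "backflow_by_cow": {
                "statistic": self.backflow_by_cow.statistic,
                "p": self.backflow_by_cow.p,
                "test_used": self.backflow_by_cow.test_used,
            },
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            "Cohort statistics report",
            "=" * 72,
            f"subjects: {self.n_subjects}    alpha: {self.alpha}",
            "",
            "Group summary (mean +/- SD):",
            self.group_summary.to_string(),
            "",
            "One-way ANOVA across CoW groups:",
            self.anova.to_string(index=False),
            "",
            "Spearman backflow vs CoW group: rho = "
            f"{self.spearman_backflow_cow[0]:.3f}, "
            f"p = {self.spearman_backflow_cow[1]:.4f}",
            f"Backflow x CoW table: {self.backflow_by_cow.test_used}, "
            f"p = {self.backflow_by_cow.p:.4f}",
        ]
        return "\n".join(lines)


def build_cohort_report(
    records: Sequence[CohortRecord],
    alpha: float = 0.05,
    features: Optional[Sequence[str]] = None,
) -> StatsReport:
    """Run the full battery on a cohort.

    ANOVA + Tukey per waveform variable with CoW group as the factor,
    Pearson of contralateral stenosis against each variable, Spearman of
    backflow grade against CoW group, and the categorical backflow-by-CoW
    table test. Deterministic given the input records.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValidationError("no records")
    groups_present = sorted(df["cow_group"].unique())
    if len(groups_present) < 2:
        raise ValidationError("cohort must contain at least 2 CoW groups")

    if features is None:
        features = [
            c
            for c in df.columns
            if c.startswith(("ica_", "radial_")) or c in RATIO_FEATURES
        ]

    anova_rows, tukey_out, pearson_rows = [], {}, []
    for feat in features:
        grouped = [
            df.loc[df.cow_group == g, feat].to_numpy() for g in groups_present
        ]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = anova_oneway(grouped, labels=groups_present)
                tukey_out[feat] = tukey_hsd(grouped, alpha=alpha, labels=groups_present)
            anova_rows.append(
                {"feature": feat, "F": res.F, "df1": res.df1, "df2": res.df2,
                 "p": res.p, "significant": res.p < alpha}
            )
        except (ValidationError, StumpwaveError) as exc:
            anova_rows.append(
                {"feature": feat, "F": np.nan, "df1": 0, "df2": 0, "p": np.nan,
                 "significant": False}
            )
            warnings.warn(f"ANOVA skipped for {feat}: {exc}", stacklevel=2)
        try:
            r, p = correlate(
                df["contralateral_stenosis"], df[feat], CorrelationMethod.PEARSON
            )
            pearson_rows.append({"feature": feat, "r": r, "p": p})
        except ValidationError:
            pearson_rows.append({"feature": feat, "r": np.nan, "p": np.nan})

    rho, rho_p = correlate(
        df["backflow_grade"], df["cow_group"], CorrelationMethod.SPEARMAN
    )

    table = pd.crosstab(df["cow_group"], df["backflow_grade"]).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cat = categorical_test(table)

    summary = (
        df.groupby("cow_group")[list(features)]
        .agg(["mean", "std", "count"])
        .round(3)
    )

    return StatsReport(
        anova=pd.DataFrame(anova_rows),
        tukey=tukey_out,
        pearson_stenosis=pd.DataFrame(pearson_rows),
        spearman_backflow_cow=(rho, rho_p),
        backflow_by_cow=cat,
        group_summary=summary,
        alpha=alpha,
        n_subjects=len(df),
    )
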