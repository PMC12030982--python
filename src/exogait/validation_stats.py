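"""Paired-method agreement analysis for sensor validation.

Two measurement systems observe the same quantity; the protocol reports
the RMSE and Pearson correlation of the paired series, the median and IQR
of the differences, a Shapiro-Wilk normality check on the differences, a
Wilcoxon signed-rank test (the nonparametric paired test used throughout,
as the data are typically non-normal), and Bland-Altman limits of
agreement (bias +/- 1.96 SD of the differences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PairedComparison", "AgreementReport", "agreement", "summarize_trials"]

_LOA_FACTOR = 1.96  # 95% limits of agreement


@dataclass(frozen=True)
class PairedComparison:
    """Two equal-length paired series, one per measurement method."""

    series_a: np.ndarray
    series_b: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.series_a, dtype=float)
        b = np.asarray(self.series_b, dtype=float)
        object.__setattr__(self, "series_a", a)
        object.__setattr__(self, "series_b", b)
        if a.shape != b.shape:
            raise ValueError(f"paired series lengths differ: {a.shape} vs {b.shape}")
        if a.ndim != 1 or a.size < 3:
            raise ValueError("paired series must be 1-D with at least 3 samples")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired series must be finite")


@dataclass(frozen=True)
class AgreementReport:
    """Agreement metrics between two methods measuring the same quantity."""

    label: str
    n: int
    rmse: float
    pearson_r: float | None  # None when either series has zero variance
    bias: float  # mean difference a - b
    median_diff: float
    iqr_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    shapiro_p: float | None
    wilcoxon_p: float | None
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict[str, object]:
        return {
            "label": self.label,
            "n": self.n,
            "rmse": self.rmse,
            "pearson_r": self.pearson_r,
            "bias": self.bias,
            "median_diff": self.median_diff,
            "iqr_diff": self.iqr_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "shapiro_p": self.shapiro_p,
            "wilcoxon_p": self.wilcoxon_p,
        }


def _pearson_or_none(a: np.ndarray, b: np.ndarray) -> float | None:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    return float(stats.pearsonr(a, b).statistic)


def agreement(
    pair: PairedComparison,
    alpha: float = 0.05,
    use_normality_gate: bool = True,
) -> AgreementReport:
    """Full agreement report on one paired comparison.

    Differences are ``a - b``.  The Shapiro-Wilk test gates the protocol's
    narrative (normal vs non-normal differences) but the Wilcoxon
    signed-rank p-value is always reported — when the gate indicates
    normality a note is attached rather than silently switching tests.
    Identical series (all differences zero) make the Wilcoxon statistic
    undefined; it is reported as None with a note.
    """
    a, b = pair.series_a, pair.series_b
    d = a - b
    notes: list[str] = []

    rmse = float(np.sqrt(np.mean(d**2)))
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    q75, q25 = np.percentile(d, [75, 25])

    shapiro_p: float | None
    if np.ptp(d) == 0:
        shapiro_p = None
        notes.append("differences are constant; normality test undefined")
    else:
        shapiro_p = float(stats.shapiro(d).pvalue)
        if use_normality_gate and shapiro_p >= alpha:
            notes.append(
                "Shapiro-Wilk does not reject normality; Wilcoxon reported regardless"
            )

    wilcoxon_p: float | None
    if np.all(d == 0):
        wilcoxon_p = None
        notes.append("all differences zero; Wilcoxon statistic undefined")
    else:
        wilcoxon_p = float(stats.wilcoxon(d, zero_method="pratt").pvalue)

    return AgreementReport(
        label=pair.label,
        n=int(d.size),
        rmse=rmse,
        pearson_r=_pearson_or_none(a, b),
        bias=bias,
        median_diff=float(np.median(d)),
        iqr_diff=float(q75 - q25),
        sd_diff=sd,
        loa_low=bias - _LOA_FACTOR * sd,
        loa_high=bias + _LOA_FACTOR * sd,
        shapiro_p=shapiro_p,
        wilcoxon_p=wilcoxon_p,
        notes=tuple(notes),
    )


_SUMMARY_METRICS = ("rmse", "pearson_r", "bias", "median_diff", "iqr_diff")


def summarize_trials(reports: Sequence[AgreementReport]) -> pd.DataFrame:
    """Min / max / mean / sample-SD per metric across repeated trials.

    Mirrors the reporting shape of a repeated-trials validation table.
    Metrics that are None in some report (e.g. an undefined Pearson r)
    are summarized over the remaining trials.
    """
    if not reports:
        raise ValueError("need at least one agreement report to summarize")
    rows = []
    for metric in _SUMMARY_METRICS:
        values = [getattr(r, metric) for r in reports if getattr(r, metric) is not None]
        if not values:
            rows.append({"metric": metric, "min": math.nan, "max": math.nan,
                         "mean": math.nan, "sd": math.nan, "n_trials": 0})
            continue
        arr = np.asarray(values, dtype=float)
        rows.append({
            "metric": metric,
            "min": float(arr.min()),
            "max": float(arr.max()),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n_trials": int(arr.size),
        })
    return pd.DataFrame(rows).set_index("metric")
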