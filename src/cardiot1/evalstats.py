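"""Method-agreement statistics.

Dice overlap for segmentations; Bland-Altman bias and limits of agreement
(± 2 SD), Pearson correlation with a zero-intercept regression slope, and
the intraclass correlation coefficient for paired T1 measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg

__all__ = [
    "AgreementReport",
    "dice",
    "bland_altman",
    "corr_with_origin_slope",
    "icc",
    "agreement_report",
]


@dataclass
class AgreementReport:
    r: float
    slope: float
    bias: float
    loa: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "r": self.r, "slope": self.slope, "bias": self.bias,
            "loa_low": self.loa[0], "loa_high": self.loa[1],
            "icc": self.icc, "icc_ci_low": self.icc_ci[0],
            "icc_ci_high": self.icc_ci[1], "n": self.n,
        }


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Two empty masks are in perfect agreement about absence: DSC 1.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def bland_altman(x, y):
    """Bias and ± 2 SD limits of agreement of the paired differences x - y.

    Returns ``(bias, (bias - 2 SD, bias + 2 SD))`` with the sample SD
    (ddof=1).  The conventional 1.96 multiplier is deliberately rounded to 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, (bias - 2 * sd, bias + 2 * sd)


def corr_with_origin_slope(x, y):
    """Pearson r plus the least-squares slope of y = slope * x (no intercept).

    The slope is Σxy / Σx²; r is the ordinary (centred) Pearson coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sum(x * y) / np.sum(x * x))
    return r, slope


def icc(x, y, variant: str = "ICC2"):
    """Intraclass correlation of two raters' paired measurements.

    Default is the two-way random-effects, absolute-agreement, single-measure
    coefficient ICC(2,1); other pingouin variants ("ICC1", "ICC3", ...) can
    be requested.  Returns ``(icc, (ci_low, ci_high))`` with the F-based 95%
    interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 paired ratings")
    if np.std(x) == 0 and np.std(y) == 0 and np.all(x == y):
        # degenerate but well-defined: identical constant raters agree fully
        raise ValueError("degenerate variance: both raters constant")
    df = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["A", "B"], n),
        "score": np.concatenate([x, y]),
    })
    table = pg.intraclass_corr(data=df, targets="target", raters="rater",
                               ratings="score")
    # pingouin orders rows ICC1, ICC2, ICC3, ICC1k, ICC2k, ICC3k; row labels
    # differ across versions (Shrout-Fleiss vs McGraw-Wong naming)
    order = {"ICC1": 0, "ICC2": 1, "ICC3": 2,
             "ICC1k": 3, "ICC2k": 4, "ICC3k": 5}
    if variant not in order:
        raise ValueError(f"unknown ICC variant {variant!r}")
    row = table.iloc[order[variant]]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    ci = tuple(float(v) for v in row[ci_col])
    return float(row["ICC"]), ci


def agreement_report(auto, reference) -> AgreementReport:
    """Full automatic-vs-reference agreement summary for paired T1 values."""
    auto = np.asarray(auto, dtype=float)
    reference = np.asarray(reference, dtype=float)
    r, slope = corr_with_origin_slope(reference, auto)
    bias, loa = bland_altman(auto, reference)
    i, ci = icc(auto, reference)
    return AgreementReport(r=r, slope=slope, bias=bias, loa=loa,
                           icc=i, icc_ci=ci, n=int(auto.size))
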