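"""Reliability and variability statistics for feature robustness.

Reproducibility between protocols is measured by the two-way
absolute-agreement single-measurement intraclass correlation ICC(A,1) and
by Lin's concordance correlation coefficient; variability by the
coefficient of variation (CV) and the quartile coefficient of dispersion
(QCD), both in percent.  Interpretation bins: reliability poor < 0.50,
moderate 0.50-0.75, good 0.75-0.90, excellent >= 0.90; variability
acceptable < 10%, moderate [10%, 20%), inadequate >= 20%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PairedDesign", "ReliabilityResult", "VariabilityResult",
    "icc_absolute_agreement", "lin_ccc", "coefficient_of_variation",
    "quartile_coefficient_of_dispersion", "classify",
    "RELIABILITY_BINS", "VARIABILITY_BINS",
]

RELIABILITY_BINS = ("poor", "moderate", "good", "excellent")
VARIABILITY_BINS = ("acceptable", "moderate", "inadequate")


@dataclass
class PairedDesign:
    """n subjects x k raters (materials x protocols) value matrix."""

    values: np.ndarray
    subjects: tuple = ()
    protocols: tuple = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D (subjects x protocols) matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 protocols")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in the design")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class ReliabilityResult:
    """Per-feature agreement between protocols."""

    feature: str
    icc: float
    ccc: float
    n: int
    k: int
    ms_rows: float = np.nan
    ms_cols: float = np.nan
    ms_err: float = np.nan
    degenerate: bool = False


@dataclass
class VariabilityResult:
    """Per-feature dispersion over a set of protocol values."""

    feature: str
    cv: float
    qcd: float
    q1: float = np.nan
    q3: float = np.nan
    n: int = 0
    undefined: bool = False


def _two_way_mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return ms_rows, ms_cols, ms_err


def icc_absolute_agreement(design: PairedDesign,
                           feature: str = "") -> ReliabilityResult:
    """ICC(A,1): two-way, absolute agreement, single measurement.

    ``(MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))`` from the
    two-way ANOVA decomposition of the n x k design.  Identical values
    everywhere are a degenerate case defined as perfect agreement (1).
    The companion CCC field is filled by :func:`reliability` helpers; here
    it is NaN.
    """
    x = design.values
    n, k = x.shape
    ms_r, ms_c, ms_e = _two_way_mean_squares(x)
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if np.isclose(denom, 0.0, atol=1e-30):
        # no variance anywhere: identical columns and subjects
        return ReliabilityResult(feature, 1.0, np.nan, n, k, ms_r, ms_c,
                                 ms_e, degenerate=True)
    icc = (ms_r - ms_e) / denom
    return ReliabilityResult(feature, float(icc), np.nan, n, k,
                             float(ms_r), float(ms_c), float(ms_e))


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    ``2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)`` with moment estimators
    using denominator n (Lin's original definition).  Returns 1 for two
    identical constant vectors (perfect, if degenerate, agreement).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        return 1.0  # both constant and equal
    return 2.0 * sxy / denom


def coefficient_of_variation(values) -> VariabilityResult:
    """CV in percent: 100 * sample SD (n-1) / |mean|; undefined at mean 0."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean == 0.0:
        return VariabilityResult("", np.nan, np.nan, n=x.size, undefined=True)
    return VariabilityResult("", 100.0 * sd / abs(mean), np.nan, n=x.size)


def quartile_coefficient_of_dispersion(values) -> VariabilityResult:
    """QCD in percent: 100 * (Q3 - Q1) / |Q3 + Q1| (type-7 quantiles)."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation (type 7)
    if q3 + q1 == 0.0:
        return VariabilityResult("", np.nan, np.nan, q1=float(q1),
                                 q3=float(q3), n=x.size, undefined=True)
    qcd = 100.0 * (q3 - q1) / abs(q3 + q1)
    return VariabilityResult("", np.nan, float(qcd), q1=float(q1),
                             q3=float(q3), n=x.size)


def classify(value: float, metric: str) -> str:
    """Interpretation bin of a reliability or variability value.

    Reliability: poor [-1, 0.50), moderate [0.50, 0.75), good [0.75,
    0.90), excellent [0.90, 1].  Variability (percent): acceptable
    [0, 10), moderate [10, 20), inadequate [20, inf).  NaN -> 'undefined'.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "undefined"
    if metric == "reliability":
        if value >= 0.90:
            return "excellent"
        if value >= 0.75:
            return "good"
        if value >= 0.50:
            return "moderate"
        return "poor"
    if metric == "variability":
        if value >= 20.0:
            return "inadequate"
        if value >= 10.0:
            return "moderate"
        return "acceptable"
    raise ValueError(f"unknown metric {metric!r}")
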