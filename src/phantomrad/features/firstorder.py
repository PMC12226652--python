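"""First-order (intensity histogram) features.

Computed on the raw HU values of the ROI; only Entropy and Uniformity use
the fixed-bin-width histogram.  Skewness and Kurtosis (the non-excess,
population form) are returned as 0 and flagged degenerate for
zero-variance ROIs.
"""

from __future__ import annotations

import numpy as np

from .discretize import discretize

__all__ = ["FIRSTORDER_NAMES", "first_order_features"]

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
    "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def first_order_features(values, voxel_volume: float = 1.0,
                         bin_width: float = 25.0):
    """The 18 first-order features of a raw-HU ROI.

    Returns ``(features, degenerate)`` where ``features`` maps name to
    value and ``degenerate`` is the set of flagged feature names.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    degenerate: set[str] = set()

    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    levels = discretize(x, bin_width)
    p = np.bincount(levels)[1:].astype(np.float64) / n
    p = p[p > 0]

    if var > 0:
        m2 = var
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2
    else:
        skew = kurt = 0.0
        degenerate.update({"Skewness", "Kurtosis"})

    feats = {
        "Energy": float(np.sum(x * x)),
        "TotalEnergy": float(voxel_volume * np.sum(x * x)),
        "Entropy": float(-np.sum(p * np.log2(p)) + 0.0),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x * x))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p * p)),
    }
    return feats, degenerate
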