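"""First-order intensity statistics: 17 descriptors."""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy import stats

from ..preprocess import discretize_fixed_binwidth

FIRSTORDER_FEATURE_NAMES = [
    "Mean",
    "Median",
    "Minimum",
    "Maximum",
    "Range",
    "Percentile10",
    "Percentile90",
    "InterquartileRange",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Energy",
    "RootMeanSquared",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "Entropy",
    "Uniformity",
]


def extract_firstorder(image: np.ndarray, mask: np.ndarray,
                       bin_width: float = 5.0) -> Dict[str, float]:
    """Intensity statistics over the ROI; entropy/uniformity use the
    fixed-bin-width discretization anchored at the ROI minimum."""
    x = np.asarray(image, dtype=float)[np.asarray(mask).astype(bool)]
    if x.size == 0:
        raise ValueError("empty mask")
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    bins = discretize_fixed_binwidth(x, bin_width)
    p = np.bincount(bins)[1:].astype(float)
    p = p[p > 0] / x.size
    var = float(x.var())
    if var > 0:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x, fisher=False))
    else:
        skew, kurt = 0.0, 0.0  # constant ROI convention
    return {
        "Mean": float(x.mean()),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "InterquartileRange": float(p75 - p25),
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((x ** 2).sum()),
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "MeanAbsoluteDeviation": float(np.abs(x - x.mean()).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean())
        if robust.size else 0.0,
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Uniformity": float((p ** 2).sum()),
    }
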