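"""Pearson correlation between the ECC uniformity metric and diffusivity.

The link the analysis closes: a per-image topological summary (the
Max–Min spread of the normalized Euler curve) sampled over the process,
against the stepwise effective diffusivity estimated on the kinetic
side.  Pairs are matched by nearest time within a tolerance because
images and kinetic samples are rarely taken on identical clocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CorrelationResult", "pearson_correlation", "correlate_ecc_diffusivity"]


class ConstantSeriesError(ValueError):
    """Raised when Pearson's r is undefined because a series is constant."""


@dataclass(frozen=True)
class CorrelationResult:
    substance: str
    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.r <= 1 + 1e-12:
            raise ValueError("r must lie in [-1, 1]")
        if self.n < 3:
            raise ValueError("need at least 3 paired points")


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantSeriesError("Pearson's r is undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)


def correlate_ecc_diffusivity(
    metric_times: np.ndarray,
    metric_values: np.ndarray,
    d_times: np.ndarray,
    d_values: np.ndarray,
    substance: str = "",
    time_tolerance: float | None = None,
) -> CorrelationResult:
    """Correlate a Max–Min time series against stepwise diffusivities.

    ``d_times`` are interval midpoints of the stepwise estimate.  Each
    diffusivity point is paired with the nearest metric sample within
    ``time_tolerance`` (default: half the smallest metric sampling
    interval); unmatched points are dropped.  A two-sided t-test
    p-value accompanies r.
    """
    metric_times = np.asarray(metric_times, dtype=float)
    metric_values = np.asarray(metric_values, dtype=float)
    d_times = np.asarray(d_times, dtype=float)
    d_values = np.asarray(d_values, dtype=float)
    if time_tolerance is None:
        gaps = np.diff(np.sort(metric_times))
        time_tolerance = float(gaps.min() / 2) if gaps.size else np.inf
    xs, ys = [], []
    for td, d in zip(d_times, d_values):
        j = int(np.argmin(np.abs(metric_times - td)))
        if abs(metric_times[j] - td) <= time_tolerance:
            xs.append(metric_values[j])
            ys.append(d)
    if len(xs) < 3:
        raise ValueError("fewer than 3 matched pairs within the time tolerance")
    x = np.asarray(xs)
    y = np.asarray(ys)
    r = pearson_correlation(x, y)
    res = stats.pearsonr(x, y)
    return CorrelationResult(substance=substance, r=r, p_value=float(res.pvalue), n=len(xs))
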