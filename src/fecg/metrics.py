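"""Amplitude, SNR, correlation and summary statistics.

Conventions:

* quasi-periodic signal amplitude = mean over complete beats of the
  per-beat (max − min) value;
* stochastic noise amplitude = 4 × sample standard deviation over the
  whole trace;
* SNR in dB = 10·log10(signal amplitude / noise amplitude);
* percentiles use midpoint-position linear interpolation (the p-th
  percentile interpolates between order statistics placed at cumulative
  positions 100·(i − 0.5)/n — the "hazen" convention).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats as spstats

from .errors import MetricError, ParameterError
from .sbmm import DEFAULT_QRS_POST_MS, DEFAULT_QRS_PRE_MS, segment_beats
from .signal_model import CorrelationResult, RPeakSeries, SummaryStats, Trace

__all__ = [
    "signal_amplitude",
    "noise_amplitude",
    "snr_db",
    "pearson",
    "ranksum",
    "summarize",
]


def signal_amplitude(
    trace: Trace,
    rpeaks: RPeakSeries,
    qrs_pre_ms: float = DEFAULT_QRS_PRE_MS,
    qrs_post_ms: float = DEFAULT_QRS_POST_MS,
) -> float:
    """Mean over complete beats of the within-beat peak-to-peak range (µV)."""
    if len(rpeaks) < 2:
        raise MetricError("signal amplitude needs at least 2 R peaks")
    seg = segment_beats(trace, rpeaks, qrs_pre_ms, qrs_post_ms)
    x = trace.samples
    spans = [
        float(np.max(x[a:b]) - np.min(x[a:b]))
        for a, b in zip(seg.qrs_start, seg.tu_end)
    ]
    if not spans:
        raise MetricError("no complete beat inside the trace")
    return float(np.mean(spans))


def noise_amplitude(trace: Trace) -> float:
    """4 × sample standard deviation (n−1 denominator) over the trace, µV."""
    return 4.0 * float(np.std(trace.samples, ddof=1))


def snr_db(signal_amplitude_uv: float, noise_amplitude_uv: float) -> float:
    """10·log10(signal amplitude / noise amplitude)."""
    if signal_amplitude_uv <= 0 or noise_amplitude_uv <= 0:
        raise MetricError(
            f"amplitudes must be positive, got signal={signal_amplitude_uv}, "
            f"noise={noise_amplitude_uv}"
        )
    return 10.0 * math.log10(signal_amplitude_uv / noise_amplitude_uv)


def pearson(x: Trace, y: Trace) -> CorrelationResult:
    """Product-moment correlation with two-sided t-transform p-value."""
    a, b = x.samples, y.samples
    if a.size != b.size:
        raise MetricError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise MetricError("pearson needs at least 3 paired samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise MetricError("pearson undefined for zero-variance input")
    r = spstats.pearsonr(a, b)
    return CorrelationResult(rho=float(r.statistic), p_value=float(r.pvalue), n=a.size)


def ranksum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value for equal medians.

    Exact null distribution when the smaller sample has ≤ 10 values and
    there are no ties; normal approximation (with tie correction and
    continuity correction) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MetricError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = spstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(1.0, res.pvalue))


def _hazen_percentile(values: np.ndarray, q: float) -> float:
    return float(np.percentile(values, q, method="hazen"))


def summarize(
    values: Sequence[float],
    mode: str = "pooled",
    record_ids: Optional[Sequence] = None,
) -> SummaryStats:
    """Median and quartiles, pooled or after per-record median reduction.

    ``mode="pooled"`` summarizes the values directly; ``"per_record_median"``
    first collapses each record (as labelled by `record_ids`) to its median
    and summarizes those.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise MetricError("summarize needs at least one value")
    if mode == "per_record_median":
        if record_ids is None or len(record_ids) != vals.size:
            raise ParameterError(
                "per_record_median requires record_ids matching values"
            )
        ids = np.asarray(record_ids)
        vals = np.array(
            [np.median(vals[ids == rid]) for rid in dict.fromkeys(record_ids)]
        )
    elif mode != "pooled":
        raise ParameterError(f"unknown mode {mode!r}")
    return SummaryStats(
        median=_hazen_percentile(vals, 50.0),
        p25=_hazen_percentile(vals, 25.0),
        p75=_hazen_percentile(vals, 75.0),
        n=int(vals.size),
    )
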