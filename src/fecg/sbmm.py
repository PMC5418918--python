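"""Segmented-beat modulation denoising.

The method estimates the quasi-periodic component of an ECG trace whose
R peaks are known.  Each beat is split into a fixed-length QRS segment
(around its R peak) and a variable-length TU segment (the remainder of
the beat, carrying the repolarization wave and the next P wave).  The TU
segment of every beat is *modulated* — resampled to a common reference
length — so beats become directly comparable; a pointwise median (or
mean) across the modulated beats yields a template; the template's TU
part is then *demodulated* back to each beat's own length and the beats
are concatenated to reconstruct a clean estimate.  The time-axis
modulation is what lets the template track beat-to-beat changes of
repolarization length caused by heart-rate variability, which
fixed-length template methods cannot do.

Only complete beats (those between two consecutive R peaks, with the
QRS window fully inside the trace) are processed; head and tail samples
outside complete beats are copied through unchanged so that
``clean + residual == input`` holds exactly everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import EstimationError, ParameterError, SegmentationError
from .signal_model import RPeakSeries, Trace

__all__ = [
    "BeatSegmentation",
    "ModulatedTemplate",
    "segment_beats",
    "modulate_segment",
    "build_template",
    "sbmm_denoise",
    "paste_template",
    "DEFAULT_QRS_PRE_MS",
    "DEFAULT_QRS_POST_MS",
    "FETAL_QRS_PRE_MS",
    "FETAL_QRS_POST_MS",
]

# Maternal QRS window defaults; fetal QRS complexes are narrower.
DEFAULT_QRS_PRE_MS = 100.0
DEFAULT_QRS_POST_MS = 100.0
FETAL_QRS_PRE_MS = 50.0
FETAL_QRS_POST_MS = 50.0


@dataclass(frozen=True)
class BeatSegmentation:
    """Per-beat QRS/TU boundaries (sample indices, half-open intervals).

    Beat *i* spans ``[qrs_start[i], tu_end[i])`` where
    ``tu_end[i] == qrs_start[i+1]`` for interior beats.  The QRS length
    ``qrs_end - qrs_start`` is identical for all beats; TU lengths vary
    with the RR interval.
    """

    qrs_start: np.ndarray
    qrs_end: np.ndarray
    tu_start: np.ndarray
    tu_end: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        for name in ("qrs_start", "qrs_end", "tu_start", "tu_end", "rr"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        n = self.qrs_start.size
        if not all(
            getattr(self, f).size == n for f in ("qrs_end", "tu_start", "tu_end", "rr")
        ):
            raise ParameterError("segmentation fields must have equal length")
        if n == 0:
            return
        ok = (self.qrs_start < self.qrs_end) & (self.qrs_end <= self.tu_start) & (
            self.tu_start < self.tu_end
        )
        if not np.all(ok):
            raise ParameterError("beat boundaries must satisfy qrs_start < qrs_end <= tu_start < tu_end")
        qrs_len = self.qrs_end - self.qrs_start
        if np.unique(qrs_len).size != 1:
            raise ParameterError("QRS length must be identical across beats")
        if n > 1 and not np.all(self.qrs_start[1:] >= self.tu_end[:-1]):
            raise ParameterError("beats must be ordered and non-overlapping")

    @property
    def n_beats(self) -> int:
        return self.qrs_start.size

    @property
    def qrs_len(self) -> int:
        return int(self.qrs_end[0] - self.qrs_start[0])

    @property
    def tu_len(self) -> np.ndarray:
        return self.tu_end - self.tu_start


@dataclass(frozen=True)
class ModulatedTemplate:
    """Beat template estimated in the modulated (common-length) domain."""

    qrs_template: np.ndarray
    tu_template: np.ndarray
    reference_tu_len: int
    n_beats_used: int

    def __post_init__(self) -> None:
        q = np.asarray(self.qrs_template, dtype=np.float64)
        t = np.asarray(self.tu_template, dtype=np.float64)
        q.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "qrs_template", q)
        object.__setattr__(self, "tu_template", t)
        if t.size != self.reference_tu_len:
            raise ParameterError(
                f"tu_template length {t.size} != reference_tu_len {self.reference_tu_len}"
            )
        if self.n_beats_used < 2:
            raise EstimationError("template requires at least 2 beats")


def _window_samples(ms: float, fs: float) -> int:
    n = int(round(ms * fs / 1000.0))
    if n < 1:
        raise ParameterError(f"QRS window {ms} ms is shorter than one sample at {fs} Hz")
    return n


def segment_beats(
    trace: Trace,
    rpeaks: RPeakSeries,
    qrs_pre_ms: float = DEFAULT_QRS_PRE_MS,
    qrs_post_ms: float = DEFAULT_QRS_POST_MS,
) -> BeatSegmentation:
    """Split the span between consecutive R peaks into QRS + TU segments.

    Beat *i* covers ``[R_i - pre, R_{i+1} - pre)``; its QRS segment is
    ``[R_i - pre, R_i + post)`` and its TU segment the remainder.  The
    last R peak only closes the final beat.  Beats whose window would
    fall outside the trace are dropped (edge beats).
    """
    rpeaks.validate_for(trace)
    if len(rpeaks) < 2:
        raise SegmentationError("at least 2 R peaks are required")
    pre = _window_samples(qrs_pre_ms, trace.fs)
    post = _window_samples(qrs_post_ms, trace.fs)

    r = rpeaks.indices
    rr = np.diff(r)
    bad = np.nonzero(rr <= pre + post)[0]
    if bad.size:
        i = int(bad[0])
        raise SegmentationError(
            f"RR interval of beat {i} ({rr[i]} samples, R at {r[i]}) is not "
            f"longer than the QRS window ({pre + post} samples)"
        )

    qrs_start = r[:-1] - pre
    qrs_end = r[:-1] + post
    tu_start = qrs_end
    tu_end = r[1:] - pre

    keep = (qrs_start >= 0) & (tu_end <= len(trace))
    if not np.any(keep):
        raise SegmentationError("no complete beat fits inside the trace")
    return BeatSegmentation(
        qrs_start=qrs_start[keep],
        qrs_end=qrs_end[keep],
        tu_start=tu_start[keep],
        tu_end=tu_end[keep],
        rr=rr[keep],
    )


def modulate_segment(
    segment: np.ndarray, target_len: int, interpolation: str = "cubic"
) -> np.ndarray:
    """Resample a segment to `target_len` samples on a uniform support.

    The segment is re-parameterized on [0, 1]; first and last samples are
    preserved exactly.  ``interpolation`` is ``"cubic"`` (cubic spline on
    segments of ≥ 4 samples, linear below) or ``"linear"``.
    """
    seg = np.asarray(segment, dtype=np.float64)
    if seg.ndim != 1 or seg.size < 2:
        raise ParameterError("segment must be 1-D with at least 2 samples")
    target_len = int(target_len)
    if target_len < 2:
        raise ParameterError("target_len must be >= 2")
    if interpolation not in ("cubic", "linear"):
        raise ParameterError(f"unknown interpolation {interpolation!r}")
    if target_len == seg.size:
        return seg.copy()

    x = np.linspace(0.0, 1.0, seg.size)
    xi = np.linspace(0.0, 1.0, target_len)
    if interpolation == "cubic" and seg.size >= 4:
        out = CubicSpline(x, seg)(xi)
    else:
        out = np.interp(xi, x, seg)
    # pin endpoints against interpolation round-off
    out[0] = seg[0]
    out[-1] = seg[-1]
    return out


def _reference_tu_len(tu_len: np.ndarray) -> int:
    # np.round resolves halves to the nearest even integer
    return int(np.round(np.median(tu_len)))


def build_template(
    trace: Trace,
    seg: BeatSegmentation,
    reference_tu_len: int | None = None,
    stat: str = "median",
    interpolation: str = "cubic",
) -> ModulatedTemplate:
    """Estimate the beat template in the modulated domain.

    Every beat's TU segment is modulated to `reference_tu_len` (default:
    the median per-beat TU length); QRS segments already share a length.
    The template is the pointwise `stat` (median or mean) across beats.
    """
    if seg.n_beats < 2:
        raise EstimationError(f"need >= 2 beats to build a template, got {seg.n_beats}")
    if stat not in ("median", "mean"):
        raise ParameterError(f"stat must be 'median' or 'mean', got {stat!r}")
    if reference_tu_len is None:
        reference_tu_len = _reference_tu_len(seg.tu_len)
    reference_tu_len = int(reference_tu_len)
    if reference_tu_len < 2:
        raise ParameterError("reference_tu_len must be >= 2")

    x = trace.samples
    qrs_stack = np.stack(
        [x[a:b] for a, b in zip(seg.qrs_start, seg.qrs_end)]
    )
    tu_stack = np.stack(
        [
            modulate_segment(x[a:b], reference_tu_len, interpolation)
            for a, b in zip(seg.tu_start, seg.tu_end)
        ]
    )
    reducer = np.median if stat == "median" else np.mean
    return ModulatedTemplate(
        qrs_template=reducer(qrs_stack, axis=0),
        tu_template=reducer(tu_stack, axis=0),
        reference_tu_len=reference_tu_len,
        n_beats_used=seg.n_beats,
    )


def paste_template(
    trace: Trace,
    seg: BeatSegmentation,
    template: ModulatedTemplate,
    interpolation: str = "cubic",
) -> np.ndarray:
    """Reconstruct the clean estimate by demodulating the template.

    For every beat the QRS template is emitted as-is and the TU template
    is demodulated (resampled back) to the beat's own TU length.  Samples
    outside complete beats are copied from the input.
    """
    clean = trace.samples.copy()
    for qa, qb, ta, tb in zip(seg.qrs_start, seg.qrs_end, seg.tu_start, seg.tu_end):
        clean[qa:qb] = template.qrs_template
        clean[ta:tb] = modulate_segment(
            template.tu_template, tb - ta, interpolation
        )
    return clean


def sbmm_denoise(
    trace: Trace,
    rpeaks: RPeakSeries,
    qrs_pre_ms: float = DEFAULT_QRS_PRE_MS,
    qrs_post_ms: float = DEFAULT_QRS_POST_MS,
    stat: str = "median",
    interpolation: str = "cubic",
    reference_tu_len: int | None = None,
) -> tuple[Trace, Trace]:
    """Denoise a (prefiltered) trace given its R peaks.

    Returns ``(clean, residual)`` with ``clean + residual == trace``
    exactly (the residual is defined by subtraction).
    """
    seg = segment_beats(trace, rpeaks, qrs_pre_ms, qrs_post_ms)
    template = build_template(
        trace, seg, reference_tu_len=reference_tu_len, stat=stat,
        interpolation=interpolation,
    )
    clean = paste_template(trace, seg, template, interpolation)
    residual = trace.samples - clean
    label = trace.label or "trace"
    return (
        trace.with_samples(clean, f"{label}:clean"),
        trace.with_samples(residual, f"{label}:residual"),
    )
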