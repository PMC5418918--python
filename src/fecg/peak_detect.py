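"""Pan-Tompkins QRS detection.

Classical stage chain: band-pass (5–15 Hz), five-point derivative,
squaring, moving-window integration (150 ms), then adaptive
dual-threshold decision with a 200 ms refractory period and RR-based
search-back.  All filters here are applied with centered/zero-phase
alignment so the integrated waveform stays aligned with the QRS and the
final indices can be refined to the local extremum of the band-passed
signal within ±50 ms.

Every threshold is derived from the data itself, which makes detections
invariant to positive rescaling of the input — abdominal lead gain and
polarity are arbitrary, so refinement uses the absolute band-passed
signal.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .signal_model import RPeakSeries, Trace

__all__ = ["pan_tompkins"]


def _preprocess(x: np.ndarray, fs: float, low_hz: float, high_hz: float,
                integration_ms: float) -> tuple[np.ndarray, np.ndarray]:
    sos = sps.butter(3, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    # five-point derivative, centered so QRS alignment is preserved
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kernel, mode="same")
    squared = deriv * deriv
    win = max(1, int(round(integration_ms * fs / 1000.0)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")
    return bp, mwi


def _adaptive_select(peaks: np.ndarray, mwi: np.ndarray, fs: float,
                     refractory: int) -> list[int]:
    """Dual running-estimate thresholding with search-back."""
    if peaks.size == 0:
        return []
    init = mwi[: int(2 * fs)]
    spki = 0.25 * float(np.max(init)) if init.size else 0.0
    npki = 0.5 * float(np.mean(init)) if init.size else 0.0
    accepted: list[int] = []
    recent_rr: list[int] = []
    # candidates rejected since the last accepted beat, for search-back
    pending: list[int] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for p in peaks:
        v = mwi[p]
        if accepted and p - accepted[-1] < refractory:
            continue
        if v > threshold():
            if accepted:
                recent_rr.append(p - accepted[-1])
                del recent_rr[:-8]
            accepted.append(int(p))
            pending.clear()
            spki = 0.125 * v + 0.875 * spki
        else:
            pending.append(int(p))
            npki = 0.125 * v + 0.875 * npki
            # search-back: no beat for 1.66× the running average RR
            if accepted and recent_rr:
                avg_rr = float(np.mean(recent_rr))
                if p - accepted[-1] > 1.66 * avg_rr:
                    cands = [
                        q for q in pending
                        if q - accepted[-1] >= refractory
                        and mwi[q] > 0.5 * threshold()
                    ]
                    if cands:
                        best = max(cands, key=lambda q: mwi[q])
                        accepted.append(int(best))
                        accepted.sort()
                        pending = [q for q in pending if q > best]
                        spki = 0.25 * mwi[best] + 0.75 * spki
    return accepted


def pan_tompkins(
    trace: Trace,
    bandpass_low_hz: float = 5.0,
    bandpass_high_hz: float = 15.0,
    integration_ms: float = 150.0,
    refractory_ms: float = 200.0,
) -> RPeakSeries:
    """Detect R peaks; returns a series with ``source="pan_tompkins"``.

    Requires fs ≥ 200 Hz and at least 2 s of signal.  A flat trace
    yields an empty series.
    """
    fs = trace.fs
    if fs < 200:
        raise ParameterError(f"Pan-Tompkins requires fs >= 200 Hz, got {fs}")
    if len(trace) < 2 * fs:
        raise ParameterError("trace must be at least 2 s long")

    x = trace.samples
    bp, mwi = _preprocess(x, fs, bandpass_low_hz, bandpass_high_hz, integration_ms)
    if np.max(mwi) <= 0:
        return RPeakSeries(np.array([], dtype=np.int64), fs, source="pan_tompkins")

    refractory = int(round(refractory_ms * fs / 1000.0))
    cand, _ = sps.find_peaks(mwi, distance=max(1, refractory // 2))
    accepted = _adaptive_select(cand, mwi, fs, refractory)
    if not accepted:
        return RPeakSeries(np.array([], dtype=np.int64), fs, source="pan_tompkins")

    # refine each detection to the local extremum of |band-passed| ±50 ms
    half = int(round(0.05 * fs))
    refined = []
    for p in accepted:
        a = max(0, p - half)
        b = min(len(x), p + half + 1)
        refined.append(a + int(np.argmax(np.abs(bp[a:b]))))
    refined = np.unique(refined)

    # enforce the refractory period after refinement, keeping the stronger peak
    out: list[int] = []
    for p in refined:
        if out and p - out[-1] < refractory:
            if np.abs(bp[p]) > np.abs(bp[out[-1]]):
                out[-1] = int(p)
        else:
            out.append(int(p))
    return RPeakSeries(np.asarray(out, dtype=np.int64), fs, source="pan_tompkins")
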