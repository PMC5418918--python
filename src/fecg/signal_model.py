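"""Core in-memory types shared by every pipeline stage.

All voltages are stored in microvolts (µV); readers convert from source
units on load so that reported amplitudes are directly comparable across
records.  Sample indexing is 0-based and intervals are half-open
``[start, end)`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import FormatError, ParameterError

__all__ = [
    "Trace",
    "RPeakSeries",
    "DirectDecomposition",
    "AbdominalDecomposition",
    "SNRReport",
    "CorrelationResult",
    "SummaryStats",
    "CONSERVATION_TOL_UV",
]

#: Maximum absolute deviation (µV) tolerated when checking that the
#: components of a decomposition sum back to their input.
CONSERVATION_TOL_UV = 1e-6


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1:
        raise ParameterError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled voltage signal.

    Parameters
    ----------
    samples : array-like
        Voltage samples in µV.  Stored as a read-only float64 array.
    fs : float
        Sampling rate in Hz; must be positive.
    label : str
        Free-text channel label.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        arr = _as_float_array(self.samples, "samples")
        if arr.size < 2:
            raise ParameterError("a Trace needs at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("Trace samples must all be finite")
        if not (self.fs > 0):
            raise ParameterError(f"sampling rate must be > 0, got {self.fs}")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def time_s(self) -> np.ndarray:
        """Sample times in seconds (0-based)."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples, label: Optional[str] = None) -> "Trace":
        """A new trace with the same fs and (by default) the same label."""
        return Trace(samples, self.fs, self.label if label is None else label)


_RPEAK_SOURCES = ("reference", "pan_tompkins", "synthetic_truth")


@dataclass(frozen=True)
class RPeakSeries:
    """Strictly increasing R-peak sample positions on a trace."""

    indices: np.ndarray
    fs: float
    source: str = "reference"

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ParameterError("R-peak indices must be one-dimensional")
        if idx.size and idx[0] < 0:
            raise FormatError("R-peak indices must be non-negative")
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise FormatError("R-peak indices must be strictly increasing")
        if not (self.fs > 0):
            raise ParameterError(f"sampling rate must be > 0, got {self.fs}")
        if self.source not in _RPEAK_SOURCES:
            raise ParameterError(
                f"source must be one of {_RPEAK_SOURCES}, got {self.source!r}"
            )
        idx = idx.copy()
        idx.setflags(write=False)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.indices.size

    def rr_samples(self) -> np.ndarray:
        """Inter-beat intervals in samples."""
        return np.diff(self.indices)

    def validate_for(self, trace: Trace) -> None:
        """Raise unless this series annotates `trace` consistently."""
        if self.fs != trace.fs:
            raise FormatError(
                f"R-peak fs {self.fs} Hz != trace fs {trace.fs} Hz"
            )
        if self.indices.size and self.indices[-1] >= len(trace):
            raise FormatError(
                f"R-peak index {self.indices[-1]} outside trace of length {len(trace)}"
            )


def _check_aligned(parts: dict, fs: float, n: int) -> None:
    for name, tr in parts.items():
        if tr.fs != fs:
            raise FormatError(f"component {name!r} fs {tr.fs} != {fs}")
        if len(tr) != n:
            raise FormatError(f"component {name!r} length {len(tr)} != {n}")


def _check_sum(total: Trace, parts: list, what: str) -> None:
    resid = total.samples - sum(p.samples for p in parts)
    dev = float(np.max(np.abs(resid)))
    if dev > CONSERVATION_TOL_UV:
        raise FormatError(
            f"{what} not conserved: max |input - sum(components)| = {dev:g} µV"
        )


@dataclass(frozen=True)
class DirectDecomposition:
    """Additive split of a prefiltered direct (scalp) recording."""

    input: Trace
    dfecg: Trace
    dn: Trace

    def __post_init__(self) -> None:
        _check_aligned({"dfecg": self.dfecg, "dn": self.dn}, self.input.fs, len(self.input))
        _check_sum(self.input, [self.dfecg, self.dn], "direct decomposition")

    @property
    def max_abs_deviation(self) -> float:
        return float(
            np.max(np.abs(self.input.samples - self.dfecg.samples - self.dn.samples))
        )


@dataclass(frozen=True)
class AbdominalDecomposition:
    """Additive split of a prefiltered abdominal channel.

    ``mecg + ifecg_noisy == input`` and ``ifecg + in_noise == ifecg_noisy``,
    each to within :data:`CONSERVATION_TOL_UV`.
    """

    input: Trace
    mecg: Trace
    ifecg_noisy: Trace
    ifecg: Trace
    in_noise: Trace

    def __post_init__(self) -> None:
        parts = {
            "mecg": self.mecg,
            "ifecg_noisy": self.ifecg_noisy,
            "ifecg": self.ifecg,
            "in_noise": self.in_noise,
        }
        _check_aligned(parts, self.input.fs, len(self.input))
        _check_sum(self.input, [self.mecg, self.ifecg_noisy], "maternal split")
        _check_sum(self.ifecg_noisy, [self.ifecg, self.in_noise], "fetal split")

    @property
    def max_abs_deviation(self) -> float:
        d1 = np.abs(self.input.samples - self.mecg.samples - self.ifecg_noisy.samples)
        d2 = np.abs(self.ifecg_noisy.samples - self.ifecg.samples - self.in_noise.samples)
        return float(max(d1.max(), d2.max()))


_SNR_KINDS = ("DSNR", "ISNR1", "ISNR2")


@dataclass(frozen=True)
class SNRReport:
    """Signal amplitude, noise amplitude and their dB ratio."""

    signal_amplitude: float
    noise_amplitude: float
    snr_db: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _SNR_KINDS:
            raise ParameterError(f"kind must be one of {_SNR_KINDS}, got {self.kind!r}")
        if self.signal_amplitude > 0 and self.noise_amplitude > 0:
            expect = 10.0 * np.log10(self.signal_amplitude / self.noise_amplitude)
            if abs(expect - self.snr_db) > 1e-9:
                raise FormatError(
                    f"snr_db {self.snr_db} inconsistent with amplitudes "
                    f"(expected {expect})"
                )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with its two-sided p-value."""

    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12):
            raise FormatError(f"rho must lie in [-1, 1], got {self.rho}")


@dataclass(frozen=True)
class SummaryStats:
    """Median and quartiles of a sample, in the sample's units."""

    median: float
    p25: float
    p75: float
    n: int
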