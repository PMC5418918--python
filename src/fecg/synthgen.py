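"""Synthetic maternal + fetal mixture generation with exact ground truth.

Beats are rendered as sums of Gaussian kernels (P, Q, R, S, T waves)
placed relative to each R peak; RR intervals follow a seeded first-order
autoregressive process, and the T wave's position and width scale with
√RR so that repolarization length varies beat to beat — exactly the
property the modulation-based denoiser has to track.  Every channel is
stored together with its exact additive components (maternal, fetal,
noise), so ``maternal + fetal + noise == recorded`` holds bit-level.

Noise is a four-part mixture: baseline wander (< 0.5 Hz), powerline
(50 Hz with drifting phase), broadband Gaussian, and EMG-like Gaussian
band-passed to 20–45 Hz.  Each part is scaled to its configured RMS in
µV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .ecg_io import RecordSet
from .signal_model import RPeakSeries, Trace

__all__ = [
    "WaveKernel",
    "BeatShape",
    "HeartConfig",
    "NoiseConfig",
    "SynthConfig",
    "SynthRecord",
    "gen_beat_train",
    "gen_record_set",
]


@dataclass(frozen=True)
class WaveKernel:
    """One Gaussian component of the beat morphology.

    `center_ms` / `width_ms` are relative to the R peak at the nominal RR
    interval; when `scales_with_rr` is set they are stretched by
    √(RR / RR_nominal) for each beat.
    """

    amplitude: float
    center_ms: float
    width_ms: float
    scales_with_rr: bool = False


@dataclass(frozen=True)
class BeatShape:
    """P-QRS-T morphology as Gaussian kernels, R amplitude normalized to 1."""

    waves: tuple[WaveKernel, ...]

    @classmethod
    def maternal(cls) -> "BeatShape":
        return cls(waves=(
            WaveKernel(0.12, -180.0, 35.0),
            WaveKernel(-0.12, -25.0, 12.0),
            WaveKernel(1.00, 0.0, 14.0),
            WaveKernel(-0.20, 25.0, 12.0),
            WaveKernel(0.35, 300.0, 70.0, scales_with_rr=True),
        ))

    @classmethod
    def fetal(cls) -> "BeatShape":
        # time-compressed relative to the adult shape: narrower QRS,
        # earlier and tighter T wave
        return cls(waves=(
            WaveKernel(0.10, -100.0, 20.0),
            WaveKernel(-0.10, -14.0, 7.0),
            WaveKernel(1.00, 0.0, 8.0),
            WaveKernel(-0.18, 14.0, 7.0),
            WaveKernel(0.30, 170.0, 40.0, scales_with_rr=True),
        ))


@dataclass(frozen=True)
class HeartConfig:
    mean_hr_bpm: float
    hr_sd_bpm: float
    amplitude_uv: float
    beat_shape: BeatShape

    def __post_init__(self) -> None:
        if not (30.0 <= self.mean_hr_bpm <= 250.0):
            raise ParameterError(
                f"mean heart rate must be in [30, 250] bpm, got {self.mean_hr_bpm}"
            )
        if self.hr_sd_bpm < 0 or self.amplitude_uv < 0:
            raise ParameterError("hr_sd_bpm and amplitude_uv must be >= 0")


@dataclass(frozen=True)
class NoiseConfig:
    """Per-component RMS levels in µV."""

    baseline_uv: float = 50.0
    powerline_uv: float = 20.0
    broadband_uv: float = 10.0
    emg_uv: float = 10.0
    powerline_hz: float = 50.0

    def __post_init__(self) -> None:
        for name in ("baseline_uv", "powerline_uv", "broadband_uv", "emg_uv"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SynthConfig:
    duration_s: float = 60.0
    fs: float = 1000.0
    maternal: HeartConfig = field(
        default_factory=lambda: HeartConfig(80.0, 3.0, 500.0, BeatShape.maternal())
    )
    fetal: HeartConfig = field(
        default_factory=lambda: HeartConfig(140.0, 5.0, 20.0, BeatShape.fetal())
    )
    fetal_amplitude_direct_uv: float = 150.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    direct_noise: NoiseConfig = field(
        default_factory=lambda: NoiseConfig(30.0, 10.0, 8.0, 8.0)
    )
    n_abdominal_channels: int = 4
    channel_gains: Optional[tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ParameterError("duration_s and fs must be positive")
        if not (1 <= self.n_abdominal_channels <= 4):
            raise ParameterError("n_abdominal_channels must be in 1..4")
        if self.fetal.mean_hr_bpm <= self.maternal.mean_hr_bpm:
            raise ParameterError(
                "fetal mean heart rate must exceed the maternal one"
            )
        gains = self.channel_gains
        if gains is None:
            gains = tuple(1.0 - 0.1 * k for k in range(self.n_abdominal_channels))
            object.__setattr__(self, "channel_gains", gains)
        if len(gains) != self.n_abdominal_channels:
            raise ParameterError("channel_gains length must match n_abdominal_channels")


@dataclass
class SynthRecord:
    """A synthetic record set plus its exact ground-truth components."""

    recordset: RecordSet
    fetal_clean: dict[str, np.ndarray]
    maternal_clean: dict[str, np.ndarray]
    noise: dict[str, np.ndarray]
    fetal_rpeaks: RPeakSeries
    maternal_rpeaks: RPeakSeries
    config: SynthConfig


def _rr_sequence(
    mean_hr_bpm: float, hr_sd_bpm: float, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """AR(1) heart-rate series converted to RR intervals (s), floored at 250 ms."""
    n_max = int(np.ceil(duration_s * mean_hr_bpm / 60.0)) + 8
    phi = 0.8
    innov_sd = hr_sd_bpm * np.sqrt(1.0 - phi * phi)
    hr = np.empty(n_max)
    hr[0] = mean_hr_bpm + hr_sd_bpm * rng.standard_normal()
    for i in range(1, n_max):
        hr[i] = mean_hr_bpm + phi * (hr[i - 1] - mean_hr_bpm) + innov_sd * rng.standard_normal()
    hr = np.clip(hr, 30.0, 250.0)
    return np.maximum(60.0 / hr, 0.25)


def _render_beats(
    r_times_s: np.ndarray,
    rr_s: np.ndarray,
    shape: BeatShape,
    t: np.ndarray,
    fs: float,
    rr_nominal_s: float,
) -> np.ndarray:
    out = np.zeros_like(t)
    for r_t, rr in zip(r_times_s, rr_s):
        stretch = np.sqrt(rr / rr_nominal_s)
        for w in shape.waves:
            c = w.center_ms / 1000.0 * (stretch if w.scales_with_rr else 1.0)
            width = w.width_ms / 1000.0 * (stretch if w.scales_with_rr else 1.0)
            lo = int(max(0, np.floor((r_t + c - 7 * width) * fs)))
            hi = int(min(t.size, np.ceil((r_t + c + 7 * width) * fs)))
            if hi <= lo:
                continue
            tt = t[lo:hi] - (r_t + c)
            out[lo:hi] += w.amplitude * np.exp(-0.5 * (tt / width) ** 2)
    return out


def gen_beat_train(
    hr_bpm: float,
    hr_sd_bpm: float,
    beat_shape: BeatShape,
    duration_s: float,
    fs: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Trace, RPeakSeries]:
    """A unit-amplitude quasi-periodic beat train with ground-truth R peaks.

    R amplitude is 1; scale the samples to the desired µV level.  With
    ``hr_sd_bpm == 0`` the train is exactly periodic.
    """
    if not (30.0 <= hr_bpm <= 250.0):
        raise ParameterError(f"heart rate must be in [30, 250] bpm, got {hr_bpm}")
    if hr_sd_bpm < 0:
        raise ParameterError("hr_sd_bpm must be >= 0")
    if duration_s <= 0 or fs <= 0:
        raise ParameterError("duration_s and fs must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    rr_nominal = 60.0 / hr_bpm
    rr = _rr_sequence(hr_bpm, hr_sd_bpm, duration_s, rng)
    r_times = np.concatenate([[0.6 * rr_nominal], 0.6 * rr_nominal + np.cumsum(rr)])
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    in_range = r_times < duration_s - 0.5 * rr_nominal
    r_times = r_times[in_range]
    rr_per_beat = np.append(np.diff(r_times), rr_nominal)
    samples = _render_beats(r_times, rr_per_beat, beat_shape, t, fs, rr_nominal)
    r_idx = np.round(r_times * fs).astype(np.int64)
    r_idx = r_idx[r_idx < n]
    return (
        Trace(samples, fs, label="beat_train"),
        RPeakSeries(r_idx, fs, source="synthetic_truth"),
    )


def _scaled_to_rms(x: np.ndarray, rms_uv: float) -> np.ndarray:
    r = float(np.sqrt(np.mean(x * x)))
    if r == 0 or rms_uv == 0:
        return np.zeros_like(x)
    return x * (rms_uv / r)


def gen_noise(
    n: int, fs: float, cfg: NoiseConfig, rng: np.random.Generator
) -> np.ndarray:
    """Baseline + powerline + broadband + EMG-band noise at configured RMS."""
    t = np.arange(n) / fs
    parts = []
    if cfg.baseline_uv > 0:
        sos = sps.butter(2, 0.15, btype="lowpass", fs=fs, output="sos")
        wander = sps.sosfiltfilt(sos, rng.standard_normal(n))
        parts.append(_scaled_to_rms(wander, cfg.baseline_uv))
    if cfg.powerline_uv > 0:
        drift = np.cumsum(rng.standard_normal(n)) * 0.002
        line = np.sin(2 * np.pi * cfg.powerline_hz * t + drift)
        parts.append(_scaled_to_rms(line, cfg.powerline_uv))
    if cfg.broadband_uv > 0:
        parts.append(cfg.broadband_uv * rng.standard_normal(n))
    if cfg.emg_uv > 0:
        hi = min(45.0, 0.45 * fs)
        sos = sps.butter(3, [20.0, hi], btype="bandpass", fs=fs, output="sos")
        emg = sps.sosfiltfilt(sos, rng.standard_normal(n))
        parts.append(_scaled_to_rms(emg, cfg.emg_uv))
    if not parts:
        return np.zeros(n)
    return np.sum(parts, axis=0)


def gen_record_set(cfg: SynthConfig) -> SynthRecord:
    """Realize the additive direct + abdominal recording model.

    direct = fetal train (direct amplitude) + direct noise;
    abdominal channel k = gain_k · maternal train + fetal train
    (abdominal amplitude) + channel noise.  All truth components are
    stored exactly as summed.
    """
    rng = np.random.default_rng(cfg.seed)
    streams = rng.spawn(2 + 1 + cfg.n_abdominal_channels)
    m_rng, f_rng, d_noise_rng = streams[0], streams[1], streams[2]
    ch_noise_rngs = streams[3:]

    n = int(round(cfg.duration_s * cfg.fs))
    m_unit, m_peaks = gen_beat_train(
        cfg.maternal.mean_hr_bpm, cfg.maternal.hr_sd_bpm, cfg.maternal.beat_shape,
        cfg.duration_s, cfg.fs, rng=m_rng,
    )
    f_unit, f_peaks = gen_beat_train(
        cfg.fetal.mean_hr_bpm, cfg.fetal.hr_sd_bpm, cfg.fetal.beat_shape,
        cfg.duration_s, cfg.fs, rng=f_rng,
    )

    fetal_clean: dict[str, np.ndarray] = {}
    maternal_clean: dict[str, np.ndarray] = {}
    noise: dict[str, np.ndarray] = {}

    fetal_clean["direct"] = f_unit.samples * cfg.fetal_amplitude_direct_uv
    maternal_clean["direct"] = np.zeros(n)
    noise["direct"] = gen_noise(n, cfg.fs, cfg.direct_noise, d_noise_rng)
    direct = Trace(
        maternal_clean["direct"] + fetal_clean["direct"] + noise["direct"],
        cfg.fs, label="direct",
    )

    abdominal: list[Trace] = []
    for k in range(cfg.n_abdominal_channels):
        name = f"abd{k + 1}"
        fetal_clean[name] = f_unit.samples * cfg.fetal.amplitude_uv
        maternal_clean[name] = (
            m_unit.samples * cfg.maternal.amplitude_uv * cfg.channel_gains[k]
        )
        noise[name] = gen_noise(n, cfg.fs, cfg.noise, ch_noise_rngs[k])
        abdominal.append(Trace(
            maternal_clean[name] + fetal_clean[name] + noise[name],
            cfg.fs, label=name,
        ))

    recordset = RecordSet(
        direct=direct,
        abdominal=abdominal,
        fetal_rpeaks=f_peaks,
        metadata={"seed": str(cfg.seed), "synthetic": "true"},
    )
    return SynthRecord(
        recordset=recordset,
        fetal_clean=fetal_clean,
        maternal_clean=maternal_clean,
        noise=noise,
        fetal_rpeaks=f_peaks,
        maternal_rpeaks=m_peaks,
        config=cfg,
    )
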