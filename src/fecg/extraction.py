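"""Direct and indirect fetal-ECG extraction cascades.

Direct route: prefilter the scalp recording, then denoise with the
fetal-QRS windows — the clean output is the direct fetal ECG estimate
and the residual is its in-band noise.

Indirect route, per abdominal channel: prefilter, detect the maternal
rhythm (Pan-Tompkins; the maternal ECG dominates abdominal leads),
denoise with maternal windows to estimate and subtract the maternal
component, then denoise the remainder with the supplied fetal R peaks to
split it into the fetal estimate and residual noise.

Signal quality is reported at two points of the indirect route: after
maternal subtraction (ISNR1, noise = what the final denoising removes)
and after fetal denoising (ISNR2, noise = what a *second* denoising pass
would still remove from the fetal estimate — the measurable proxy for
the noise remaining in it).  Both use the same fetal signal amplitude,
so they differ only in the noise term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import sbmm
from .ecg_io import RecordSet
from .errors import ExtractionError
from .metrics import noise_amplitude, pearson, signal_amplitude, snr_db
from .peak_detect import pan_tompkins
from .preprocess import bandpass_prefilter
from .signal_model import (
    AbdominalDecomposition,
    DirectDecomposition,
    RPeakSeries,
    Trace,
)

__all__ = ["ExtractionConfig", "extract_direct", "extract_indirect",
           "evaluate_record", "round_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunables for both cascades; defaults follow standard practice."""

    prefilter_low_hz: float = 0.5
    prefilter_high_hz: float = 45.0
    prefilter_order: int = 4
    maternal_qrs_pre_ms: float = sbmm.DEFAULT_QRS_PRE_MS
    maternal_qrs_post_ms: float = sbmm.DEFAULT_QRS_POST_MS
    fetal_qrs_pre_ms: float = sbmm.FETAL_QRS_PRE_MS
    fetal_qrs_post_ms: float = sbmm.FETAL_QRS_POST_MS
    stat: str = "median"
    interpolation: str = "cubic"
    pt_bandpass_low_hz: float = 5.0
    pt_bandpass_high_hz: float = 15.0
    pt_integration_ms: float = 150.0
    pt_refractory_ms: float = 200.0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ExtractionConfig":
        """Build from a flat key/value mapping, ignoring unknown keys."""
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in mapping.items() if k in known})


def extract_direct(
    drec: Trace,
    fetal_rpeaks: RPeakSeries,
    cfg: ExtractionConfig = ExtractionConfig(),
) -> DirectDecomposition:
    """Prefilter + fetal denoising of a direct (scalp) recording."""
    fetal_rpeaks.validate_for(drec)
    pre = bandpass_prefilter(
        drec, cfg.prefilter_low_hz, cfg.prefilter_high_hz, cfg.prefilter_order
    )
    dfecg, dn = sbmm.sbmm_denoise(
        pre, fetal_rpeaks,
        qrs_pre_ms=cfg.fetal_qrs_pre_ms, qrs_post_ms=cfg.fetal_qrs_post_ms,
        stat=cfg.stat, interpolation=cfg.interpolation,
    )
    return DirectDecomposition(input=pre, dfecg=dfecg, dn=dn)


def extract_indirect(
    irec_channel: Trace,
    fetal_rpeaks: RPeakSeries,
    cfg: ExtractionConfig = ExtractionConfig(),
) -> AbdominalDecomposition:
    """Maternal cancellation followed by fetal denoising on one channel."""
    fetal_rpeaks.validate_for(irec_channel)
    pre = bandpass_prefilter(
        irec_channel, cfg.prefilter_low_hz, cfg.prefilter_high_hz,
        cfg.prefilter_order,
    )
    maternal_peaks = pan_tompkins(
        pre,
        bandpass_low_hz=cfg.pt_bandpass_low_hz,
        bandpass_high_hz=cfg.pt_bandpass_high_hz,
        integration_ms=cfg.pt_integration_ms,
        refractory_ms=cfg.pt_refractory_ms,
    )
    if len(maternal_peaks) < 2:
        raise ExtractionError(
            f"no maternal rhythm: found {len(maternal_peaks)} maternal R peaks"
        )
    log.info("channel %s: %d maternal R peaks", irec_channel.label, len(maternal_peaks))
    mecg, noisy = sbmm.sbmm_denoise(
        pre, maternal_peaks,
        qrs_pre_ms=cfg.maternal_qrs_pre_ms, qrs_post_ms=cfg.maternal_qrs_post_ms,
        stat=cfg.stat, interpolation=cfg.interpolation,
    )
    ifecg_noisy = pre.with_samples(noisy.samples, "ifecg_noisy")
    ifecg, in_noise = sbmm.sbmm_denoise(
        ifecg_noisy, fetal_rpeaks,
        qrs_pre_ms=cfg.fetal_qrs_pre_ms, qrs_post_ms=cfg.fetal_qrs_post_ms,
        stat=cfg.stat, interpolation=cfg.interpolation,
    )
    return AbdominalDecomposition(
        input=pre, mecg=mecg, ifecg_noisy=ifecg_noisy,
        ifecg=ifecg, in_noise=in_noise,
    )


def _residual_after_second_pass(
    ifecg: Trace, fetal_rpeaks: RPeakSeries, cfg: ExtractionConfig
) -> Trace:
    _, residual = sbmm.sbmm_denoise(
        ifecg, fetal_rpeaks,
        qrs_pre_ms=cfg.fetal_qrs_pre_ms, qrs_post_ms=cfg.fetal_qrs_post_ms,
        stat=cfg.stat, interpolation=cfg.interpolation,
    )
    return residual


def evaluate_record(
    recordset: RecordSet,
    cfg: ExtractionConfig = ExtractionConfig(),
) -> pd.DataFrame:
    """Per-channel signal-quality table for one record.

    Columns: channel, dfecg_ampl_uv, dn_ampl_uv, dsnr_db (record-level,
    repeated per row when a direct trace exists), ifecg_ampl_uv,
    in_ampl_uv, isnr1_db, isnr2_db, rho.
    """
    if recordset.fetal_rpeaks is None:
        raise ExtractionError("evaluate_record requires fetal R peaks")
    if not recordset.abdominal:
        raise ExtractionError("evaluate_record requires at least one abdominal channel")
    fpk = recordset.fetal_rpeaks

    direct_cols: dict[str, float] = {}
    dfecg_trace = None
    if recordset.direct is not None:
        d = extract_direct(recordset.direct, fpk, cfg)
        dfecg_trace = d.dfecg
        s = signal_amplitude(d.dfecg, fpk, cfg.fetal_qrs_pre_ms, cfg.fetal_qrs_post_ms)
        nz = noise_amplitude(d.dn)
        direct_cols = {
            "dfecg_ampl_uv": s,
            "dn_ampl_uv": nz,
            "dsnr_db": snr_db(s, nz),
        }
    else:
        log.warning("record has no direct trace; DSNR and rho columns omitted")

    rows = []
    for ch, trace in enumerate(recordset.abdominal, start=1):
        a = extract_indirect(trace, fpk, cfg)
        s = signal_amplitude(a.ifecg, fpk, cfg.fetal_qrs_pre_ms, cfg.fetal_qrs_post_ms)
        n1 = noise_amplitude(a.in_noise)
        n2 = noise_amplitude(_residual_after_second_pass(a.ifecg, fpk, cfg))
        row = {"channel": trace.label or f"ch{ch}", **direct_cols,
               "ifecg_ampl_uv": s, "in_ampl_uv": n1,
               "isnr1_db": snr_db(s, n1), "isnr2_db": snr_db(s, n2)}
        if dfecg_trace is not None:
            row["rho"] = pearson(dfecg_trace, a.ifecg).rho
        rows.append(row)
    return pd.DataFrame(rows)


def round_table(table: pd.DataFrame) -> pd.DataFrame:
    """Printed-table formatting: µV to integer, dB to 0.1, ρ to 0.01."""
    out = table.copy()
    for col in out.columns:
        if col.endswith("_ampl_uv"):
            out[col] = out[col].round(0).astype("Int64")
        elif col.endswith("_db"):
            out[col] = out[col].round(1)
        elif col == "rho":
            out[col] = out[col].round(2)
    return out
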