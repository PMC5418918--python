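"""Reading and writing traces, annotations and decompositions.

Two on-disk formats are supported:

* **WFDB** (PhysioNet) header/signal/annotation triples, via a minimal
  built-in implementation of the format-16 subset (16-bit little-endian
  interleaved samples, MIT annotation encoding).  This covers the layout
  used by the abdominal/direct fetal ECG database without requiring the
  external ``wfdb`` package.
* **CSV** single-column traces (assumed µV) — the plain-text interchange
  used for synthetic fixtures and pipeline outputs.

Physical conversion follows the WFDB rule ``physical = (adc − baseline) /
gain`` with gain in ADC units per millivolt; traces are held in µV.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError
from .signal_model import (
    AbdominalDecomposition,
    DirectDecomposition,
    RPeakSeries,
    Trace,
)

__all__ = [
    "RecordSet",
    "read_wfdb_record",
    "write_wfdb_record",
    "read_csv_trace",
    "write_csv_trace",
    "write_decomposition",
    "write_record_dir",
    "read_record_dir",
]


@dataclass
class RecordSet:
    """One acquisition: optional direct channel, 1–4 abdominal channels,
    optional fetal R-peak annotations."""

    direct: Optional[Trace]
    abdominal: list[Trace]
    fetal_rpeaks: Optional[RPeakSeries] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        traces = ([self.direct] if self.direct is not None else []) + list(self.abdominal)
        if not traces:
            raise FormatError("a RecordSet needs at least one trace")
        fs0, n0 = traces[0].fs, len(traces[0])
        for tr in traces[1:]:
            if tr.fs != fs0:
                raise FormatError(f"channel fs mismatch: {tr.fs} != {fs0}")
            if len(tr) != n0:
                raise FormatError(f"channel length mismatch: {len(tr)} != {n0}")
        if self.fetal_rpeaks is not None:
            self.fetal_rpeaks.validate_for(traces[0])

    @property
    def fs(self) -> float:
        return (self.direct or self.abdominal[0]).fs

    @property
    def n_samples(self) -> int:
        return len(self.direct or self.abdominal[0])


# ---------------------------------------------------------------------------
# WFDB subset: header (.hea), signal (.dat, format 16), MIT annotations
# ---------------------------------------------------------------------------

_ANN_NORMAL = 1   # beat annotation code
_ANN_SKIP = 59    # long-interval escape
_ANN_END = 0


@dataclass
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float          # ADC units per mV
    baseline: int
    units: str
    description: str


def _parse_header(path: Path) -> tuple[str, int, float, int, list[_SignalSpec]]:
    try:
        lines = [
            ln.strip() for ln in path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    except OSError as exc:
        raise FormatError(f"cannot read WFDB header {path}: {exc}") from exc
    if not lines:
        raise FormatError(f"empty WFDB header: {path}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed WFDB record line in {path}: {lines[0]!r}")
    name, n_sig = head[0], int(head[1])
    fs = float(head[2].split("/")[0])
    n_samp = int(head[3])
    specs: list[_SignalSpec] = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        if len(parts) < 2:
            raise FormatError(f"malformed signal line in {path}: {ln!r}")
        fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = parts[2] if len(parts) > 2 else "200"
        units = "mV"
        if "/" in gain_field:
            gain_field, units = gain_field.split("/", 1)
        baseline = 0
        if "(" in gain_field:
            gain_field, rest = gain_field.split("(", 1)
            baseline = int(rest.rstrip(")"))
        gain = float(gain_field) if gain_field else 200.0
        if gain == 0:
            gain = 200.0
        desc = " ".join(parts[8:]) if len(parts) > 8 else f"sig{len(specs)}"
        specs.append(_SignalSpec(parts[0], fmt, gain, baseline, units, desc))
    if len(specs) != n_sig:
        raise FormatError(f"header {path} declares {n_sig} signals, found {len(specs)}")
    return name, n_sig, fs, n_samp, specs


_UNIT_TO_UV = {"mv": 1000.0, "uv": 1.0, "µv": 1.0, "v": 1e6}


def _read_dat(path: Path, n_sig: int, n_samp: int) -> np.ndarray:
    try:
        raw = np.fromfile(path, dtype="<i2")
    except OSError as exc:
        raise FormatError(f"cannot read WFDB signal file {path}: {exc}") from exc
    if raw.size < n_sig * n_samp:
        raise FormatError(
            f"signal file {path} too short: {raw.size} values for "
            f"{n_sig}×{n_samp}"
        )
    return raw[: n_sig * n_samp].reshape(n_samp, n_sig)


def _read_annotation(path: Path) -> np.ndarray:
    try:
        data = path.read_bytes()
    except OSError as exc:
        raise FormatError(f"cannot read annotation file {path}: {exc}") from exc
    indices: list[int] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == _ANN_END and interval == 0:
            break
        if code == _ANN_SKIP:
            if i + 3 >= len(data):
                raise FormatError(f"truncated SKIP in annotation file {path}")
            hi = data[i] | (data[i + 1] << 8)
            lo = data[i + 2] | (data[i + 3] << 8)
            i += 4
            t += struct.unpack("<i", struct.pack("<I", (hi << 16) | lo))[0]
        else:
            t += interval
            indices.append(t)
    arr = np.asarray(indices, dtype=np.int64)
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise FormatError(
            f"annotation file {path}: sample indices are not strictly increasing"
        )
    return arr


def _write_annotation(path: Path, indices: np.ndarray) -> None:
    """Encode beat annotations; does not validate monotonicity."""
    out = bytearray()
    t = 0
    for idx in np.asarray(indices, dtype=np.int64):
        delta = int(idx - t)
        if 0 <= delta < 1024:
            out += struct.pack("<H", (_ANN_NORMAL << 10) | delta)
        else:
            packed = struct.unpack("<I", struct.pack("<i", delta))[0]
            out += struct.pack("<H", (_ANN_SKIP << 10) | 0)
            out += struct.pack("<H", (packed >> 16) & 0xFFFF)
            out += struct.pack("<H", packed & 0xFFFF)
            out += struct.pack("<H", (_ANN_NORMAL << 10) | 0)
        t = idx
    out += struct.pack("<H", 0)
    path.write_bytes(bytes(out))


def write_wfdb_record(
    path: Union[str, Path],
    traces: list[Trace],
    rpeaks: Optional[RPeakSeries] = None,
    annotation_extension: str = "atr",
    gain: float = 1000.0,
) -> None:
    """Write a format-16 WFDB record (header + dat, optional annotations).

    With the default gain of 1000 ADC units/mV one ADC unit equals 1 µV,
    so integer-µV traces round-trip bit-exactly.  Values are clipped to
    the int16 range.
    """
    path = Path(path)
    if not traces:
        raise FormatError("need at least one trace")
    fs = traces[0].fs
    n = len(traces[0])
    for tr in traces[1:]:
        if tr.fs != fs or len(tr) != n:
            raise FormatError("all channels must share fs and length")
    adc = np.column_stack(
        [np.round(tr.samples / 1000.0 * gain) for tr in traces]
    )
    adc = np.clip(adc, -32768, 32767).astype("<i2")
    dat_name = path.name + ".dat"
    lines = [f"{path.name} {len(traces)} {fs:g} {n}"]
    for k, tr in enumerate(traces):
        label = tr.label or f"sig{k}"
        first = int(adc[0, k])
        lines.append(
            f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} 0 0 {label}"
        )
    try:
        path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
        adc.tofile(path.parent / dat_name)
    except OSError as exc:
        raise FormatError(f"cannot write WFDB record {path}: {exc}") from exc
    if rpeaks is not None:
        _write_annotation(path.with_suffix("." + annotation_extension), rpeaks.indices)


def read_wfdb_record(
    path: Union[str, Path],
    annotation_extension: Optional[str] = None,
) -> RecordSet:
    """Load a WFDB record (and optional beat annotations) as a RecordSet.

    All channels are converted to µV.  A channel whose description
    contains "direct" (case-insensitive) is taken as the direct (scalp)
    channel; all others are abdominal.  Annotation sample indices become
    ``fetal_rpeaks`` with ``source="reference"``.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing WFDB header file: {hea}")
    _, n_sig, fs, n_samp, specs = _parse_header(hea)
    dat = path.parent / specs[0].file_name
    if not dat.exists():
        raise FormatError(f"missing WFDB signal file: {dat}")
    adc = _read_dat(dat, n_sig, n_samp)

    direct = None
    abdominal: list[Trace] = []
    for k, spec in enumerate(specs):
        scale = _UNIT_TO_UV.get(spec.units.lower(), 1000.0)
        uv = (adc[:, k].astype(np.float64) - spec.baseline) / spec.gain * scale
        tr = Trace(uv, fs, label=spec.description)
        if "direct" in spec.description.lower() and direct is None:
            direct = tr
        else:
            abdominal.append(tr)

    rpeaks = None
    if annotation_extension:
        ann = path.with_suffix("." + annotation_extension)
        if not ann.exists():
            raise FormatError(f"missing annotation file: {ann}")
        idx = _read_annotation(ann)
        if idx.size and idx[-1] >= n_samp:
            raise FormatError(
                f"annotation index {idx[-1]} outside record of {n_samp} samples"
            )
        rpeaks = RPeakSeries(idx, fs, source="reference")
    return RecordSet(
        direct=direct,
        abdominal=abdominal,
        fetal_rpeaks=rpeaks,
        metadata={"record": path.name, "n_sig": str(n_sig)},
    )


# ---------------------------------------------------------------------------
# CSV traces
# ---------------------------------------------------------------------------

def write_csv_trace(trace: Trace, path: Union[str, Path]) -> None:
    """One-column CSV with a header row; 12 significant digits (µV)."""
    df = pd.DataFrame({trace.label or "uv": trace.samples})
    df.to_csv(path, index=False, float_format="%.12g")


def read_csv_trace(
    path: Union[str, Path],
    fs: float,
    column: Union[str, int] = 0,
) -> Trace:
    """Read one numeric CSV column as a trace in µV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, OSError) as exc:
        raise ParseError(f"cannot parse CSV {path}: {exc}") from exc
    if df.shape[0] == 0:
        raise ParseError(f"CSV {path} contains no data rows")
    try:
        col = df[column] if isinstance(column, str) else df.iloc[:, column]
    except (KeyError, IndexError) as exc:
        raise ParseError(f"CSV {path} has no column {column!r}") from exc
    values = pd.to_numeric(col, errors="coerce")
    bad = values.index[values.isna() & col.notna()]
    if len(bad):
        raise ParseError(
            f"CSV {path}: non-numeric value {col[bad[0]]!r} at data row {bad[0]}"
        )
    if values.isna().any():
        row = int(values.index[values.isna()][0])
        raise ParseError(f"CSV {path}: missing value at data row {row}")
    label = column if isinstance(column, str) else str(df.columns[column])
    return Trace(values.to_numpy(dtype=np.float64), fs, label=label)


# ---------------------------------------------------------------------------
# CSV record directories (the plain-text record layout used by the CLI)
# ---------------------------------------------------------------------------

def write_record_dir(recordset: RecordSet, path: Union[str, Path]) -> Path:
    """Write a record set as one CSV per channel plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    channels = []
    if recordset.direct is not None:
        write_csv_trace(
            recordset.direct.with_samples(recordset.direct.samples, "direct"),
            path / "direct.csv",
        )
        channels.append("direct")
    for k, tr in enumerate(recordset.abdominal, start=1):
        name = f"abd{k}"
        write_csv_trace(tr.with_samples(tr.samples, name), path / f"{name}.csv")
        channels.append(name)
    if recordset.fetal_rpeaks is not None:
        pd.DataFrame({"index": recordset.fetal_rpeaks.indices}).to_csv(
            path / "fetal_rpeaks.csv", index=False
        )
    manifest = {
        "fs": recordset.fs,
        "n_samples": recordset.n_samples,
        "channels": channels,
        "has_fetal_rpeaks": recordset.fetal_rpeaks is not None,
        "metadata": recordset.metadata,
    }
    (path / "record.json").write_text(json.dumps(manifest, indent=2))
    return path


def read_record_dir(path: Union[str, Path]) -> RecordSet:
    """Load a record directory written by :func:`write_record_dir`."""
    path = Path(path)
    manifest_path = path / "record.json"
    if not manifest_path.exists():
        raise FormatError(f"missing record manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    fs = float(manifest["fs"])
    direct = None
    abdominal: list[Trace] = []
    for name in manifest["channels"]:
        tr = read_csv_trace(path / f"{name}.csv", fs)
        if name == "direct":
            direct = tr
        else:
            abdominal.append(tr)
    rpeaks = None
    if manifest.get("has_fetal_rpeaks"):
        df = pd.read_csv(path / "fetal_rpeaks.csv")
        rpeaks = RPeakSeries(
            df["index"].to_numpy(dtype=np.int64), fs, source="reference"
        )
    return RecordSet(
        direct=direct,
        abdominal=abdominal,
        fetal_rpeaks=rpeaks,
        metadata=dict(manifest.get("metadata", {})),
    )


# ---------------------------------------------------------------------------
# Decomposition output
# ---------------------------------------------------------------------------

def write_decomposition(
    decomp: Union[DirectDecomposition, AbdominalDecomposition],
    path: Union[str, Path],
) -> Path:
    """Write one CSV per component plus a JSON sidecar; returns the sidecar path."""
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FormatError(f"cannot create output directory {path}: {exc}") from exc
    if isinstance(decomp, DirectDecomposition):
        components = {"input": decomp.input, "dfecg": decomp.dfecg, "dn": decomp.dn}
    else:
        components = {
            "input": decomp.input,
            "mecg": decomp.mecg,
            "ifecg_noisy": decomp.ifecg_noisy,
            "ifecg": decomp.ifecg,
            "in_noise": decomp.in_noise,
        }
    for name, tr in components.items():
        write_csv_trace(tr.with_samples(tr.samples, label=name), path / f"{name}.csv")
    sidecar = {
        "fs": decomp.input.fs,
        "components": {name: len(tr) for name, tr in components.items()},
        "conserved": bool(decomp.max_abs_deviation <= 1e-6),
        "max_abs_deviation_uv": decomp.max_abs_deviation,
        "kind": type(decomp).__name__,
    }
    out = path / "decomposition.json"
    out.write_text(json.dumps(sidecar, indent=2))
    return out
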