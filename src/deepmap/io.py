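"""Readers and writers for the interchange formats.

A recording lives in a directory holding ``header.json`` (sampling rate,
channel names and roles, electrode coordinates) plus the samples in one
of two dialects:

* ``signals.csv`` — one column per channel, full-precision text floats;
  round-trips float64 samples bit-exactly;
* ``record.hea`` / ``record.dat`` — a minimal WFDB-compatible record
  (format 16: 16-bit little-endian integers with per-channel gain).
  WFDB storage quantizes to ADC units, so a round-trip is bit-exact from
  the first read-back onward (write-read is idempotent), not for
  arbitrary float input.

Annotation files are CSV with columns channel, train, time_ms, label,
deep_value_ms; a row with label "none" registers a scored unit without a
mark.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Recording
from .metrics import Annotation, AnnotationSet

__all__ = [
    "write_recording", "read_recording",
    "write_annotations", "read_annotations",
    "RecordingFormatError",
]

_WFDB_GAIN = 1000.0  # ADC units per mV => 1 uV resolution, +/-32.7 mV range


class RecordingFormatError(ValueError):
    """Malformed recording directory; the message names the offending field."""


def _header_dict(recording: Recording, dialect: str) -> dict:
    return {
        "sampling_rate": recording.sampling_rate,
        "surface_channels": list(recording.surface_channels),
        "bipolar_channels": list(recording.bipolar_channels),
        "electrode_positions": {
            name: [float(c) for c in pos]
            for name, pos in recording.electrode_positions.items()
        },
        "dialect": dialect,
    }


def write_recording(recording: Recording, path: str | Path,
                    dialect: str = "csv") -> Path:
    """Write a recording directory in the chosen dialect ("csv" or "wfdb")."""
    if dialect not in ("csv", "wfdb"):
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'wfdb'")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    (out / "header.json").write_text(
        json.dumps(_header_dict(recording, dialect), indent=1) + "\n")

    names = recording.channel_names
    signals = {**recording.surface_channels, **recording.bipolar_channels}
    if dialect == "csv":
        with open(out / "signals.csv", "w") as fh:
            fh.write(",".join(names) + "\n")
            cols = [signals[n] for n in names]
            for row in zip(*cols):
                fh.write(",".join(format(x, ".17g") for x in row) + "\n")
    else:
        _write_wfdb(out, names, signals, recording.sampling_rate)
    return out


def _write_wfdb(out: Path, names: list[str],
                signals: dict[str, np.ndarray], fs: float) -> None:
    n_samples = len(next(iter(signals.values())))
    digital = np.column_stack([
        np.clip(np.round(signals[n] * _WFDB_GAIN), -32768, 32767)
        for n in names
    ]).astype("<i2")
    with open(out / "record.hea", "w") as fh:
        fh.write(f"record {len(names)} {fs:g} {n_samples}\n")
        for i, name in enumerate(names):
            first = int(digital[0, i]) if n_samples else 0
            checksum = int(np.sum(digital[:, i], dtype=np.int64) % 65536)
            fh.write(f"record.dat 16 {_WFDB_GAIN:g}(0)/mV 16 0 "
                     f"{first} {checksum} 0 {name}\n")
    digital.tofile(out / "record.dat")


def _read_wfdb(path: Path) -> tuple[float, list[str], dict[str, np.ndarray]]:
    hea = path / "record.hea"
    if not hea.exists():
        raise RecordingFormatError("record.hea not found")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    parts = lines[0].split()
    n_sig, fs, n_samples = int(parts[1]), float(parts[2]), int(parts[3])
    names: list[str] = []
    gains: list[float] = []
    for ln in lines[1:1 + n_sig]:
        cols = ln.split()
        if cols[1] != "16":
            raise RecordingFormatError(f"unsupported WFDB format {cols[1]!r}")
        gains.append(float(cols[2].split("(")[0]))
        names.append(cols[-1])
    digital = np.fromfile(path / "record.dat", dtype="<i2")
    if digital.size != n_sig * n_samples:
        raise RecordingFormatError(
            f"record.dat holds {digital.size} samples, header promises "
            f"{n_sig * n_samples}")
    digital = digital.reshape(n_samples, n_sig)
    sigs = {name: digital[:, i].astype(float) / gains[i]
            for i, name in enumerate(names)}
    return fs, names, sigs


def read_recording(path: str | Path) -> Recording:
    """Read a recording directory (either dialect, auto-detected)."""
    p = Path(path)
    header_path = p / "header.json"
    if not header_path.exists():
        raise RecordingFormatError("header.json not found")
    header = json.loads(header_path.read_text())
    for key in ("sampling_rate", "surface_channels", "bipolar_channels",
                "electrode_positions"):
        if key not in header:
            raise RecordingFormatError(f"header.json is missing {key!r}")

    if (p / "signals.csv").exists():
        df = pd.read_csv(p / "signals.csv", dtype=float,
                         float_precision="round_trip")
        sigs = {name: df[name].to_numpy() for name in df.columns}
    elif (p / "record.hea").exists():
        _, _, sigs = _read_wfdb(p)
    else:
        raise RecordingFormatError("no signals.csv or record.hea in directory")

    lengths = {len(s) for s in sigs.values()}
    if len(lengths) > 1:
        raise RecordingFormatError(f"channel lengths differ: {sorted(lengths)}")
    missing = [n for n in header["surface_channels"]
               + header["bipolar_channels"] if n not in sigs]
    if missing:
        raise RecordingFormatError(f"channels in header but not in data: "
                                   f"{missing}")
    return Recording(
        sampling_rate=float(header["sampling_rate"]),
        surface_channels={n: sigs[n] for n in header["surface_channels"]},
        bipolar_channels={n: sigs[n] for n in header["bipolar_channels"]},
        electrode_positions={
            n: np.asarray(xyz, dtype=float)
            for n, xyz in header["electrode_positions"].items()
        },
    )


# ---------------------------------------------------------------------------
# annotation CSV

def write_annotations(annotations: AnnotationSet, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for unit in annotations.units:
        channel, train = unit
        if annotations.has_mark(unit):
            m = annotations.marks[unit]
            rows.append((channel, train, m.time_ms, "deep", m.deep_value_ms))
        else:
            rows.append((channel, train, "", "none", ""))
    with open(path, "w") as fh:
        fh.write("channel,train,time_ms,label,deep_value_ms\n")
        for ch, tr, t, lab, dv in rows:
            t_s = "" if t in ("", None) else format(t, ".17g")
            dv_s = "" if dv in ("", None) else format(dv, ".17g")
            fh.write(f"{ch},{tr},{t_s},{lab},{dv_s}\n")
    return path


def read_annotations(path: str | Path) -> AnnotationSet:
    df = pd.read_csv(path, dtype={"channel": str, "label": str})
    out = AnnotationSet()
    for _, row in df.iterrows():
        unit = (str(row["channel"]), int(row.get("train", 0)))
        if str(row["label"]).lower() == "deep":
            out.add(Annotation(
                unit=unit,
                time_ms=None if pd.isna(row["time_ms"])
                else float(row["time_ms"]),
                deep_value_ms=None if pd.isna(row["deep_value_ms"])
                else float(row["deep_value_ms"]),
            ))
        else:
            out.add_unit(unit)
    return out
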