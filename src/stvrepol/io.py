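"""Waveform and annotation I/O.

The interchange waveform format is CSV: a comment header line carrying the
sampling rate and units (``# fs=1000 units=mV``), a label row, then one
column per channel.  Annotations (beat times and labels) travel as CSV with
``beat_time_ms,label`` columns; ground truth additionally as JSON.
Amplitudes are normalized to mV on read.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .records import GroundTruth, SignalRecord
from .sensing import SenseSeries, senses_from_annotations

__all__ = [
    "read_waveform",
    "write_waveform_csv",
    "write_ground_truth",
    "read_ground_truth",
    "read_annotations",
    "write_sense_series",
]

_UNIT_SCALE_TO_MV = {"mv": 1.0, "uv": 1e-3, "µv": 1e-3, "v": 1e3}


def write_waveform_csv(record: SignalRecord, path) -> None:
    """Write a record as CSV with a ``# fs=... units=...`` comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g} units={record.units}\n")
        fh.write(",".join(record.channel_labels) + "\n")
        np.savetxt(fh, record.samples.T, delimiter=",", fmt="%.6f")


def read_waveform(path, format: str | None = None) -> SignalRecord:
    """Read a waveform file into a :class:`SignalRecord` (amplitudes in mV).

    Only ``csv`` is supported; the format is inferred from the extension
    when not given.  The CSV must carry the sampling rate in its comment
    header — a file without one cannot be interpreted as a waveform.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt != "csv":
        raise FormatError(
            f"unsupported waveform format {fmt!r}; supported formats: csv"
        )
    with open(path) as fh:
        header = fh.readline().strip()
        m = re.match(r"#\s*fs=([\d.eE+-]+)(?:\s+units=(\S+))?", header)
        if not m:
            raise FormatError(
                f"{path}: first line must be '# fs=<Hz> [units=<u>]', got "
                f"{header!r}"
            )
        fs = float(m.group(1))
        units = (m.group(2) or "mV")
        df = pd.read_csv(fh)
    scale = _UNIT_SCALE_TO_MV.get(units.lower())
    if scale is None:
        raise FormatError(f"{path}: unknown units {units!r}")
    samples = df.to_numpy(dtype=float).T * scale
    if samples.size == 0:
        raise FormatError(f"{path}: no samples")
    return SignalRecord(samples=samples, fs=fs,
                        channel_labels=[str(c) for c in df.columns])


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Ground truth as JSON (``.json``) or a CSV annotation table."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "sense_time_ms": truth.sense_time.tolist(),
            "label": list(truth.label),
            "qrs_onset_ms": truth.qrs_onset.tolist(),
            "r_peak_ms": truth.r_peak.tolist(),
            "t_end_ms": truth.t_end.tolist(),
            "true_repol_interval_ms": truth.true_repol_interval.tolist(),
            "rr_prev_ms": truth.rr_prev.tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        truth.to_frame().to_csv(path, index=False)


def read_ground_truth(path) -> GroundTruth:
    path = Path(path)
    if path.suffix.lower() == ".json":
        d = json.loads(path.read_text())
        return GroundTruth(
            sense_time=d["sense_time_ms"],
            label=d["label"],
            qrs_onset=d["qrs_onset_ms"],
            r_peak=d["r_peak_ms"],
            t_end=d["t_end_ms"],
            true_repol_interval=d["true_repol_interval_ms"],
            rr_prev=d["rr_prev_ms"],
        )
    df = pd.read_csv(path)
    return GroundTruth(
        sense_time=df["sense_time_ms"].to_numpy(),
        label=df["label"].tolist(),
        qrs_onset=df["qrs_onset_ms"].to_numpy(),
        r_peak=df["r_peak_ms"].to_numpy(),
        t_end=df["t_end_ms"].to_numpy(),
        true_repol_interval=df["true_repol_interval_ms"].to_numpy(),
        rr_prev=df["rr_prev_ms"].to_numpy(),
    )


def read_annotations(path) -> tuple[SenseSeries, list[str]]:
    """Beat annotations from CSV with ``beat_time_ms`` and optional
    ``label`` columns; returns the senses and per-beat labels."""
    df = pd.read_csv(path)
    if "beat_time_ms" not in df.columns:
        raise FormatError(f"{path}: annotation CSV needs a beat_time_ms column")
    labels = (df["label"].tolist() if "label" in df.columns
              else ["normal"] * len(df))
    return senses_from_annotations(df["beat_time_ms"].to_numpy()), labels


def write_sense_series(senses: SenseSeries, path, labels=None) -> None:
    df = pd.DataFrame({"beat_time_ms": senses.times})
    if labels is not None:
        df["label"] = labels
    df.to_csv(path, index=False)
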