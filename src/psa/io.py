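"""Reading and writing multichannel recordings.

Two on-disk formats:

* CSV + JSON sidecar — the package's plain-text dialect for synthetic
  fixtures: a header row of channel labels, one sample per row, and a
  ``<path>.json`` sidecar holding ``fs``, ``channel_labels`` and
  ``modality``.
* EDF — the standard biosignal container for real recordings. Reading
  goes through mne; writing uses a minimal 16-bit EDF encoder (one data
  record spanning the whole recording) so round-trips can be verified
  against an independent reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError
from .signals import EOG_CHANNELS, MultichannelRecording


def _infer_modality(label: str) -> str:
    lab = label.upper()
    if lab in {c.upper() for c in EOG_CHANNELS} or "EOG" in lab:
        return "EOG"
    return "EEG"


# ---------------------------------------------------------------- CSV

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_csv(recording: MultichannelRecording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(recording.samples, columns=list(recording.channel_labels))
    df.to_csv(path, index=False, float_format="%.8g")
    meta = {
        "fs": recording.fs,
        "channel_labels": list(recording.channel_labels),
        "modality": list(recording.modality),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_csv(path: str | Path) -> MultichannelRecording:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"malformed sidecar {sidecar}: {e}") from e
    if "fs" not in meta:
        raise FormatError(f"sidecar {sidecar} missing required field 'fs'")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise FormatError(f"malformed CSV {path}: {e}") from e
    labels = meta.get("channel_labels", list(df.columns))
    if list(df.columns) != list(labels):
        raise FormatError(
            f"CSV header {list(df.columns)} does not match sidecar labels {labels}"
        )
    modality = meta.get("modality") or [_infer_modality(c) for c in labels]
    return MultichannelRecording(
        df.to_numpy(dtype=float), float(meta["fs"]), tuple(labels), tuple(modality)
    )


# ---------------------------------------------------------------- EDF

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: MultichannelRecording, path: str | Path) -> Path:
    """Minimal EDF encoder: one data record, 16-bit samples, µV units."""
    path = Path(path)
    data = recording.samples
    n_samples, n_ch = data.shape
    duration = n_samples / recording.fs
    if duration <= 0 or len(f"{duration:.6g}") > 8:
        raise InvalidParameterError(f"record duration {duration} not encodable")

    pmin = data.min(axis=0)
    pmax = data.max(axis=0)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin) * gain + dmin).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad("1", 8),
            _pad(f"{duration:.6g}", 8),
            _pad(str(n_ch), 4),
        ]
    )
    fields = [
        [_pad(lab, 16) for lab in recording.channel_labels],
        [_pad("", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{v:.6g}", 8) for v in pmin],
        [_pad(f"{v:.6g}", 8) for v in pmax],
        [_pad(str(dmin), 8)] * n_ch,
        [_pad(str(dmax), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(n_samples), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as f:
        f.write(header)
        for block in fields:
            f.write(b"".join(block))
        # one record: all samples of signal 0, then signal 1, ...
        f.write(np.ascontiguousarray(digital.T).tobytes())
    return path


def read_edf(path: str | Path) -> MultichannelRecording:
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as e:  # mne raises several types for malformed files
        raise FormatError(f"cannot read EDF {path}: {e}") from e
    data = raw.get_data().T * 1e6  # mne loads in volts; package units are µV
    labels = tuple(raw.ch_names)
    modality = tuple(_infer_modality(c) for c in labels)
    return MultichannelRecording(data, float(raw.info["sfreq"]), labels, modality)


# ---------------------------------------------------------------- dispatch

def read_recording(path: str | Path, format: str | None = None) -> MultichannelRecording:
    """Read a recording; format inferred from the suffix when omitted."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return read_csv(path)
    if fmt == "edf":
        return read_edf(path)
    raise FormatError(f"unknown recording format {fmt!r} for {path}")


def write_recording(
    recording: MultichannelRecording, path: str | Path, format: str | None = None
) -> Path:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return write_csv(recording, path)
    if fmt == "edf":
        return write_edf(recording, path)
    raise FormatError(f"unknown recording format {fmt!r} for {path}")
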