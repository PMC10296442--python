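"""EDF (European Data Format) reading and writing for EEG recordings.

A self-contained implementation of the classic EDF layout (ASCII headers,
16-bit little-endian samples, 1-second data records). Samples are scaled
at 0.1 microvolt per digital unit (physical range +/- 3276.8 uV), so a
write/read round trip is exact to within half a quantization step. The
acquisition passband is carried in the per-signal prefiltering field.
"""

from __future__ import annotations

import datetime as _dt
import re
from pathlib import Path

import numpy as np

from .recording import EEGRecording

_PHYS_MAX = 3276.7
_PHYS_MIN = -3276.8
_DIG_MAX = 32767
_DIG_MIN = -32768
_SCALE = (_PHYS_MAX - _PHYS_MIN) / (_DIG_MAX - _DIG_MIN)  # 0.1 uV / bit


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b.ljust(width)


def write_edf(rec: EEGRecording, path: str | Path,
              patient_id: str = "X", recording_id: str = "synthetic",
              start: _dt.datetime | None = None) -> None:
    """Write a recording as EDF with 1-second data records.

    The recording length must be a whole number of seconds (the generators
    produce whole-second epochs); samples outside +/- 3276.8 uV are clipped.
    """
    if rec.fs != int(rec.fs):
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(rec.fs)
    if rec.n_samples % fs != 0:
        raise ValueError("recording length must be a whole number of seconds")
    n_records = rec.n_samples // fs
    ns = rec.n_channels
    start = start or _dt.datetime(2000, 1, 1)
    prefilter = f"HP:{rec.band[0]:g}Hz LP:{rec.band[1]:g}Hz"

    header = b"".join([
        _fixed("0", 8),
        _fixed(patient_id, 80),
        _fixed(recording_id, 80),
        _fixed(start.strftime("%d.%m.%y"), 8),
        _fixed(start.strftime("%H.%M.%S"), 8),
        _fixed(str(256 * (ns + 1)), 8),
        _fixed("", 44),
        _fixed(str(n_records), 8),
        _fixed("1", 8),
        _fixed(str(ns), 4),
    ])
    sig = b"".join([
        b"".join(_fixed(f"EEG {ch}", 16) for ch in rec.channel_names),
        b"".join(_fixed("AgAgCl electrode", 80) for _ in range(ns)),
        b"".join(_fixed("uV", 8) for _ in range(ns)),
        b"".join(_fixed(f"{_PHYS_MIN:g}", 8) for _ in range(ns)),
        b"".join(_fixed(f"{_PHYS_MAX:g}", 8) for _ in range(ns)),
        b"".join(_fixed(str(_DIG_MIN), 8) for _ in range(ns)),
        b"".join(_fixed(str(_DIG_MAX), 8) for _ in range(ns)),
        b"".join(_fixed(prefilter, 80) for _ in range(ns)),
        b"".join(_fixed(str(fs), 8) for _ in range(ns)),
        b"".join(_fixed("", 32) for _ in range(ns)),
    ])
    dig = np.clip(np.round(rec.data / _SCALE), _DIG_MIN, _DIG_MAX).astype("<i2")
    # records: per second, channels sequential
    dig = dig.reshape(ns, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(dig.tobytes())


class EDFParseError(ValueError):
    """Malformed or truncated EDF file; carries the byte offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at byte offset {offset})")
        self.offset = offset


def _read_field(buf: bytes, pos: int, width: int) -> tuple[str, int]:
    if pos + width > len(buf):
        raise EDFParseError("unexpected end of header", pos)
    return buf[pos:pos + width].decode("ascii", "replace").strip(), pos + width


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolts).

    Validates the advertised record count against the file size and raises
    :class:`EDFParseError` on truncation rather than silently shortening
    the data. The passband is recovered from the prefiltering field when
    present.
    """
    raw = Path(path).read_bytes()
    pos = 0
    _, pos = _read_field(raw, pos, 8)        # version
    _, pos = _read_field(raw, pos, 80)       # patient
    _, pos = _read_field(raw, pos, 80)       # recording
    _, pos = _read_field(raw, pos, 8)        # date
    _, pos = _read_field(raw, pos, 8)        # time
    hdr_bytes, pos = _read_field(raw, pos, 8)
    _, pos = _read_field(raw, pos, 44)
    n_records_s, pos = _read_field(raw, pos, 8)
    record_dur_s, pos = _read_field(raw, pos, 8)
    ns_s, pos = _read_field(raw, pos, 4)
    try:
        n_records = int(n_records_s)
        record_dur = float(record_dur_s)
        ns = int(ns_s)
    except ValueError as e:
        raise EDFParseError(f"non-numeric header field: {e}", pos) from None
    if ns < 1:
        raise EDFParseError("no signals", pos)

    def per_signal(width: int) -> list[str]:
        nonlocal pos
        vals = []
        for _ in range(ns):
            v, pos = _read_field(raw, pos, width)
            vals.append(v)
        return vals

    labels = per_signal(16)
    per_signal(80)                           # transducer
    per_signal(8)                            # dimension
    phys_min = [float(v) for v in per_signal(8)]
    phys_max = [float(v) for v in per_signal(8)]
    dig_min = [int(v) for v in per_signal(8)]
    dig_max = [int(v) for v in per_signal(8)]
    prefilter = per_signal(80)
    n_samp = [int(v) for v in per_signal(8)]
    per_signal(32)                           # reserved

    if len(set(n_samp)) != 1:
        raise EDFParseError("heterogeneous per-record sample counts unsupported", pos)
    spr = n_samp[0]
    record_bytes = 2 * spr * ns
    expected = pos + n_records * record_bytes
    if len(raw) < expected:
        raise EDFParseError(
            f"truncated data: expected {expected} bytes, file has {len(raw)}",
            len(raw))
    data = np.frombuffer(raw[pos:expected], dtype="<i2")
    data = data.reshape(n_records, ns, spr).transpose(1, 0, 2).reshape(ns, -1)
    data = data.astype(np.float64)
    for c in range(ns):
        gain = (phys_max[c] - phys_min[c]) / (dig_max[c] - dig_min[c])
        data[c] = (data[c] - dig_min[c]) * gain + phys_min[c]

    names = tuple(re.sub(r"^EEG\s+", "", lab) for lab in labels)
    band = (2.0, 30.0)
    m = re.search(r"HP:([\d.]+)Hz LP:([\d.]+)Hz", prefilter[0])
    if m:
        band = (float(m.group(1)), float(m.group(2)))
    fs = spr / record_dur
    return EEGRecording(names, fs, data, band)
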