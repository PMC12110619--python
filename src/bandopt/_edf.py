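"""Minimal EDF/BDF writer.

Covers plain continuous multi-channel export only: one data record holding the
whole signal, physical dimension µV, symmetric per-channel physical range.
Reading is done elsewhere through MNE, which also serves as the independent
check on this writer in the test suite.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _num8(value: float) -> str:
    """Format a number into at most 8 ASCII characters."""
    for fmt in (".8g", ".6g", ".4g", ".2g"):
        s = format(float(value), fmt)
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot fit {value} in 8 chars")


def write_edf(path: str | Path, data: np.ndarray, fs: float,
              labels: list[str], bits: int = 16) -> None:
    """Write ``data`` (channels × samples, volts) as EDF (16-bit) or BDF (24-bit)."""
    if bits not in (16, 24):
        raise ValueError("bits must be 16 (EDF) or 24 (BDF)")
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    data_uv = data * 1e6
    dig_max = 32767 if bits == 16 else 8388607
    dig_min = -dig_max

    # symmetric physical range per channel, padded so the 8-char header fields
    # round outward rather than clipping samples
    phys_max = np.maximum(np.abs(data_uv).max(axis=1), 1e-6) * 1.001
    phys_max = np.array([float(_num8(v)) for v in phys_max])
    phys_max = np.where(phys_max <= np.abs(data_uv).max(axis=1), phys_max * 1.01,
                        phys_max)
    phys_min = -phys_max

    header_bytes = 256 + 256 * n_ch
    record_duration = n_samp / fs

    head = b""
    if bits == 16:
        head += _field("0", 8)
    else:
        head += b"\xff" + "BIOSEMI".encode("ascii")
    head += _field("X X X X", 80)            # patient id
    head += _field("Startdate X X X X", 80)  # recording id
    head += _field("01.01.00", 8)
    head += _field("00.00.00", 8)
    head += _field(str(header_bytes), 8)
    head += _field("24BIT" if bits == 24 else "", 44)
    head += _field("1", 8)                   # one data record
    head += _field(_num8(record_duration), 8)
    head += _field(str(n_ch), 4)

    head += b"".join(_field(lab, 16) for lab in labels)
    head += b"".join(_field("", 80) for _ in labels)          # transducer
    head += b"".join(_field("uV", 8) for _ in labels)
    head += b"".join(_field(_num8(v), 8) for v in phys_min)
    head += b"".join(_field(_num8(v), 8) for v in phys_max)
    head += b"".join(_field(str(dig_min), 8) for _ in labels)
    head += b"".join(_field(str(dig_max), 8) for _ in labels)
    head += b"".join(_field("", 80) for _ in labels)          # prefiltering
    head += b"".join(_field(str(n_samp), 8) for _ in labels)
    head += b"".join(_field("", 32) for _ in labels)
    assert len(head) == header_bytes

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data_uv - phys_min[:, None]) / gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype(np.int32)

    with open(path, "wb") as fh:
        fh.write(head)
        if bits == 16:
            fh.write(digital.astype("<i2").tobytes())
        else:
            raw = digital.astype("<i4").tobytes()
            fh.write(np.frombuffer(raw, dtype=np.uint8).reshape(-1, 4)[:, :3].tobytes())
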