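"""Minimal EDF / BioSemi BDF continuous-recording I/O.

Supports the subset of the European Data Format needed here: continuous
multi-channel recordings with identical sampling rate across signals.
EDF stores 16-bit little-endian samples, BDF (BioSemi) 24-bit. Events are
taken from a ``Status`` channel (onsets of non-zero runs) or from a
sidecar CSV with columns ``label,sample``.

Written from the published format description; no third-party reader is
available in this environment.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from ._montage import Montage
from .prep import ContinuousRecording

__all__ = ["read_recording", "write_recording"]

_HDR_FIX = 256  # fixed part of the header, bytes
_HDR_SIG = 256  # per-signal part, bytes


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_recording(
    path: str | Path,
    rec: ContinuousRecording,
    fmt: str = "EDF",
    events_csv: str | Path | None = None,
) -> Path:
    """Write a ContinuousRecording as EDF (16-bit) or BDF (24-bit).

    Physical units are microvolts; the physical range is chosen
    symmetrically around zero from the data. Events go to ``events_csv``
    (defaults to ``<path>.events.csv``).
    """
    fmt = fmt.upper()
    if fmt not in ("EDF", "BDF"):
        raise ValueError("fmt must be 'EDF' or 'BDF'")
    path = Path(path)
    n_sig, n_samp = rec.data.shape
    phys_max = float(np.max(np.abs(rec.data)))
    phys_max = phys_max if phys_max > 0 else 1.0
    dig_max = 32767 if fmt == "EDF" else 8388607
    dig_min = -dig_max

    hdr = bytearray()
    if fmt == "EDF":
        hdr += _ascii("0", 8)
    else:
        hdr += b"\xff" + _ascii("BIOSEMI", 7)
    hdr += _ascii("X", 80)                       # patient id
    hdr += _ascii("X", 80)                       # recording id
    hdr += _ascii("01.01.20", 8)                 # start date
    hdr += _ascii("00.00.00", 8)                 # start time
    hdr += _ascii(_HDR_FIX + n_sig * _HDR_SIG, 8)
    hdr += _ascii("24BIT" if fmt == "BDF" else "", 44)
    hdr += _ascii(1, 8)                          # one data record
    hdr += _ascii(n_samp / rec.fs, 8)            # record duration, s
    hdr += _ascii(n_sig, 4)

    for lab in rec.labels:
        hdr += _ascii(lab, 16)
    hdr += _ascii("", 80) * n_sig                # transducer
    hdr += _ascii("uV", 8) * n_sig
    hdr += _ascii(f"{-phys_max:.8g}"[:8], 8) * n_sig
    hdr += _ascii(f"{phys_max:.8g}"[:8], 8) * n_sig
    hdr += _ascii(dig_min, 8) * n_sig
    hdr += _ascii(dig_max, 8) * n_sig
    hdr += _ascii("", 80) * n_sig                # prefiltering
    hdr += _ascii(n_samp, 8) * n_sig
    hdr += _ascii("", 32) * n_sig

    scale = dig_max / phys_max
    digital = np.round(rec.data * scale).astype(np.int32)
    digital = np.clip(digital, dig_min, dig_max)
    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        if fmt == "EDF":
            fh.write(digital.astype("<i2").tobytes())
        else:
            le32 = digital.astype("<i4").tobytes()
            arr = np.frombuffer(le32, dtype=np.uint8).reshape(-1, 4)
            fh.write(arr[:, :3].tobytes())       # low 3 bytes = 24-bit LE

    if rec.events:
        ev_path = Path(events_csv) if events_csv else path.with_suffix(
            path.suffix + ".events.csv"
        )
        with open(ev_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "sample"])
            for lab, idx in rec.events:
                w.writerow([lab, idx])
    return path


def _read_events_csv(path: Path) -> tuple[tuple[str, int], ...]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return tuple((r["label"], int(r["sample"])) for r in rows)


def _status_events(status: np.ndarray) -> tuple[tuple[str, int], ...]:
    """Onsets of non-zero runs in a trigger channel."""
    vals = np.round(status).astype(int)
    onsets = np.flatnonzero((vals != 0) & (np.r_[0, vals[:-1]] == 0))
    return tuple((str(vals[i]), int(i)) for i in onsets)


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    events_csv: str | Path | None = None,
    montage: Montage | None = None,
) -> ContinuousRecording:
    """Read a continuous EDF or BDF file into microvolt channels.

    ``fmt`` is inferred from the header when omitted. Events come from a
    sidecar CSV if given (or found next to the file), else from a
    ``Status`` channel if present.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HDR_FIX:
        raise ValueError(f"malformed header: file ends at byte {len(raw)}")
    if raw[0] == 0xFF and raw[1:8].strip() == b"BIOSEMI":
        detected = "BDF"
    elif raw[0:8].strip() == b"0":
        detected = "EDF"
    else:
        raise ValueError("malformed header at byte 0: unknown version magic")
    fmt = (fmt or detected).upper()

    def field(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", "replace").strip()

    try:
        hdr_bytes = int(field(184, 8))
        n_records = int(field(236, 8))
        rec_dur = float(field(244, 8))
        n_sig = int(field(252, 4))
    except ValueError as exc:
        raise ValueError("malformed header at bytes 184-255") from exc
    if len(raw) < hdr_bytes:
        raise ValueError(f"malformed header: file ends at byte {len(raw)}")

    def sig_fields(block: int, width: int) -> list[str]:
        base = _HDR_FIX + block
        return [
            raw[base + i * width : base + (i + 1) * width]
            .decode("ascii", "replace")
            .strip()
            for i in range(n_sig)
        ]

    labels = sig_fields(0, 16)
    off = n_sig * 16 + n_sig * 80 + n_sig * 8
    phys_min = [float(v) for v in sig_fields(off, 8)]
    phys_max = [float(v) for v in sig_fields(off + n_sig * 8, 8)]
    dig_min = [int(v) for v in sig_fields(off + 2 * n_sig * 8, 8)]
    dig_max = [int(v) for v in sig_fields(off + 3 * n_sig * 8, 8)]
    spr = [int(v) for v in sig_fields(off + 4 * n_sig * 8 + n_sig * 80, 8)]
    if len(set(spr)) != 1:
        raise ValueError("signals with differing sampling rates unsupported")
    n_per_rec = spr[0]
    fs = n_per_rec / rec_dur

    bps = 2 if fmt == "EDF" else 3
    expected = hdr_bytes + n_records * n_sig * n_per_rec * bps
    if len(raw) < expected:
        raise ValueError(
            f"truncated file: expected {expected} bytes, got {len(raw)}"
        )
    body = np.frombuffer(raw, dtype=np.uint8, count=expected - hdr_bytes,
                         offset=hdr_bytes)
    if fmt == "EDF":
        digital = body.view("<i2").astype(np.int32)
    else:
        b = body.reshape(-1, 3).astype(np.int32)
        digital = b[:, 0] | (b[:, 1] << 8) | (b[:, 2] << 16)
        digital = np.where(digital >= 1 << 23, digital - (1 << 24), digital)
    digital = digital.reshape(n_records, n_sig, n_per_rec)
    data = np.concatenate(
        [digital[r] for r in range(n_records)], axis=1
    ).astype(float)
    for i in range(n_sig):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        data[i] = (data[i] - dig_min[i]) * gain + phys_min[i]

    events: tuple[tuple[str, int], ...] = ()
    sidecar = (
        Path(events_csv)
        if events_csv
        else path.with_suffix(path.suffix + ".events.csv")
    )
    if sidecar.exists():
        events = _read_events_csv(sidecar)
    elif "Status" in labels:
        events = _status_events(data[labels.index("Status")])
    keep = [i for i, lab in enumerate(labels) if lab != "Status"]
    return ContinuousRecording(
        labels=tuple(labels[i] for i in keep),
        fs=fs,
        data=data[keep],
        events=events,
        montage=montage,
    )
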