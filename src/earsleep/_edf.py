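"""Minimal EDF (European Data Format) codec for multi-channel EEG.

Implements the 16-bit EDF layout: a 256-byte fixed header, 256 bytes of
per-signal header fields, and data records of little-endian int16 samples.
All signals are stored with physical dimension "uV" and a symmetric physical
range, so the quantization step of channel *c* is
``(phys_max - phys_min) / (dig_max - dig_min)``.

Records are one second long. Signals whose length is not a whole number of
seconds are zero-padded up to the next record boundary on write; the reader
returns whole records, so callers that need exact round-trips should write
whole-second signals.
"""

from __future__ import annotations

import datetime as _dt
import math

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def _fmt_float(x: float, width: int = 8) -> str:
    """Format a float into EDF's fixed-width ASCII numeric field."""
    for fmt in ("%g", "%.6g", "%.5g", "%.4g", "%.3g", "%.2g", "%.1g"):
        s = fmt % x
        if len(s) <= width:
            return s
    raise ValueError(f"cannot format {x!r} in {width} ASCII chars")


def write_edf(
    path,
    data: np.ndarray,
    labels: list[str],
    fs: float,
    start_time: _dt.datetime | None = None,
) -> None:
    """Write ``data`` (n_channels, n_samples) in µV to an EDF file."""
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    if len(labels) != n_ch:
        raise ValueError("label count does not match channel count")
    if fs <= 0 or fs != int(fs):
        raise ValueError("EDF writer requires a positive integer sampling rate")
    spr = int(fs)  # samples per 1-second record
    n_rec = max(1, math.ceil(n_samp / spr))

    if start_time is None:
        start_time = _dt.datetime(2000, 1, 1, 0, 0, 0)

    # Symmetric physical range per channel; reparse the ASCII fields so the
    # scaling used for encoding is exactly what a reader will recover.
    pmaxs, pmins = [], []
    for ch in range(n_ch):
        absmax = float(np.max(np.abs(data[ch]))) if n_samp else 0.0
        if absmax == 0.0:
            absmax = 1.0
        pmax_s = _fmt_float(absmax * 1.0000001)
        pmax = float(pmax_s)
        if pmax < absmax:  # formatting rounded down; bump the last digit
            pmax_s = _fmt_float(absmax * 1.01)
            pmax = float(pmax_s)
        pmaxs.append(pmax_s)
        pmins.append(_fmt_float(-pmax))

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii(start_time.strftime("%d.%m.%y"), 8),
            _ascii(start_time.strftime("%H.%M.%S"), 8),
            _ascii(str(256 * (n_ch + 1)), 8),
            _ascii("", 44),
            _ascii(str(n_rec), 8),
            _ascii("1", 8),
            _ascii(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_ascii(lb, 16) for lb in labels),
            b"".join(_ascii("", 80) for _ in labels),
            b"".join(_ascii("uV", 8) for _ in labels),
            b"".join(_ascii(s, 8) for s in pmins),
            b"".join(_ascii(s, 8) for s in pmaxs),
            b"".join(_ascii(str(_DIG_MIN), 8) for _ in labels),
            b"".join(_ascii(str(_DIG_MAX), 8) for _ in labels),
            b"".join(_ascii("", 80) for _ in labels),
            b"".join(_ascii(str(spr), 8) for _ in labels),
            b"".join(_ascii("", 32) for _ in labels),
        ]
    )

    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data
    digital = np.empty_like(padded, dtype="<i2")
    for ch in range(n_ch):
        pmin, pmax = float(pmins[ch]), float(pmaxs[ch])
        scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        d = np.rint((padded[ch] - pmin) * scale) + _DIG_MIN
        digital[ch] = np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # record-major layout: for each record, each signal's chunk in turn
        for rec in range(n_rec):
            sl = slice(rec * spr, (rec + 1) * spr)
            for ch in range(n_ch):
                fh.write(digital[ch, sl].tobytes())


def read_edf(path):
    """Read an EDF file; returns (data µV, labels, fs, start_time)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256 or head[:8].strip() not in (b"0", b"0+"):
            raise ValueError(f"{path}: not an EDF file (bad version field)")
        try:
            date_s = head[168:176].decode("ascii").strip()
            time_s = head[176:184].decode("ascii").strip()
            n_rec = int(head[236:244])
            rec_dur = float(head[244:252])
            n_ch = int(head[252:256])
        except (UnicodeDecodeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed EDF header ({exc})") from exc

        raw = fh.read(256 * n_ch)
        if len(raw) < 256 * n_ch:
            raise ValueError(f"{path}: truncated EDF signal header")

        def sfield(name, width):
            base = {"label": 0, "transducer": 16 * n_ch, "dim": 96 * n_ch,
                    "pmin": 104 * n_ch, "pmax": 112 * n_ch, "dmin": 120 * n_ch,
                    "dmax": 128 * n_ch, "prefilter": 136 * n_ch,
                    "spr": 216 * n_ch}[name]
            return [
                raw[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        labels = sfield("label", 16)
        pmin = [float(s) for s in sfield("pmin", 8)]
        pmax = [float(s) for s in sfield("pmax", 8)]
        dmin = [int(s) for s in sfield("dmin", 8)]
        dmax = [int(s) for s in sfield("dmax", 8)]
        spr = [int(s) for s in sfield("spr", 8)]

        if len(set(spr)) != 1:
            raise ValueError(f"{path}: mixed per-signal sampling rates unsupported")
        fs = spr[0] / rec_dur

        body = np.frombuffer(fh.read(), dtype="<i2")

    expect = n_rec * sum(spr)
    if body.size < expect:
        raise ValueError(f"{path}: data section shorter than header declares")
    body = body[:expect].reshape(n_rec, n_ch, spr[0])
    data = np.empty((n_ch, n_rec * spr[0]))
    for ch in range(n_ch):
        scale = (pmax[ch] - pmin[ch]) / (dmax[ch] - dmin[ch])
        data[ch] = (body[:, ch, :].reshape(-1).astype(float) - dmin[ch]) * scale + pmin[ch]

    try:
        start = _dt.datetime.strptime(date_s + " " + time_s, "%d.%m.%y %H.%M.%S")
    except ValueError:
        start = None
    return data, labels, fs, start
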