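"""Minimal EDF (European Data Format) writer.

Writes the classic EDF layout: a 256-byte fixed header, 256 bytes of signal
header per channel (field-wise concatenated), then little-endian 16-bit data
records.  Physical units are microvolts.  Only writing lives here; reading
goes through mne's EDF reader (see :mod:`erptrials.io`), which also serves as
the round-trip check in the test suite.

Record layout: when the sampling rate is an integer that divides the sample
count, one-second records are used; otherwise the whole signal is stored as a
single record whose duration field must represent ``n_samples / rate``
exactly in eight ASCII characters (true for every rate this package emits).
"""

from __future__ import annotations

import datetime

import numpy as np

DIG_MIN, DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> str:
    """Shortest decimal for ``value`` that fits ``width`` chars exactly."""
    for fmt in ("%d", "%.10g", "%.8g", "%.6g", "%.4g", "%.2g"):
        s = fmt % value
        if fmt == "%d" and float(s) != value:
            continue
        if len(s) <= width:
            return s
    raise ValueError(f"cannot represent {value} in {width} EDF chars")


def write_edf(rec, path) -> None:
    from .io import ValidationError

    x = np.asarray(rec.samples, dtype=float)
    ns, n = x.shape
    if n < 1:
        raise ValidationError("cannot write empty recording")

    rate = float(rec.rate)
    if rate == int(rate) and n % int(rate) == 0:
        spr, n_rec = int(rate), n // int(rate)
    else:
        spr, n_rec = n, 1
    dur_str = _num(spr / rate, 8)
    if abs(spr / float(dur_str) - rate) > 1e-9 * rate:
        raise ValidationError(
            f"rate {rate} Hz has no exact EDF record-duration representation")

    # physical range per channel, re-parsed from its 8-char header string so
    # that the scaling we apply matches what any reader will reconstruct
    pmins, pmaxs, dig = [], [], np.empty_like(x, dtype=np.int16)
    for c in range(ns):
        lo, hi = float(x[c].min()), float(x[c].max())
        if hi <= lo:
            hi = lo + 1.0
        lo_s, hi_s = _num(lo, 8), _num(hi, 8)
        lo, hi = float(lo_s), float(hi_s)
        if hi <= lo:  # rounding collapsed the range
            hi_s = _num(lo + 1.0, 8)
            hi = float(hi_s)
        pmins.append(lo_s)
        pmaxs.append(hi_s)
        gain = (DIG_MAX - DIG_MIN) / (hi - lo)
        d = np.rint((x[c] - lo) * gain + DIG_MIN)
        dig[c] = np.clip(d, DIG_MIN, DIG_MAX).astype(np.int16)

    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate 01-JAN-2000 X X X", 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(256 * (ns + 1), 8),
        _field("", 44),
        _field(n_rec, 8),
        _field(dur_str, 8),
        _field(ns, 4),
    ])
    labels = [name[:16] for name in rec.channel_names]
    header += b"".join(_field(lab, 16) for lab in labels)
    header += b"".join(_field("", 80) for _ in range(ns))          # transducer
    header += b"".join(_field("uV", 8) for _ in range(ns))
    header += b"".join(_field(p, 8) for p in pmins)
    header += b"".join(_field(p, 8) for p in pmaxs)
    header += b"".join(_field(DIG_MIN, 8) for _ in range(ns))
    header += b"".join(_field(DIG_MAX, 8) for _ in range(ns))
    header += b"".join(_field("", 80) for _ in range(ns))          # prefilter
    header += b"".join(_field(spr, 8) for _ in range(ns))
    header += b"".join(_field("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for c in range(ns):
                fh.write(dig[c, r * spr:(r + 1) * spr].tobytes())
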