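"""Core data containers and file I/O for continuous recordings and event markers.

A :class:`Recording` holds one or more equally sampled channels in microvolts;
an :class:`EventSeries` holds strictly increasing stimulus-onset times in
seconds.  Two on-disk formats are supported for signals: a TAB-separated text
dialect (diff-able, used for fixtures) and EDF (16-bit, the interchange format
of clinical EEG).  Event markers are always plain text.

Text signal dialect::

    # optional comments
    rate=250
    start_time=0.0
    channels=EEG1<TAB>EEG2
    <sample><TAB><sample>
    ...

Event dialect: one event per line, ``time_s<TAB>label`` with the label
optional; ``#`` comments allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class FormatError(ValueError):
    """Raised when a file cannot be parsed in the requested format."""


class ValidationError(ValueError):
    """Raised when data violate a structural invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A continuous multi-channel recording.

    Parameters
    ----------
    samples : array, shape (n_channels, n_samples) or (n_samples,)
        Amplitudes in microvolts.  A 1-D array is promoted to one channel.
    rate : float
        Sampling frequency in Hz, > 0.
    channel_names : sequence of str, optional
        Defaults to ``ch0, ch1, ...``.
    start_time : float
        Time of sample 0 in seconds; sample ``i`` is at
        ``start_time + i / rate``.
    """

    samples: np.ndarray
    rate: float
    channel_names: tuple = ()
    start_time: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise ValidationError("samples must be 1-D or 2-D")
        if arr.shape[1] < 1:
            raise ValidationError("recording must contain at least one sample")
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValidationError(f"rate must be > 0, got {self.rate}")
        self.samples = arr
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(arr.shape[0]))
        else:
            self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) != arr.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{arr.shape[0]} channels")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    def channel(self, selector=0) -> np.ndarray:
        """Return one channel as a 1-D array; selector is an index or name."""
        if isinstance(selector, str):
            try:
                idx = self.channel_names.index(selector)
            except ValueError:
                raise ValidationError(
                    f"no channel named {selector!r}; have {self.channel_names}")
        else:
            idx = int(selector)
            if not -self.n_channels <= idx < self.n_channels:
                raise ValidationError(f"channel index {idx} out of range")
        return self.samples[idx]


@dataclass
class EventSeries:
    """Ordered stimulus/marker times in seconds, with optional labels."""

    times: np.ndarray
    labels: tuple = field(default=None)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).ravel()
        if t.size and np.any(np.diff(t) <= 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValidationError(
                f"event times must be strictly increasing (event {bad})")
        self.times = t
        if self.labels is not None:
            self.labels = tuple(str(x) for x in self.labels)
            if len(self.labels) != t.size:
                raise ValidationError("one label per event required")

    def __len__(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# text format
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    # repr gives the shortest decimal that round-trips a float64 exactly
    return repr(float(x))


def _read_text_recording(path) -> Recording:
    header = {}
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not rows and "=" in line and line.split("\t")[0].count("=") == 1:
                key, _, val = line.partition("=")
                header[key.strip()] = val
                continue
            try:
                rows.append([float(v) for v in line.split("\t")])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: bad sample {line!r}")
    if "rate" not in header:
        raise FormatError(f"{path}: missing required header field 'rate'")
    try:
        rate = float(header["rate"])
    except ValueError:
        raise FormatError(f"{path}: field 'rate' is not a number")
    if not rows:
        raise ValidationError(f"{path}: no samples")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged sample rows (widths {sorted(widths)})")
    data = np.asarray(rows, dtype=float).T
    names = tuple(header["channels"].split("\t")) if "channels" in header else ()
    return Recording(data, rate=rate, channel_names=names,
                     start_time=float(header.get("start_time", 0.0)))


def _write_text_recording(rec: Recording, path) -> None:
    with open(path, "w") as fh:
        fh.write("# erptrials recording, amplitudes in uV\n")
        fh.write(f"rate={_fmt(rec.rate)}\n")
        fh.write(f"start_time={_fmt(rec.start_time)}\n")
        fh.write("channels=" + "\t".join(rec.channel_names) + "\n")
        for row in rec.samples.T:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _read_edf_recording(path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"{path}: cannot parse as EDF: {exc}") from exc
    data = raw.get_data(units="uV")
    rate = float(raw.info["sfreq"])
    # EDF stores samples-per-record and record duration separately; the
    # reader's division can leave float dust on an exactly integer rate
    if abs(rate - round(rate)) < 1e-6 * rate:
        rate = float(round(rate))
    return Recording(data, rate=rate, channel_names=tuple(raw.ch_names),
                     start_time=0.0)


def read_recording(path, format: str = None, channel=None) -> Recording:
    """Read a recording from ``path``.

    ``format`` is ``"edf"`` or ``"text"``; when omitted it is inferred from
    the file extension (.edf vs anything else).
    """
    if format is None:
        format = "edf" if str(path).lower().endswith(".edf") else "text"
    if format == "edf":
        rec = _read_edf_recording(path)
    elif format == "text":
        rec = _read_text_recording(path)
    else:
        raise FormatError(f"unknown recording format {format!r}")
    if channel is not None:
        rec = Recording(rec.channel(channel), rec.rate,
                        (rec.channel_names[0] if isinstance(channel, int)
                         else channel,), rec.start_time)
    return rec


def write_recording(rec: Recording, path, format: str = None) -> None:
    """Write a recording; round-trips through :func:`read_recording`."""
    if format is None:
        format = "edf" if str(path).lower().endswith(".edf") else "text"
    if format == "edf":
        from ._edf import write_edf
        write_edf(rec, path)
    elif format == "text":
        _write_text_recording(rec, path)
    else:
        raise FormatError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def read_events(path) -> EventSeries:
    times, labels, any_label = [], [], False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            try:
                t = float(parts[0])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: bad time {parts[0]!r}")
            if times and t <= times[-1]:
                raise ValidationError(
                    f"{path}: line {lineno}: time {t} not greater than "
                    f"previous {times[-1]}")
            times.append(t)
            if len(parts) > 1 and parts[1] != "":
                labels.append(parts[1])
                any_label = True
            else:
                labels.append("")
    return EventSeries(np.asarray(times), tuple(labels) if any_label else None)


def write_events(ev: EventSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("# erptrials events: time_s<TAB>label\n")
        for i, t in enumerate(ev.times):
            label = ev.labels[i] if ev.labels is not None else ""
            fh.write(_fmt(t) + ("\t" + label if label else "") + "\n")
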