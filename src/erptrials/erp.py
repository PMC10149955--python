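"""Epoch extraction, averaging with SEM bands, and ERP component windows.

An event-related potential (ERP) is the per-sample average of fixed-length
signal epochs cut around repeated stimulus markers.  Components — the positive
(P) and negative (N) deflections of the average, named by their peak latency
in milliseconds (P200, N340, ...) — are delimited either manually or by the
zero crossings of the averaged waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Recording, EventSeries, ValidationError


def window_to_samples(window, rate: float) -> tuple:
    """Convert a (start_s, end_s) post-stimulus window into sample offsets.

    Half-open convention: offsets ``[round(start*rate), round(end*rate))``
    relative to the event sample, so the epoch length is identical across
    trials regardless of fractional event times.
    """
    start_s, end_s = window
    i0 = int(round(start_s * rate))
    i1 = int(round(end_s * rate))
    if i1 <= i0:
        raise ValidationError(f"window {window} collapses at rate {rate} Hz")
    return i0, i1


@dataclass
class TrialMatrix:
    """Epochs cut around events: one row per kept event.

    ``data`` is n_kept x n_samples in microvolts; column ``j`` is at time
    ``(j - n_pre) / rate`` relative to the event.  Events whose full window
    fell outside the recording are listed in ``dropped_event_indices`` as
    ``(event_index, reason)`` pairs.
    """

    data: np.ndarray
    rate: float
    n_pre: int
    kept_event_indices: np.ndarray
    dropped_event_indices: tuple
    source_times: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def time_axis(self) -> np.ndarray:
        return (np.arange(self.n_samples) - self.n_pre) / self.rate

    def window_columns(self, window) -> tuple:
        """Column bounds [i0, i1) of a post-stimulus window within the epoch."""
        w0, w1 = window_to_samples(window, self.rate)
        return self.n_pre + w0, self.n_pre + w1


@dataclass
class ErpEstimate:
    """Averaged ERP: per-sample mean and standard error over trials."""

    mean: np.ndarray
    sem: np.ndarray
    n: int
    rate: float
    n_pre: int

    @property
    def time_axis(self) -> np.ndarray:
        return (np.arange(self.mean.size) - self.n_pre) / self.rate

    def window_columns(self, window) -> tuple:
        w0, w1 = window_to_samples(window, self.rate)
        i0, i1 = self.n_pre + w0, self.n_pre + w1
        if i0 < 0 or i1 > self.mean.size:
            raise ValidationError(
                f"window {window} outside the epoch time axis")
        return i0, i1


@dataclass
class ComponentSpec:
    """One ERP component: polarity, post-stimulus window, peak location."""

    name: str
    polarity: int
    window: tuple
    peak_latency: float
    peak_amplitude: float = 0.0

    def __post_init__(self):
        if self.polarity not in (-1, 1):
            raise ValidationError("polarity must be +1 or -1")
        s, e = self.window
        if not (0 <= s < e):
            raise ValidationError(f"need 0 <= start < end, got {self.window}")
        if not (s <= self.peak_latency <= e):
            raise ValidationError("peak_latency must lie within the window")
        if self.peak_amplitude and np.sign(self.peak_amplitude) != self.polarity:
            raise ValidationError("peak_amplitude sign contradicts polarity")


def extract_epochs(rec: Recording, ev: EventSeries, pre_s: float,
                   post_s: float, channel=0,
                   baseline: str = "none") -> TrialMatrix:
    """Cut epochs ``[t - pre_s, t + post_s)`` around each event.

    Events too close to either edge of the recording are dropped and recorded
    with a reason.  ``baseline="prestim"`` subtracts each trial's pre-stimulus
    mean; the default applies no correction.
    """
    if pre_s < 0 or post_s < 0 or (pre_s == 0 and post_s == 0):
        raise ValidationError("need pre_s, post_s >= 0 and not both zero")
    x = rec.channel(channel)
    n_pre = int(round(pre_s * rec.rate))
    n_post = int(round(post_s * rec.rate))
    rows, kept, dropped, times = [], [], [], []
    for i, t in enumerate(ev.times):
        e = int(round((t - rec.start_time) * rec.rate))
        lo, hi = e - n_pre, e + n_post
        if lo < 0:
            dropped.append((i, "window starts before recording"))
        elif hi > x.size:
            dropped.append((i, "window ends after recording"))
        else:
            rows.append(x[lo:hi])
            kept.append(i)
            times.append(t)
    if not rows:
        raise ValidationError(
            f"no event of {len(ev)} fits a [-{pre_s}, +{post_s}) s window")
    data = np.asarray(rows, dtype=float)
    if baseline == "prestim":
        if n_pre == 0:
            raise ValidationError("prestim baseline requires pre_s > 0")
        data = data - data[:, :n_pre].mean(axis=1, keepdims=True)
    elif baseline != "none":
        raise ValidationError(f"unknown baseline mode {baseline!r}")
    return TrialMatrix(data, rec.rate, n_pre, np.asarray(kept, dtype=int),
                       tuple(dropped), np.asarray(times))


def average_epochs(tm: TrialMatrix, index_set=None) -> ErpEstimate:
    """Average epochs (optionally a subset) with the standard error per sample.

    SEM is the sample standard deviation (n-1 denominator) over trials divided
    by sqrt(n); defined as 0 when n = 1.
    """
    data = tm.data if index_set is None else tm.data[np.asarray(
        sorted(index_set), dtype=int)]
    n = data.shape[0]
    if n < 1:
        raise ValidationError("cannot average zero trials")
    mean = data.mean(axis=0)
    if n == 1:
        sem = np.zeros_like(mean)
    else:
        sem = data.std(axis=0, ddof=1) / np.sqrt(n)
    return ErpEstimate(mean, sem, n, tm.rate, tm.n_pre)


def _auto_name(polarity: int, peak_latency: float) -> str:
    return ("P" if polarity > 0 else "N") + str(int(round(peak_latency * 1000)))


def detect_component_windows(erp: ErpEstimate, min_duration_s: float = 0.0,
                             search_range=None) -> list:
    """Delimit components as maximal constant-sign runs of the averaged mean.

    Runs are bounded by zero crossings (located by linear interpolation and
    snapped outward to the sample grid) within ``search_range`` — by default
    the whole post-stimulus part of the axis — and kept when at least
    ``min_duration_s`` long.  Each run yields a :class:`ComponentSpec` whose
    polarity is the run's sign and whose peak is the signed extremum.
    """
    t = erp.time_axis
    if search_range is None:
        search_range = (0.0, t[-1] + 1.0 / erp.rate)
    s0, s1 = search_range
    if s0 < 0:
        raise ValidationError("search range must be post-stimulus")
    sel = np.flatnonzero((t >= s0) & (t < s1))
    if sel.size == 0:
        return []
    m = erp.mean
    specs = []
    i = sel[0]
    stop = sel[-1] + 1
    while i < stop:
        if m[i] == 0:
            i += 1
            continue
        sign = 1 if m[i] > 0 else -1
        j = i
        while j + 1 < stop and np.sign(m[j + 1]) == sign:
            j += 1
        # locate bounding zero crossings, snapped outward to the grid
        if i > sel[0] and np.sign(m[i - 1]) != sign:
            frac = m[i - 1] / (m[i - 1] - m[i]) if m[i - 1] != m[i] else 0.0
            start_s = t[i - 1] + frac / erp.rate
            start_s = np.floor(start_s * erp.rate) / erp.rate
        else:
            start_s = t[i]
        if j + 1 < stop and np.sign(m[j + 1]) != sign and m[j + 1] != 0:
            frac = m[j] / (m[j] - m[j + 1])
            end_s = t[j] + frac / erp.rate
            end_s = np.ceil(end_s * erp.rate) / erp.rate
        else:
            end_s = t[j] + 1.0 / erp.rate
        start_s = max(start_s, 0.0)
        if end_s - start_s >= max(min_duration_s, 2.0 / erp.rate):
            run = slice(i, j + 1)
            k = i + int(np.argmax(np.abs(m[run])))
            specs.append(ComponentSpec(
                name=_auto_name(sign, t[k]), polarity=sign,
                window=(float(start_s), float(end_s)),
                peak_latency=float(t[k]), peak_amplitude=float(m[k])))
        i = j + 1
    return specs


def read_components(path) -> list:
    """Read a component table (TSV: name, polarity, start_s, end_s,
    peak_latency_s[, peak_amplitude_uv])."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "polarity", "start_s", "end_s", "peak_latency_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    specs = []
    for row in df.itertuples(index=False):
        specs.append(ComponentSpec(
            name=str(row.name), polarity=int(row.polarity),
            window=(float(row.start_s), float(row.end_s)),
            peak_latency=float(row.peak_latency_s),
            peak_amplitude=float(getattr(row, "peak_amplitude_uv", 0.0))))
    return specs


def write_components(specs, path) -> None:
    import pandas as pd

    pd.DataFrame([{
        "name": s.name, "polarity": s.polarity, "start_s": s.window[0],
        "end_s": s.window[1], "peak_latency_s": s.peak_latency,
        "peak_amplitude_uv": s.peak_amplitude,
    } for s in specs]).to_csv(path, sep="\t", index=False)


def component_amplitude(erp: ErpEstimate, spec: ComponentSpec) -> tuple:
    """Latency and signed amplitude of the maximal absolute deflection of the
    averaged waveform within the component's window."""
    i0, i1 = erp.window_columns(spec.window)
    seg = erp.mean[i0:i1]
    k = int(np.argmax(np.abs(seg)))
    return float(erp.time_axis[i0 + k]), float(seg[k])


__all__ = [
    "TrialMatrix", "ErpEstimate", "ComponentSpec", "extract_epochs",
    "average_epochs", "detect_component_windows", "component_amplitude",
    "window_to_samples", "read_components", "write_components",
]
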