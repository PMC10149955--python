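"""Template matching of single trials by sine similarity.

The averaged component shape inside its window is the template.  Each trial is
scored by the Pearson correlation ``r`` between its own window slice and the
template, converted to sine similarity::

    S = 1 - r**2   if r > 0
    S = 1          otherwise

so that S lives in [0, 1] and *smaller means more alike*; anti-correlated
trials are maximally dissimilar rather than interestingly inverted.  Response
latency jitter is absorbed by a ``maxshift`` search: the comparison window
slides over the trial by every integer shift in ``[-maxshift, +maxshift]``
and the smallest S is kept.  Trials at or below an S threshold are the
"efficient" ones — those judged to carry the component — the rest are the
residual trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ValidationError
from .erp import ErpEstimate, TrialMatrix, ComponentSpec


@dataclass
class Template:
    """Reference waveform of one component: the averaged shape in its window."""

    values: np.ndarray
    window: tuple
    source_n: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size < 3:
            raise ValidationError(
                f"template needs >= 3 samples (Pearson r needs variance), "
                f"got {v.size}")
        self.values = v


@dataclass
class TrialSimilarity:
    """Per-trial best-shift similarity scores against one template."""

    r: np.ndarray
    S: np.ndarray
    best_shift: np.ndarray
    maxshift: int
    window: tuple
    trial_times: np.ndarray


@dataclass
class TrialClassification:
    """Efficient / residual split of the trials at one S threshold."""

    component_name: str
    threshold: float
    efficient: np.ndarray
    residual: np.ndarray
    efficient_times: np.ndarray
    residual_times: np.ndarray


def extract_template(erp: ErpEstimate, spec: ComponentSpec) -> Template:
    """Slice of the averaged ERP over the component window."""
    i0, i1 = erp.window_columns(spec.window)
    if i1 - i0 < 3:
        raise ValidationError(
            f"window {spec.window} spans {i1 - i0} samples; need >= 3")
    return Template(erp.mean[i0:i1].copy(), spec.window, erp.n)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; 0 (with a warning) when either
    vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError("need at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0:
        warnings.warn("zero-variance vector in pearson_r; returning r = 0",
                      stacklevel=2)
        return 0.0
    return float(np.clip((xc @ yc) / den, -1.0, 1.0))


def sine_similarity(r: float) -> float:
    """Map a correlation to sine similarity: ``1 - r**2`` for r > 0, else 1."""
    if not -1.0 <= r <= 1.0:
        raise ValidationError(f"r must be in [-1, 1], got {r}")
    return 1.0 - r * r if r > 0 else 1.0


def mean_squared_difference(f, g) -> float:
    """Mean of squared pointwise differences.

    The unnormalised precursor of sine similarity; exposed for comparison but
    not used by the pipeline, because its scale depends on the amplitude of
    the trial noise rather than on shape alone.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.size != g.size:
        raise ValidationError(f"length mismatch: {f.size} vs {g.size}")
    if f.size < 1:
        raise ValidationError("need at least 1 point")
    d = f - g
    return float(d @ d / d.size)


def _shift_order(maxshift: int) -> list:
    """Shift search order implementing the tie-break: smallest |shift| first,
    negative before positive."""
    order = [0]
    for k in range(1, maxshift + 1):
        order.extend([-k, k])
    return order


def trial_similarity(tm: TrialMatrix, template: Template,
                     maxshift: int = 0) -> TrialSimilarity:
    """Best-shift sine similarity of every trial against the template.

    Positive ``best_shift`` means the trial's component occurs *later* than
    the template: the comparison window slides over the trial while the
    template stays fixed.  Zero-variance (flat) trial segments score r = 0 and
    S = 1.
    """
    if maxshift < 0:
        raise ValidationError("maxshift must be >= 0")
    i0, i1 = tm.window_columns(template.window)
    if i1 - i0 != template.values.size:
        raise ValidationError("template length does not match the window at "
                              "this sampling rate")
    if i0 - maxshift < 0 or i1 + maxshift > tm.n_samples:
        raise ValidationError(
            f"window {template.window} shifted by +-{maxshift} samples leaves "
            f"the epoch")
    t = template.values - template.values.mean()
    t_norm = np.sqrt(t @ t)
    if t_norm == 0:
        raise ValidationError("template has zero variance")

    shifts = _shift_order(maxshift)
    n = tm.n_trials
    r_all = np.empty((len(shifts), n))
    for si, s in enumerate(shifts):
        seg = tm.data[:, i0 + s:i1 + s]
        segc = seg - seg.mean(axis=1, keepdims=True)
        seg_norm = np.sqrt(np.einsum("ij,ij->i", segc, segc))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (segc @ t) / (seg_norm * t_norm)
        r[seg_norm == 0] = 0.0
        r_all[si] = np.clip(r, -1.0, 1.0)
    S_all = np.where(r_all > 0, 1.0 - r_all ** 2, 1.0)
    best = np.argmin(S_all, axis=0)  # first minimum wins -> tie-break order
    idx = (best, np.arange(n))
    return TrialSimilarity(
        r=r_all[idx], S=S_all[idx],
        best_shift=np.asarray(shifts)[best], maxshift=maxshift,
        window=template.window, trial_times=tm.source_times.copy())


def classify_trials(ts: TrialSimilarity, threshold: float,
                    component_name: str = "") -> TrialClassification:
    """Split trials at an S threshold: efficient are those with S <= threshold."""
    if not 0 <= threshold <= 1:
        raise ValidationError("threshold must be in [0, 1]")
    eff = np.flatnonzero(ts.S <= threshold)
    res = np.flatnonzero(ts.S > threshold)
    return TrialClassification(
        component_name=component_name, threshold=float(threshold),
        efficient=eff, residual=res,
        efficient_times=ts.trial_times[eff], residual_times=ts.trial_times[res])
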