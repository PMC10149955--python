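"""Permutation test for the presence of an ERP component.

The null distribution of a component's amplitude is built by repeatedly
averaging the recording on randomly placed pseudo-triggers: each permutation
draws as many random markers as there are real stimuli, averages the epochs,
and takes the signed value of the maximal absolute deflection within the
component's window.  Sorting the pseudo-amplitudes (descending for positive
components, ascending for negative ones) turns ranks into p-values: with 500
permutations the rank-25 value is the 95% critical amplitude and an observed
amplitude at rank k has p = k/500.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Recording, EventSeries, ValidationError
from .erp import ComponentSpec, window_to_samples


@dataclass
class PermutationResult:
    """Sorted pseudo-response amplitudes for one component window."""

    deflections: np.ndarray
    n_perm: int
    n_events: int
    window: tuple
    polarity: int
    seed: int

    def __post_init__(self):
        d = np.asarray(self.deflections, dtype=float)
        if d.size != self.n_perm:
            raise ValidationError("deflections length must equal n_perm")
        self.deflections = d


def _draw_marker_samples(rng: np.random.Generator, n: int, lo: int, hi: int,
                         allowed: np.ndarray = None) -> np.ndarray:
    """Draw ``n`` distinct sample indices uniformly from [lo, hi), optionally
    restricted to an explicit ``allowed`` index set."""
    pool = hi - lo if allowed is None else allowed.size
    if pool < n:
        raise ValidationError(
            f"interval of {pool} admissible samples cannot host {n} "
            f"distinct markers")
    if allowed is not None:
        return np.sort(rng.choice(allowed, size=n, replace=False))
    picked = np.unique(rng.integers(lo, hi, size=n))
    while picked.size < n:
        extra = rng.integers(lo, hi, size=n - picked.size)
        picked = np.unique(np.concatenate([picked, extra]))
    return picked


def _allowed_samples(rec: Recording, lo: int, hi: int, exclude_events,
                     pre_s: float, post_s: float) -> np.ndarray:
    """Sample indices in [lo, hi) whose epoch would not overlap any epoch of
    ``exclude_events``."""
    ok = np.ones(hi - lo, dtype=bool)
    span = int(round(pre_s * rec.rate)) + int(round(post_s * rec.rate))
    for t in np.asarray(exclude_events.times, dtype=float):
        e = int(round((t - rec.start_time) * rec.rate))
        a = max(e - span + 1, lo)
        b = min(e + span, hi)
        if b > a:
            ok[a - lo:b - lo] = False
    return lo + np.flatnonzero(ok)


def generate_random_events(rec: Recording, n: int, pre_s: float, post_s: float,
                           seed=None, rng=None,
                           exclude_events: EventSeries = None) -> EventSeries:
    """Uniformly random pseudo-triggers over the recording.

    Times are drawn over ``[start + pre_s, end - post_s)`` at sample
    resolution, sorted, with duplicates re-drawn, so every pseudo-epoch fits
    inside the recording.  By default pseudo-triggers may fall anywhere in
    that interval, including inside real stimulation epochs; pass
    ``exclude_events`` to forbid overlap with the real epochs instead.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_pre = int(round(pre_s * rec.rate))
    n_post = int(round(post_s * rec.rate))
    lo, hi = n_pre, rec.n_samples - n_post
    if hi <= lo:
        raise ValidationError(
            f"recording of {rec.duration:.3f} s shorter than the "
            f"[-{pre_s}, +{post_s}) s window")
    if n == 0:
        return EventSeries(np.empty(0))
    allowed = None if exclude_events is None else _allowed_samples(
        rec, lo, hi, exclude_events, pre_s, post_s)
    samples = _draw_marker_samples(rng, n, lo, hi, allowed)
    return EventSeries(rec.start_time + samples / rec.rate)


def permutation_distribution(rec: Recording, spec: ComponentSpec,
                             n_events: int, n_perm: int, pre_s: float,
                             post_s: float, seed=None, channel=0, rng=None,
                             exclude_events: EventSeries = None
                             ) -> PermutationResult:
    """Null distribution of the component amplitude from pseudo-triggers.

    Per permutation: draw ``n_events`` random markers, average the epochs, and
    record the signed value at the maximal absolute deflection within
    ``spec.window``.  Only the component window is materialised per epoch —
    identical to averaging the full epoch and then slicing, since averaging is
    per-sample.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    x = rec.channel(channel)
    n_pre = int(round(pre_s * rec.rate))
    n_post = int(round(post_s * rec.rate))
    lo, hi = n_pre, x.size - n_post
    if hi <= lo:
        raise ValidationError("recording shorter than the epoch window")
    w0, w1 = window_to_samples(spec.window, rec.rate)
    offsets = np.arange(w0, w1)
    allowed = None if exclude_events is None else _allowed_samples(
        rec, lo, hi, exclude_events, pre_s, post_s)
    deflections = np.empty(n_perm)
    for p in range(n_perm):
        markers = _draw_marker_samples(rng, n_events, lo, hi, allowed)
        avg = x[markers[:, None] + offsets[None, :]].mean(axis=0)
        deflections[p] = avg[np.argmax(np.abs(avg))]
    order = np.sort(deflections)
    if spec.polarity > 0:
        order = order[::-1]
    return PermutationResult(order.copy(), n_perm, n_events, spec.window,
                             spec.polarity, seed if isinstance(seed, int) else -1)


def critical_value(pr: PermutationResult, alpha: float = 0.05) -> float:
    """Amplitude at the alpha-level rank of the sorted null distribution.

    Rank is ``ceil(alpha * n_perm)`` 1-based — rank 25 for alpha = 0.05 with
    500 permutations.
    """
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must be in (0, 1]")
    rank = max(int(np.ceil(alpha * pr.n_perm)), 1)
    return float(pr.deflections[rank - 1])


def component_p_value(observed: float, pr: PermutationResult) -> float:
    """Permutation p-value of an observed component amplitude.

    For positive polarity p is the fraction of pseudo-amplitudes >= observed;
    for negative polarity, <= observed.  A count of zero is floored at
    ``1/n_perm`` (reported downstream as "< 1/n_perm").
    """
    if pr.polarity > 0:
        if observed < 0:
            warnings.warn("observed amplitude is negative for a positive "
                          "component; p-value will be large", stacklevel=2)
        count = int(np.sum(pr.deflections >= observed))
    else:
        if observed > 0:
            warnings.warn("observed amplitude is positive for a negative "
                          "component; p-value will be large", stacklevel=2)
        count = int(np.sum(pr.deflections <= observed))
    return max(count, 1) / pr.n_perm


def is_significant(p: float, alpha: float = 0.05) -> bool:
    return p <= alpha
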