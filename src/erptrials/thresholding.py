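"""Threshold sweep, residual-flatness criterion, and exclusive trial sets.

The classification threshold is validated by what it leaves behind: at the
right threshold the average of the residual (non-selected) trials is flat
inside the component window.  Too strict a threshold leaves part of the
response in the residuals (their average still bulges with the component's
polarity); too loose a threshold swallows noise trials into the efficient set
and the residual average starts bulging the *opposite* way.  Two read-outs of
this are computed over a threshold grid:

* flatness — the sum of absolute values of the averaged residual waveform,
  minimal at the threshold of choice (the primary, deterministic rule);
* curvature sign — the sign of the bulge of a least-squares quadratic fit,
  whose reversal marks the same transition (advisory output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ValidationError
from .erp import TrialMatrix, ErpEstimate, ComponentSpec, average_epochs
from .similarity import Template, TrialSimilarity, trial_similarity, \
    classify_trials

#: |a| (uV/s^2) below which the quadratic coefficient counts as flat
CURVATURE_TOL = 1e-3

#: the default threshold grid
DEFAULT_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)


def residual_flatness(waveform) -> float:
    """Sum of absolute values of an averaged waveform (uV x samples)."""
    w = np.asarray(waveform, dtype=float)
    if w.size == 0:
        raise ValidationError("empty waveform")
    return float(np.abs(w).sum())


def curvature_sign(waveform, rate: float = 1.0,
                   tol: float = CURVATURE_TOL) -> int:
    """Sign of the bulge of a least-squares quadratic fit.

    Fits ``a*t^2 + b*t + c`` (t in seconds) and returns the sign of ``-a``,
    so a positive bump (downward-opening parabola) gives +1; ``|a| < tol``
    gives 0.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 3:
        raise ValidationError("need >= 3 samples for a quadratic fit")
    t = np.arange(w.size) / rate
    t = t - t.mean()
    a = np.polyfit(t, w, 2)[0]
    if abs(a) < tol:
        return 0
    return int(np.sign(-a))


@dataclass
class ThresholdSweep:
    """Per-threshold bookkeeping for one component.

    ``efficient_avg``/``residual_avg`` hold the group-averaged window
    waveforms, ``None`` when the group is empty; ``flatness`` is NaN and
    ``curvature`` None in that case — an empty residual set never wins the
    minimal-flatness rule by vacuity.
    """

    component_name: str
    thresholds: np.ndarray
    n_efficient: np.ndarray
    n_residual: np.ndarray
    efficient_avg: list
    residual_avg: list
    flatness: np.ndarray
    curvature: list
    maxshift: int


def threshold_sweep(tm: TrialMatrix, template: Template, spec: ComponentSpec,
                    thresholds=DEFAULT_THRESHOLDS, maxshift: int = 0,
                    ts: TrialSimilarity = None) -> ThresholdSweep:
    """Classify at each threshold and average both groups over the window.

    ``thresholds`` must be ascending; similarity scores are computed once and
    reused (pass a precomputed ``ts`` to reuse across sweeps).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0 or np.any(np.diff(thresholds) <= 0):
        raise ValidationError("thresholds must be a nonempty ascending grid")
    if np.any((thresholds < 0) | (thresholds > 1)):
        raise ValidationError("thresholds must lie in [0, 1]")
    if ts is None:
        ts = trial_similarity(tm, template, maxshift)
    i0, i1 = tm.window_columns(spec.window)

    n_eff, n_res, eff_avg, res_avg, flat, curv = [], [], [], [], [], []
    for thr in thresholds:
        cls = classify_trials(ts, thr, spec.name)
        n_eff.append(cls.efficient.size)
        n_res.append(cls.residual.size)
        eff_avg.append(tm.data[cls.efficient, i0:i1].mean(axis=0)
                       if cls.efficient.size else None)
        if cls.residual.size:
            w = tm.data[cls.residual, i0:i1].mean(axis=0)
            res_avg.append(w)
            flat.append(residual_flatness(w))
            curv.append(curvature_sign(w, tm.rate))
        else:
            res_avg.append(None)
            flat.append(np.nan)
            curv.append(None)
    return ThresholdSweep(
        component_name=spec.name, thresholds=thresholds,
        n_efficient=np.asarray(n_eff), n_residual=np.asarray(n_res),
        efficient_avg=eff_avg, residual_avg=res_avg,
        flatness=np.asarray(flat), curvature=curv, maxshift=maxshift)


def select_optimal_threshold(sweep: ThresholdSweep,
                             spec: ComponentSpec) -> tuple:
    """Pick the threshold whose residual average is flattest.

    Primary rule: minimal flatness, ties going to the lowest threshold.  The
    report also carries the first threshold (ascending) whose residual
    curvature sign differs from the component polarity — the
    curvature-reversal reading of the same transition — and flags when the two
    rules disagree.
    """
    if np.all(np.isnan(sweep.flatness)):
        raise ValidationError("no threshold produced a nonempty residual set")
    best = int(np.nanargmin(sweep.flatness))
    threshold = float(sweep.thresholds[best])

    reversal = None
    for i, c in enumerate(sweep.curvature):
        if c is not None and c != spec.polarity:
            reversal = float(sweep.thresholds[i])
            break
    report = {
        "component": spec.name,
        "threshold": threshold,
        "flatness": float(sweep.flatness[best]),
        "n_efficient": int(sweep.n_efficient[best]),
        "n_residual": int(sweep.n_residual[best]),
        "curvature_reversal_threshold": reversal,
        "rules_disagree": reversal is not None and reversal != threshold,
    }
    return threshold, report


def exclusive_trials(classifications) -> dict:
    """Per component, the efficient trials in which *only* that component was
    classified present: the "pure shape" trial sets.

    All classifications must partition the same trial set.
    """
    if not classifications:
        return {}
    universes = [set(c.efficient) | set(c.residual) for c in classifications]
    if any(u != universes[0] for u in universes[1:]):
        raise ValidationError("classifications cover different trial sets")
    out = {}
    for c in classifications:
        others = set()
        for other in classifications:
            if other is not c:
                others.update(other.efficient.tolist())
        out[c.component_name] = np.asarray(
            sorted(set(c.efficient.tolist()) - others), dtype=int)
    return out


def reaverage(tm: TrialMatrix, index_set) -> ErpEstimate:
    """Average the full epochs of the listed trials."""
    idx = np.asarray(sorted(index_set), dtype=int)
    if idx.size == 0:
        raise ValidationError("cannot re-average an empty trial set")
    return average_epochs(tm, idx)
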