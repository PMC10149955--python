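"""Ground-truthed simulation of event-locked recordings.

The generator emulates the situation the analysis is built for: several ERP
components, each present only in a random subset of trials, riding on
broadband noise.  Each present component contributes a half-sine bump of its
polarity centred at ``peak_latency + jitter`` after the stimulus; the noise is
a variance-normalised mixture of white and 1/f ("pink") noise.  Every draw is
reproducible from the master seed, with one independent stream per
(trial, component) pair so that editing one component leaves the ground truth
of the others untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Recording, EventSeries, ValidationError

#: margin kept between the recording edges and the first/last event (s);
#: large enough for a 1 s epoch plus the 1 s guard both sides
EDGE_MARGIN_S = 2.0


@dataclass
class ComponentModel:
    """Generative model of one ERP component.

    ``presence_prob`` is the probability that a given trial contains the
    component at all; ``jitter_sd`` the SD of its Gaussian latency jitter.
    The waveform is a half-sine of ``width`` seconds support, zero at both
    window edges and extremal at the peak.
    """

    name: str
    polarity: int
    peak_latency: float
    width: float
    amplitude_mean: float
    amplitude_sd: float
    presence_prob: float
    jitter_sd: float = 0.0

    def __post_init__(self):
        if self.polarity not in (-1, 1):
            raise ValidationError("polarity must be +1 or -1")
        if not 0 <= self.presence_prob <= 1:
            raise ValidationError("presence_prob must be in [0, 1]")
        if self.width <= 0:
            raise ValidationError("width must be > 0")
        if self.amplitude_mean <= 0:
            raise ValidationError("amplitude_mean must be > 0")

    @property
    def window(self) -> tuple:
        """Nominal (start_s, end_s) support of the component."""
        return (self.peak_latency - self.width / 2,
                self.peak_latency + self.width / 2)


@dataclass
class SimulationConfig:
    rate: float = 250.0
    n_trials: int = 131
    inter_stimulus_interval: float = 2.5
    isi_jitter: float = 0.25
    noise_sd: float = 20.0
    pink_fraction: float = 0.5
    components: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if self.rate <= 0:
            raise ValidationError("rate must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.pink_fraction <= 1:
            raise ValidationError("pink_fraction must be in [0, 1]")
        if self.inter_stimulus_interval <= 2 * abs(self.isi_jitter):
            raise ValidationError("inter_stimulus_interval too small for jitter")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    gain = np.zeros_like(f)
    gain[1:] = 1.0 / np.sqrt(f[1:])
    pink = np.fft.irfft(spec * gain, n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def _trial_rng(seed: int, trial: int, comp: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, trial, comp)))


def generate(config: SimulationConfig):
    """Simulate one recording session.

    Returns
    -------
    rec : Recording
        Single-channel recording in microvolts, ``start_time = 0``.
    ev : EventSeries
        ``n_trials`` stimulus onsets, each at least ``EDGE_MARGIN_S`` from
        both recording edges.
    truth : pandas.DataFrame
        One row per (trial, component): ``trial``, ``component``, ``present``,
        ``jitter_s``, ``amplitude_uv``.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    ev_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    isi = cfg.inter_stimulus_interval + ev_rng.uniform(
        -cfg.isi_jitter, cfg.isi_jitter, size=cfg.n_trials)
    times = EDGE_MARGIN_S + np.concatenate(([0.0], np.cumsum(isi[1:])))
    # stimulus markers are timestamped at sample resolution, as an acquisition
    # system would; this also keeps epochs phase-aligned to the sample grid
    times = np.round(times * cfg.rate) / cfg.rate
    n = int(math.ceil((times[-1] + EDGE_MARGIN_S) * cfg.rate)) + 1

    x = np.zeros(n)
    if cfg.noise_sd > 0:
        white = noise_rng.standard_normal(n)
        if cfg.pink_fraction > 0:
            pink = _pink_noise(n, noise_rng)
            x += cfg.noise_sd * (math.sqrt(1 - cfg.pink_fraction) * white
                                 + math.sqrt(cfg.pink_fraction) * pink)
        else:
            x += cfg.noise_sd * white

    rows = []
    t_axis = np.arange(n) / cfg.rate
    for i, t_ev in enumerate(times):
        for k, comp in enumerate(cfg.components):
            rng = _trial_rng(cfg.seed, i, k)
            present = bool(rng.random() < comp.presence_prob)
            jitter = float(rng.normal(0.0, comp.jitter_sd)) if comp.jitter_sd else 0.0
            amp = float(max(rng.normal(comp.amplitude_mean, comp.amplitude_sd), 0.0)) \
                if comp.amplitude_sd else comp.amplitude_mean
            rows.append({"trial": i, "component": comp.name, "present": present,
                         "jitter_s": jitter if present else 0.0,
                         "amplitude_uv": amp if present else 0.0})
            if not present:
                continue
            t0 = t_ev + comp.peak_latency + jitter - comp.width / 2
            j0 = max(int(math.ceil(t0 * cfg.rate)), 0)
            j1 = min(int(math.floor((t0 + comp.width) * cfg.rate)) + 1, n)
            seg = t_axis[j0:j1]
            x[j0:j1] += comp.polarity * amp * np.sin(np.pi * (seg - t0) / comp.width)

    rec = Recording(x, rate=cfg.rate, channel_names=("sim",), start_time=0.0)
    ev = EventSeries(times)
    truth = pd.DataFrame(rows)
    return rec, ev, truth


def reference_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A session resembling the motivating experiment: 131 stimuli and three
    components — positive peaks near 200 and 500 ms and a negative one near
    340 ms post-stimulus — each present in only part of the trials.

    Keyword overrides that name a :class:`SimulationConfig` field replace it;
    ``presence_prob``, ``amplitude_mean``, ``amplitude_sd`` and ``jitter_sd``
    are applied to all three components at once.
    """
    comp_keys = {"presence_prob", "amplitude_mean", "amplitude_sd", "jitter_sd"}
    comp_over = {k: overrides.pop(k) for k in list(overrides) if k in comp_keys}
    components = [
        ComponentModel("P200", +1, 0.200, 0.12, 20.0, 5.0, 0.6, 0.01),
        ComponentModel("N340", -1, 0.340, 0.12, 20.0, 5.0, 0.6, 0.01),
        ComponentModel("P500", +1, 0.500, 0.16, 20.0, 5.0, 0.6, 0.01),
    ]
    if comp_over:
        components = [replace(c, **comp_over) for c in components]
    return SimulationConfig(components=components, seed=seed, **overrides)
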