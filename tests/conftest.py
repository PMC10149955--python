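import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import erptrials as et

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_session():
    """A short noise-free session: every trial contains every component,
    no jitter, no amplitude spread — the averaged ERP equals each trial."""
    cfg = et.reference_config(seed=42, n_trials=12, noise_sd=0.0,
                               presence_prob=1.0, jitter_sd=0.0,
                               amplitude_sd=0.0)
    rec, ev, truth = et.generate(cfg)
    return cfg, rec, ev, truth


@pytest.fixture(scope="session")
def noisy_session():
    """A realistic short session: components present in half the trials at
    3x the in-window noise RMS, no jitter."""
    cfg = et.reference_config(seed=7, n_trials=60, presence_prob=0.5,
                               amplitude_mean=60.0, jitter_sd=0.0)
    rec, ev, truth = et.generate(cfg)
    tm = et.extract_epochs(rec, ev, 1.0, 1.0)
    return cfg, rec, ev, truth, tm


def component_specs(cfg):
    """Analysis windows matching the generator's nominal component supports."""
    return [et.ComponentSpec(c.name, c.polarity, c.window, c.peak_latency)
            for c in cfg.components]
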