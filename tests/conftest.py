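"""Shared fixtures: small simulated datasets built once per session."""

import numpy as np
import pytest

from rsvpweak.conditions import make_condition_table
from rsvpweak.pipeline import make_fixtures, subject_epochs
from rsvpweak.preprocess import preprocess_recording
from rsvpweak.schedule import schedule_to_events
from rsvpweak.simulate import SimulationConfig

TINY_CHANNELS = ("Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz", "P3")


@pytest.fixture(scope="session")
def tiny_recordings():
    """One simulated session on 8 channels, with its events table."""
    recs, events = make_fixtures("tiny", seed=5)
    return recs, events


@pytest.fixture(scope="session")
def tiny_epochs(tiny_recordings):
    """Preprocessed epochs of the tiny session (1500 epochs, 8 ch, 125 Hz)."""
    recs, _ = tiny_recordings
    rec = recs[0]
    events = schedule_to_events(rec.schedules)
    return preprocess_recording(rec, events)


@pytest.fixture(scope="session")
def noiseless_epochs():
    """Deterministic single-session data: no noise, no trial jitter, no
    secondary components. The measurement-gain compensation stays on, so the
    preprocessed target average must reproduce the injected calibration."""
    import dataclasses

    conds = [dataclasses.replace(c, erp_amplitude_sd=0.0, erp_latency_sd=0.0)
             for c in make_condition_table()]
    # a long inter-trial interval keeps each trial clear of its neighbors'
    # slow high-pass undershoot tails, so recovery is exact, not just close
    cfg = SimulationConfig(seed=3, n_sessions=1, conditions=conds,
                           channels=TINY_CHANNELS, noise_sd=0.0, secondary=(),
                           iti_ms=4000)
    return cfg, subject_epochs(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
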