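"""Shared fixtures: small synthetic sessions and hand-built micro-sessions."""

import numpy as np
import pandas as pd
import pytest

from popsubspace.session import (
    PositionTrack,
    SessionRecording,
    SleepEpochs,
    SpikeTrainSet,
    TrialTable,
)
from popsubspace.synth import SynthConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """One deterministic mid-sized synthetic session with healthy activity."""
    cfg = SynthConfig(
        n_neurons=10,
        n_trials=14,
        baseline_log_rate_mean=np.log(8.0),
        baseline_log_rate_sd=0.6,
        sleep_epoch_length=120.0,
    )
    session, truth = generate_session(cfg, 11)
    return session, truth


def make_manual_session(
    trains: dict,
    trial_rows: list,
    pos: tuple | None = None,
    sleep: dict | None = None,
    metadata: dict | None = None,
) -> SessionRecording:
    """Assemble a SessionRecording from explicit arrays (no validation side effects)."""
    trials = pd.DataFrame(
        trial_rows,
        columns=["trial", "t_start_s", "t_armend_s", "t_iti_end_s", "direction", "light", "outcome"],
    )
    if pos is None:
        t0 = trials["t_start_s"].min() - 1.0
        t1 = trials["t_iti_end_s"].max() + 1.0
        t = np.arange(t0, t1, 1.0 / 30.0)
        pos = (t, np.zeros_like(t), np.full_like(t, -85.0))
    if sleep is None:
        t0 = float(trials["t_start_s"].min())
        t1 = float(trials["t_iti_end_s"].max())
        sleep = {"pre": [(t0 - 60.0, t0 - 10.0)], "post": [(t1 + 10.0, t1 + 60.0)]}
    meta = {
        "rat_id": "manual",
        "rule_name": "go to the lit arm",
        "rule_class": "cue",
        "rule_change_trial": None,
        "maze": {"arm_length_cm": 85.0, "n_arms": 3, "arm_separation_deg": 120.0},
    }
    if metadata:
        meta.update(metadata)
    return SessionRecording(
        spikes=SpikeTrainSet(trains={k: np.asarray(v, dtype=float) for k, v in trains.items()}),
        position=PositionTrack(t=np.asarray(pos[0], float), x=np.asarray(pos[1], float), y=np.asarray(pos[2], float)),
        trials=TrialTable(frame=trials),
        sleep=SleepEpochs(intervals=sleep),
        metadata=meta,
    )


@pytest.fixture
def manual_session_factory():
    return make_manual_session
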