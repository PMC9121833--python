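"""Active-neuron selection, rate vectors, maze linearization, phase detection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popsubspace.segmentation import (
    SegmentationError,
    build_phase_matrix,
    detect_outbound_starts,
    linearize_position,
    phase_intervals,
    phase_rate_vectors,
    section_rate_vectors,
    select_active_neurons,
    trial_iti_rate_correlation,
)
from popsubspace.synth import SynthConfig, generate_session

TRIALS_3 = [
    (1, 0.0, 2.0, 10.0, "left", "left", 1),
    (2, 10.0, 12.0, 20.0, "right", "left", 0),
    (3, 20.0, 21.5, 30.0, "right", "right", 1),
]


def test_active_selection_requires_spike_every_trial(manual_session_factory):
    trains = {
        0: [0.5, 1.0, 10.5, 20.5],          # spikes in all three trials
        1: [0.5, 20.5],                      # silent in trial 2 -> excluded
        2: [3.0, 13.0, 23.0],                # only ITIs -> excluded
    }
    s = manual_session_factory(trains, TRIALS_3)
    assert select_active_neurons(s) == [0]


def test_active_selection_all_silent_errors(manual_session_factory):
    s = manual_session_factory({0: [5.0], 1: [6.0]}, TRIALS_3)
    with pytest.raises(SegmentationError, match="no active neurons"):
        select_active_neurons(s)


def test_rate_is_count_over_duration(manual_session_factory):
    # trial 3 lasts 1.5 s and contains 3 spikes of neuron 0 -> 2.0 Hz
    trains = {0: [0.5, 10.5, 20.1, 20.2, 21.0]}
    s = manual_session_factory(trains, TRIALS_3)
    rv = phase_rate_vectors(s, "trial", active_ids=[0])
    assert rv.rates[2, 0] == pytest.approx(3 / 1.5)
    # empty ITI -> 0 Hz
    rvi = phase_rate_vectors(s, "iti", active_ids=[0])
    assert rvi.rates[2, 0] == 0.0


def test_poisson_rate_estimate_within_3_se():
    cfg = SynthConfig(
        n_neurons=4, n_trials=200, baseline_log_rate_mean=np.log(5.0), baseline_log_rate_sd=0.0,
        phase_separation=0.0, feature_gain={f: 0.0 for f in ("direction", "light", "outcome")},
        rate_noise_sd=0.0, sleep_epoch_length=30.0, trial_duration_mean=6.5,
    )
    s, truth = generate_session(cfg, 12)
    active = select_active_neurons(s)
    rv = phase_rate_vectors(s, "trial", active)
    lam = np.maximum(truth.baseline_rates, 0.1)[0]
    total = float((s.trials.frame["t_armend_s"] - s.trials.frame["t_start_s"]).sum())
    se = np.sqrt(lam / total)
    assert abs(rv.rates[:, 0].mean() - lam) < 3.5 * se


def test_linearize_endpoints_and_center(manual_session_factory, small_session):
    # samples exactly at the skeleton landmarks of one trial
    t = [0.2, 0.8, 1.4]
    xy = np.array([[0.0, -85.0], [0.0, 0.0]])
    arm_end_right = 85.0 * np.array([np.cos(np.pi / 6), np.sin(np.pi / 6)])
    pos = (np.array(t), np.array([0.0, 0.0, arm_end_right[0]]), np.array([-85.0, 0.0, arm_end_right[1]]))
    s = manual_session_factory({0: [0.5, 10.5, 20.5]}, TRIALS_3[:1], pos=pos)
    s.trials.frame.loc[0, "direction"] = "right"
    lin = linearize_position(s)
    assert lin["coord"].tolist() == pytest.approx([0.0, 0.5, 1.0])
    assert lin["section"].tolist() == [1, 3, 5]


def test_sections_cover_equal_fifths_of_uniform_traversal(small_session):
    session, _ = small_session
    lin = linearize_position(session)
    df = session.trials.frame
    row = df.iloc[0]
    sel = lin[(lin["trial"] == 1) & (lin["time_s"] < row["t_armend_s"])]
    counts = sel["section"].value_counts(normalize=True)
    # uniform-speed outward run: each section holds ~1/5 of the samples
    for p in range(1, 6):
        assert counts.get(p, 0.0) == pytest.approx(0.2, abs=0.08)


def test_section_rates_localize_spikes(manual_session_factory):
    # uniform outward run 0->10 s; spikes only in the last fifth (section 5)
    t = np.arange(0.0, 10.0, 1 / 30)
    frac = t / 10.0
    start = np.array([0.0, -85.0])
    center = np.zeros(2)
    arm = 85.0 * np.array([np.cos(np.pi / 6), np.sin(np.pi / 6)])
    pts = np.where(
        (frac < 0.5)[:, None], start + (frac * 2)[:, None] * (center - start),
        center + ((frac - 0.5) * 2)[:, None] * (arm - center),
    )
    trial_rows = [(1, 0.0, 10.0, 12.0, "right", "right", 1)]
    spikes = {0: list(np.arange(8.05, 9.95, 0.1)), 1: list(np.arange(0.05, 9.95, 0.5))}
    s = manual_session_factory(spikes, trial_rows, pos=(t, pts[:, 0], pts[:, 1]))
    for p in (1, 2, 3, 4):
        rv = section_rate_vectors(s, "trial", p, active_ids=[0, 1])
        assert rv.rates[0, 0] == 0.0
        assert rv.rates[0, 1] > 0.0
    rv5 = section_rate_vectors(s, "trial", 5, active_ids=[0, 1])
    assert rv5.rates[0, 0] > 5.0


def test_outbound_reversal_detected_within_one_sample():
    cfg = SynthConfig(n_neurons=6, n_trials=10, sleep_epoch_length=30.0, outbound_delay=1.14)
    s, _ = generate_session(cfg, 21)
    ob = detect_outbound_starts(s)
    assert not ob["degenerate"].any()
    assert abs(ob["delay_s"].median() - 1.14) <= 1 / 30 + 1e-9


def test_outbound_immediate_reversal_small_delay():
    # without the arm-end pause the 3-sample smoothing defers detection by
    # up to ~3 samples (the slow return must overcome the outward smear)
    cfg = SynthConfig(n_neurons=6, n_trials=10, sleep_epoch_length=30.0, outbound_delay=0.0)
    s, _ = generate_session(cfg, 21)
    ob = detect_outbound_starts(s)
    assert (ob["delay_s"] <= 3.5 / 30 + 1e-9).all()


def test_outbound_never_turning_flagged(manual_session_factory):
    # trajectory parked at the arm end for the whole ITI
    t = np.arange(0.0, 30.0, 1 / 30)
    arm = 85.0 * np.array([np.cos(np.pi / 6), np.sin(np.pi / 6)])
    x = np.full_like(t, arm[0])
    y = np.full_like(t, arm[1])
    s = manual_session_factory({0: [0.5]}, [(1, 0.0, 2.0, 29.0, "right", "right", 1)], pos=(t, x, y))
    ob = detect_outbound_starts(s)
    assert bool(ob["degenerate"].iloc[0])
    assert ob["outbound_start_s"].iloc[0] == pytest.approx(29.0)


def test_phase_matrix_interleaves_in_temporal_order(manual_session_factory):
    trains = {0: [0.5, 1.0, 10.5, 20.5], 1: [0.2, 10.2, 11.0, 20.2]}
    s = manual_session_factory(trains, TRIALS_3)
    active = select_active_neurons(s)
    pm = build_phase_matrix(s, active)
    assert pm.matrix.shape == (6, len(active))
    assert list(pm.labels) == ["trial", "iti"] * 3
    rt = phase_rate_vectors(s, "trial", active)
    ri = phase_rate_vectors(s, "iti", active)
    for k in range(3):
        assert np.array_equal(pm.matrix[2 * k], rt.rates[k])
        assert np.array_equal(pm.matrix[2 * k + 1], ri.rates[k])


def test_inbound_equals_trial_when_outbound_starts_at_armend(small_session):
    session, _ = small_session
    df = session.trials.frame
    ob = pd.DataFrame(
        {"trial": df["trial"], "outbound_start_s": df["t_armend_s"], "delay_s": 0.0, "degenerate": False}
    )
    assert np.array_equal(
        phase_intervals(session, "inbound", ob), phase_intervals(session, "trial")
    )
    assert np.array_equal(
        phase_intervals(session, "outbound", ob), phase_intervals(session, "iti")
    )


def test_trial_iti_rank_correlation_matches_scipy(small_session):
    session, _ = small_session
    active = select_active_neurons(session)
    out = trial_iti_rate_correlation(session, active)
    rt = phase_rate_vectors(session, "trial", active)
    ri = phase_rate_vectors(session, "iti", active)
    i = 0
    rho, p = stats.spearmanr(rt.rates[i], ri.rates[i])
    assert out["spearman_rho"].iloc[i] == pytest.approx(rho)
    assert out["p_value"].iloc[i] == pytest.approx(p)
    assert out["spearman_rho"].abs().max() <= 1.0
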