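"""Sleep binning, rank-correlation oracle, and reactivation statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popsubspace.reactivation import (
    SWEEP_GRID,
    ReactivationResult,
    binsize_sweep,
    feature_mean_vector,
    mean_vector_angles,
    pre_post_reactivation_correlation,
    reactivation_distributions,
    reactivation_vs_performance,
    sleep_bin_vectors,
    spearman_to_bins,
)
from popsubspace.segmentation import select_active_neurons
from popsubspace.synth import SynthConfig, generate_session

rng = np.random.default_rng(17)


def brute_force_spearman(a, b):
    """Average ranks by hand, then the Pearson formula."""
    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), float)
        i = 0
        sv = np.asarray(v, float)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    ra, rb = avg_ranks(a), avg_ranks(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float(ra @ rb / np.sqrt((ra @ ra) * (rb @ rb)))


def test_spearman_matches_brute_force_on_tied_inputs():
    """Vectorized rank correlation equals the hand-rolled oracle (and scipy)
    on hundreds of short tied and untied vectors."""
    for _ in range(300):
        n = int(rng.integers(3, 9))
        a = rng.integers(0, 4, size=n).astype(float)  # heavy ties
        b = rng.integers(0, 4, size=n).astype(float)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        got, dropped = spearman_to_bins(a, b.reshape(1, -1))
        assert dropped == 0
        assert got[0] == pytest.approx(brute_force_spearman(a, b), abs=1e-12)
        assert got[0] == pytest.approx(stats.spearmanr(a, b).statistic, abs=1e-12)


def test_spearman_invariant_to_monotone_transform():
    v = rng.normal(size=8)
    B = rng.normal(size=(5, 8))
    c1, _ = spearman_to_bins(v, B)
    c2, _ = spearman_to_bins(np.exp(v), B)
    assert np.allclose(c1, c2)


def test_spearman_drops_constant_bins():
    v = np.arange(6.0)
    B = np.vstack([np.ones(6), rng.normal(size=6)])
    c, dropped = spearman_to_bins(v, B)
    assert dropped == 1 and len(c) == 1
    with pytest.raises(ValueError, match="constant feature vector"):
        spearman_to_bins(np.ones(6), B)


def test_feature_mean_vector_arithmetic():
    X = np.array([[1.0, 1.0], [3.0, 3.0], [10.0, 0.0]])
    labels = np.array(["a", "a", "b"])
    assert np.allclose(feature_mean_vector(X, labels, "a"), [2.0, 2.0])
    assert np.allclose(feature_mean_vector(X, labels, "b"), [10.0, 0.0])
    grand = (2 * feature_mean_vector(X, labels, "a") + 1 * feature_mean_vector(X, labels, "b")) / 3
    assert np.allclose(grand, X.mean(axis=0))
    with pytest.raises(ValueError, match="no rows"):
        feature_mean_vector(X, labels, "c")


def test_sleep_bin_counts(small_session):
    session, _ = small_session
    active = select_active_neurons(session)
    for bin_s in (1.0, 0.7, 3.0):
        sv = sleep_bin_vectors(session, "pre", bin_s, active)
        expected = sum(int(np.floor((b - a) / bin_s + 1e-9)) for a, b in session.sleep.epoch("pre"))
        assert sv.rates.shape == (expected, len(active))
    with pytest.raises(ValueError, match="no usable bins"):
        sleep_bin_vectors(session, "pre", 1e6, active)


def test_partial_trailing_bin_dropped(manual_session_factory):
    s = manual_session_factory(
        {0: [0.5, 10.5, 20.5], 1: [0.6, 10.6, 20.6], 2: [0.7, 10.7, 20.7]},
        [(1, 0.0, 2.0, 10.0, "left", "left", 1)],
        sleep={"pre": [(-10.0, -7.5)], "post": [(20.0, 30.0)]},
    )
    sv = sleep_bin_vectors(s, "pre", 1.0, [0, 1, 2])
    assert len(sv.bin_starts) == 2  # [0,2.5) tiles into 2 full 1 s bins
    sv_post = sleep_bin_vectors(s, "post", 1.0, [0, 1, 2])
    assert len(sv_post.bin_starts) == 10


def test_sweep_grid_has_67_sizes():
    assert len(SWEEP_GRID) == 67
    assert SWEEP_GRID[0] == pytest.approx(0.1)
    assert SWEEP_GRID[-1] == pytest.approx(10.0)
    assert np.allclose(np.diff(SWEEP_GRID), 0.15)


def test_statistic_is_median_difference():
    res = ReactivationResult(
        feature="direction", value="right", source="trial", bin_s=1.0,
        pre_correlations=np.full(9, 0.1), post_correlations=np.full(7, 0.3),
    )
    assert res.statistic == pytest.approx(0.2)
    assert res.m_pre == pytest.approx(0.1)
    assert res.m_post == pytest.approx(0.3)


def test_statistic_invariant_to_sws_interval_order(small_session):
    session, _ = small_session
    active = select_active_neurons(session)
    r1 = reactivation_distributions(session, "direction", "right", active_ids=active)
    (a, b), = session.sleep.epoch("pre")
    mid = a + np.floor((b - a) / 2)
    session.sleep.intervals["pre"] = [(mid, b), (a, mid)]
    session.sleep.intervals["pre"].sort()
    r2 = reactivation_distributions(session, "direction", "right", active_ids=active)
    assert r2.statistic == pytest.approx(r1.statistic)
    session.sleep.intervals["pre"] = [(a, b)]


def test_implanted_reactivation_detected_across_bin_sizes():
    cfg = SynthConfig(
        n_neurons=12, n_trials=14, sleep_epoch_length=400.0,
        baseline_log_rate_mean=np.log(8.0), baseline_log_rate_sd=0.8,
        rho_pre=0.05, rho_post=0.5,
    )
    s, _ = generate_session(cfg, 2)
    active = select_active_neurons(s)
    res = reactivation_distributions(s, "direction", "right", active_ids=active)
    assert res.statistic > 0
    assert res.ks_p < 0.05
    sweep = binsize_sweep(s, source="trial", features=("direction",), grid=np.array([0.55, 1.0, 1.45]), active_ids=active)
    near = sweep[(sweep["feature"] == "direction") & (sweep["value"] == "right")]
    # implanted at 1 s: the statistic stays positive at neighboring bin sizes
    assert (near["statistic"] > 0).all()


def test_pre_post_correlation_table():
    frames = []
    r = np.random.default_rng(5)
    pre = r.normal(0.2, 0.05, 8)
    frames.append(pd.DataFrame({
        "session": [f"s{i}" for i in range(8)], "source": "trial",
        "feature": "direction", "value": "right",
        "m_pre": pre, "m_post": pre * 2 + r.normal(0, 0.001, 8),
    }))
    out = pre_post_reactivation_correlation(pd.concat(frames))
    assert out["rho"].iloc[0] > 0.9
    with pytest.raises(ValueError, match=">= 5"):
        pre_post_reactivation_correlation(frames[0].iloc[:3])


def test_reactivation_vs_performance_link():
    d = np.linspace(0, 0.8, 10)
    s = d * 0.5 + np.random.default_rng(0).normal(0, 0.01, 10)
    rho, p = reactivation_vs_performance(s, d)
    assert rho > 0.9 and p < 0.05
    rho, p = reactivation_vs_performance(s, np.full(10, 0.3))
    assert np.isnan(rho)
    with pytest.raises(ValueError, match="delta_r"):
        reactivation_vs_performance(s[:3], d[:3])


def test_mean_vectors_aligned_while_axes_orthogonal():
    """Shared baseline keeps mean activity aligned across phases even when the
    coding axes are implanted orthogonal."""
    cfg = SynthConfig(
        n_neurons=12, n_trials=20, sleep_epoch_length=40.0,
        baseline_log_rate_mean=20.0, baseline_log_rate_sd=0.3,
        feature_gain={f: 8.0 for f in ("direction", "light", "outcome")},
        implanted_angle={f: np.pi / 2 for f in ("direction", "light", "outcome")},
        phase_separation=1.0, rate_noise_sd=1.0,
    )
    s, _ = generate_session(cfg, 6)
    df = mean_vector_angles(s)
    assert (df["mean_vector_angle"] < df["decoding_axis_angle"]).mean() >= 0.8
    assert df["mean_vector_angle"].between(0, np.pi).all()
    assert df["mean_vector_angle"].median() < 0.1 * np.pi
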