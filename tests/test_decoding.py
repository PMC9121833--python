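"""Decoder correctness against brute-force refits, axis geometry, cross-decoding."""

import math

import numpy as np
import pytest
from scipy import optimize

from popsubspace.decoding import (
    DegenerateLabelsError,
    aligned_labels,
    angle_between,
    cross_decode,
    decoding_vs_performance,
    fit_decoder_axis,
    loo_decode,
    position_decoding_profile,
    shuffled_chance,
)
from popsubspace.segmentation import select_active_neurons
from popsubspace.synth import SynthConfig, generate_session

rng = np.random.default_rng(7)


def brute_force_logistic(X, y, C=1.0):
    """Independent optimizer for the standardized L2 logistic objective."""
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    s = 2.0 * y - 1.0

    def obj(wb):
        w, b = wb[:-1], wb[-1]
        m = s * (Z @ w + b)
        return 0.5 * w @ w + C * np.sum(np.logaddexp(0.0, -m))

    res = optimize.minimize(obj, np.zeros(X.shape[1] + 1), method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    w, b = res.x[:-1], res.x[-1]
    return w, b, mu, sd


def brute_force_loo_predictions(X, y):
    preds = np.empty(len(y), dtype=int)
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        w, b, mu, sd = brute_force_logistic(X[mask], y[mask])
        p = 1.0 / (1.0 + np.exp(-(((X[i] - mu) / sd) @ w + b)))
        preds[i] = int(p >= 0.5)
    return preds


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_loo_predictions_match_brute_force_refit(seed):
    """Per-fold predictions agree with an independent optimizer (T=6, N=3)."""
    r = np.random.default_rng(seed)
    X = r.normal(size=(6, 3)) + np.outer(np.repeat([0, 1], 3), [1.0, -0.5, 0.2])
    y = np.repeat([0, 1], 3)
    res = loo_decode(X, y)
    assert np.array_equal(res.predictions, brute_force_loo_predictions(X, y))


def test_well_separated_classes_decode_perfectly():
    X = np.vstack([rng.normal(-4, 0.3, size=(4, 3)), rng.normal(4, 0.3, size=(4, 3))])
    y = np.repeat(["a", "b"], 4)
    assert loo_decode(X, y).accuracy == 1.0


def test_uninformative_activity_within_permutation_band():
    X = rng.normal(size=(24, 5))
    y = np.tile(["l", "r"], 12)
    acc = loo_decode(X, y).accuracy
    nulls = shuffled_chance(X, y, reps=99, seed=5)
    lo, hi = np.quantile(nulls, [0.025, 0.975])
    assert lo - 1e-9 <= acc <= hi + 1e-9


def test_degenerate_labels_rejected():
    X = rng.normal(size=(8, 3))
    with pytest.raises(DegenerateLabelsError):
        loo_decode(X, np.zeros(8))


def test_shuffled_chance_seeded_and_sized():
    X = rng.normal(size=(10, 3))
    y = np.tile([0, 1], 5)
    a = shuffled_chance(X, y, reps=50, seed=3)
    b = shuffled_chance(X, y, reps=50, seed=3)
    assert len(a) == 50
    assert np.array_equal(a, b)


def test_decoder_axis_recovers_implanted_direction():
    # equal-magnitude components keep per-feature variances homogeneous, so
    # the per-fold standardization does not tilt the recovered direction
    c = np.array([1.0, -1.0, 1.0, 1.0]) / 2.0
    x = np.repeat([-1.0, 1.0], 40)
    X = 3.0 * np.outer(x, c) + rng.normal(0, 1.0, size=(80, 4)) + 10.0
    axis = fit_decoder_axis(X, (x > 0).astype(int))
    ang = angle_between(axis.weights, c)
    assert min(ang, math.pi - ang) < 0.1 * math.pi


def test_decoder_axis_label_flip_negates_weights():
    X = rng.normal(size=(20, 4)) + np.outer(np.tile([0, 1], 10), [1.0, 0, -1.0, 0.5])
    y = np.tile([0, 1], 10)
    w1 = fit_decoder_axis(X, y).weights
    w2 = fit_decoder_axis(X, 1 - y).weights
    assert np.allclose(w1, -w2, atol=1e-6)


def test_decoder_axis_invariant_to_row_duplication():
    X = rng.normal(size=(16, 3)) + np.outer(np.tile([0, 1], 8), [0.8, -0.3, 0.1])
    y = np.tile([0, 1], 8)
    w1 = fit_decoder_axis(X, y).weights
    w2 = fit_decoder_axis(np.vstack([X, X]), np.concatenate([y, y])).weights
    # duplication halves the effective regularization, so the direction is
    # preserved only up to the (weak) penalty's pull
    assert angle_between(w1, w2) < 0.05


@pytest.mark.parametrize(
    "u, v, expected",
    [((1, 0), (0, 1), math.pi / 2), ((1, 0), (1, 0), 0.0), ((1, 0), (-1, 0), math.pi), ((1, 0), (1, 1), math.pi / 4)],
)
def test_angle_between_closed_forms(u, v, expected):
    assert angle_between(np.array(u, float), np.array(v, float)) == pytest.approx(expected)


def test_angle_between_properties():
    u, v = rng.normal(size=4), rng.normal(size=4)
    a = angle_between(u, v)
    assert angle_between(v, u) == pytest.approx(a)
    assert angle_between(2.5 * u, 0.3 * v) == pytest.approx(a)
    assert angle_between(u, -v) == pytest.approx(math.pi - a)
    with pytest.raises(ValueError, match="undefined angle"):
        angle_between(u, np.zeros(4))


def test_cross_decode_training_set_optimism():
    X = rng.normal(size=(16, 4)) + np.outer(np.tile([0, 1], 8), [1.0, 0.5, -0.5, 0])
    y = np.tile([0, 1], 8)
    full = cross_decode((X, y), (X, y), mode="full").accuracy
    loo = cross_decode((X, y), (X, y), mode="loo").accuracy
    assert full >= loo


def test_cross_decode_aligned_vs_orthogonal_axes():
    """Shared coding axis transfers across sets; orthogonal axes do not."""
    c1 = np.array([1.0, 0, 0, 0])
    c2 = np.array([0, 1.0, 0, 0])
    x = np.tile([-1.0, 1.0], 15)
    y = (x > 0).astype(int)
    A = 4.0 * np.outer(x, c1) + rng.normal(0, 0.5, size=(30, 4))
    B_aligned = 4.0 * np.outer(x, c1) + rng.normal(0, 0.5, size=(30, 4)) + 3.0
    B_orth = 4.0 * np.outer(x, c2) + rng.normal(0, 0.5, size=(30, 4)) + 3.0
    within = loo_decode(A, y).accuracy
    acc_aligned = cross_decode((A, y), (B_aligned, y), mode="full").accuracy
    res_orth = cross_decode((A, y), (B_orth, y), mode="full", null_reps=50, seed=2)
    assert abs(acc_aligned - within) <= 0.1
    lo, hi = np.quantile(res_orth.null_accuracies, [0.025, 0.975])
    assert lo - 1e-9 <= res_orth.accuracy <= hi + 1e-9


def test_aligned_labels_reference_shifts():
    labels = np.array([10, 20, 30, 40])
    idx, lab = aligned_labels(labels, "trial", "previous")
    assert idx.tolist() == [1, 2, 3] and lab.tolist() == [10, 20, 30]
    idx, lab = aligned_labels(labels, "trial", "following")
    assert idx.tolist() == [0, 1, 2] and lab.tolist() == [20, 30, 40]
    # the ITI after trial i carries trial i's labels as its "previous" trial
    idx, lab = aligned_labels(labels, "iti", "previous")
    assert idx.tolist() == [0, 1, 2, 3] and lab.tolist() == [10, 20, 30, 40]
    # shifting to the previous then asking for the following realigns
    idx1, lab1 = aligned_labels(labels, "trial", "previous")
    idx2, lab2 = aligned_labels(lab1, "trial", "following")
    assert lab2.tolist() == labels[idx1[idx2] ].tolist()


def test_decoding_vs_performance_link_and_errors():
    perf = np.linspace(0.3, 0.9, 12)
    acc = 0.5 * perf + rng.normal(0, 0.01, 12)
    rho, p, slope = decoding_vs_performance(acc, perf)
    assert rho > 0.9 and p < 0.05 and slope > 0
    rho, p, slope = decoding_vs_performance(np.full(6, 0.2), perf[:6])
    assert np.isnan(rho)
    with pytest.raises(ValueError, match=">= 5"):
        decoding_vs_performance(acc[:2], perf[:2])


def test_position_profile_detects_section_specific_coding(manual_session_factory):
    """Labels implanted only in maze sections 3-5 decode only there."""
    r = np.random.default_rng(0)
    T = 16
    t_all, x_all, y_all, rows = [], [], [], []
    start = np.array([0.0, -85.0])
    center = np.zeros(2)
    arms = {
        "right": 85.0 * np.array([np.cos(np.pi / 6), np.sin(np.pi / 6)]),
        "left": 85.0 * np.array([np.cos(5 * np.pi / 6), np.sin(5 * np.pi / 6)]),
    }
    trains = {n: [] for n in range(6)}
    t0 = 0.0
    labels = np.tile(["left", "right"], T // 2)
    for i in range(T):
        dur_t, dur_i = 10.0, 12.0
        arm = arms[labels[i]]
        tt = np.arange(t0, t0 + dur_t + dur_i, 1 / 30)
        frac = np.where(tt < t0 + dur_t, (tt - t0) / dur_t, 1 - (tt - t0 - dur_t) / dur_i)
        pts = np.where(
            (frac < 0.5)[:, None], start + (frac * 2)[:, None] * (center - start),
            center + ((frac - 0.5) * 2)[:, None] * (arm - center),
        )
        t_all.append(tt)
        x_all.append(pts[:, 0])
        y_all.append(pts[:, 1])
        rows.append((i + 1, round(t0, 4), round(t0 + dur_t, 4), round(t0 + dur_t + dur_i, 4), labels[i], "right", 1))
        # outward run: sections 1-2 during [t0, t0+4), sections 3-5 in [t0+4, t0+10)
        hot = labels[i] == "right"
        for n in range(6):
            base = 6.0
            gain = (8.0 if (hot == (n % 2 == 0)) else 0.0)
            for a, b, rate in ((t0, t0 + 4.0, base), (t0 + 4.0, t0 + dur_t, base + gain), (t0 + dur_t, t0 + dur_t + dur_i, base)):
                k = r.poisson(rate * (b - a))
                trains[n].extend(a + r.random(k) * (b - a))
        t0 += dur_t + dur_i
    s = manual_session_factory(
        {n: np.sort(v) for n, v in trains.items()},
        rows,
        pos=(np.concatenate(t_all), np.concatenate(x_all), np.concatenate(y_all)),
    )
    prof = position_decoding_profile(s, "direction", reference="current", reps=20, seed=1, include_cross=False)
    tr = prof[prof["phase"] == "trial"].set_index("section")
    assert tr.loc[4, "relative_accuracy"] > 0.25
    assert tr.loc[5, "relative_accuracy"] > 0.25
    assert tr.loc[1, "accuracy"] <= tr.loc[1, "null_q975"]
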