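"""Synthetic session generator with implanted, recoverable structure.

The generator emits sessions with exactly the statistical structure the
analyses probe, plus the ground truth needed for parameter-recovery tests:

* two phase subspaces — trial and ITI mean-rate vectors shifted by a
  controllable amount ``phase_separation`` along a random unit direction;
* task-feature coding along unit axes, with a controllable angle between the
  trial-phase and ITI-phase coding axis of each feature.  Trial activity
  encodes the CURRENT trial's labels; ITI activity encodes the labels of the
  trial the animal just completed (the preceding trial, in the convention
  that ITI(i) follows trial i);
* a behavioral change point: success probability steps from ``p_before`` to
  ``p_after`` at ``learning_trial``;
* homogeneous Poisson spiking within each phase at the phase's rate vector;
* a piecewise-linear trajectory along the maze skeleton, with the heading
  reversal placed ``outbound_delay`` seconds after the arm-end arrival;
* sleep epochs tiled with 1 s segments that are, with probability
  ``rho_pre``/``rho_post``, noisy scaled copies of a feature-specific trial
  mean-rate vector (reactivation) and otherwise permuted baseline activity.

Identical ``(config, seed)`` produce identical sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .session import (
    InvalidSessionError,
    MazeGeometry,
    PositionTrack,
    SessionRecording,
    SleepEpochs,
    SpikeTrainSet,
    TrialTable,
    quantize_times,
)
import pandas as pd

__all__ = ["SynthConfig", "GroundTruth", "generate_session", "generate_cohort", "FEATURES"]

FEATURES = ("direction", "light", "outcome")

#: floor applied to every generated rate (Hz); keeps Poisson rates positive
RATE_FLOOR = 0.1


@dataclass
class SynthConfig:
    """Parameters of the generative model (rates in Hz, durations in s).

    Defaults follow the study conditions the analyses assume: trials of
    6.5 +/- 0.5 s, long self-paced ITIs near 55.6 s, ~12-neuron populations,
    a 1.14 s outbound delay, and pre/post sleep epochs of 20 min.
    """

    n_neurons: int = 12
    n_trials: int = 30
    baseline_log_rate_mean: float = math.log(5.0)
    baseline_log_rate_sd: float = 0.5
    phase_separation: float = 4.0
    feature_gain: dict = field(default_factory=lambda: {f: 2.0 for f in FEATURES})
    implanted_angle: dict = field(default_factory=lambda: {f: math.pi / 2 for f in FEATURES})
    rate_noise_sd: float = 0.5
    trial_duration_mean: float = 6.5
    trial_duration_sd: float = 0.5
    iti_duration_mean: float = 55.6
    iti_duration_sd: float = 5.0
    outbound_delay: float = 1.14
    learning_trial: int | None = None
    p_before: float = 0.4
    p_after: float = 0.85
    lapse_rate: float = 0.05
    rule_name: str = "go to the lit arm"
    rule_class: str = "cue"  # {"direction", "cue"}
    rule_change_trial: int | None = None
    sleep_epoch_length: float = 1200.0
    rho_pre: float = 0.1
    rho_post: float = 0.4
    reactivation_noise_sd: float = 0.3
    tracking_rate_hz: float = 30.0
    rat_id: str = "synth"
    seed: int = 0  # default stream; generate_session's argument overrides

    def validate(self) -> None:
        if self.n_neurons < 1 or self.n_trials < 1:
            raise ValueError("n_neurons and n_trials must be >= 1")
        if self.phase_separation < 0 or self.rate_noise_sd < 0:
            raise ValueError("rates, gains and noise must be nonnegative")
        for f, g in self.feature_gain.items():
            if g < 0:
                raise ValueError(f"feature gain for {f} must be nonnegative")
        for f, a in self.implanted_angle.items():
            if not (0.0 <= a <= math.pi):
                raise ValueError(f"implanted angle for {f} must lie in [0, pi]")
            if a > 0 and self.n_neurons < 2:
                raise ValueError("cannot embed two axes: need N >= 2 for a nonzero angle")
        for p in (self.p_before, self.p_after, self.rho_pre, self.rho_post, self.lapse_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.rule_class not in ("direction", "cue"):
            raise ValueError("rule_class must be 'direction' or 'cue'")


@dataclass
class GroundTruth:
    """Implanted parameters of one synthetic session."""

    phase_offset_direction: np.ndarray  # unit vector, length N
    coding_axes_trial: dict  # feature -> unit vector
    coding_axes_iti: dict  # feature -> unit vector
    baseline_rates: np.ndarray  # softplus-transformed baseline, Hz
    learning_trial: int | None
    rho_pre: float
    rho_post: float
    seed: int

    def to_jsonable(self) -> dict:
        return {
            "phase_offset_direction": self.phase_offset_direction.tolist(),
            "coding_axes_trial": {f: v.tolist() for f, v in self.coding_axes_trial.items()},
            "coding_axes_iti": {f: v.tolist() for f, v in self.coding_axes_iti.items()},
            "baseline_rates": self.baseline_rates.tolist(),
            "learning_trial": self.learning_trial,
            "rho_pre": self.rho_pre,
            "rho_post": self.rho_post,
            "seed": self.seed,
        }


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal(n)
    while np.linalg.norm(v) < 1e-12:
        v = rng.standard_normal(n)
    return _unit(v)


def _axis_pair(rng: np.random.Generator, n: int, angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors with the exact requested angle between them."""
    u = _random_unit(rng, n)
    if n == 1:
        return u, u.copy() if angle < math.pi / 2 else -u
    w = rng.standard_normal(n)
    w -= (w @ u) * u
    while np.linalg.norm(w) < 1e-9:
        w = rng.standard_normal(n)
        w -= (w @ u) * u
    w = _unit(w)
    v = math.cos(angle) * u + math.sin(angle) * w
    return u, _unit(v)


def _correct_direction(rule_class: str, rule_name: str, light: str) -> str:
    if rule_class == "cue":
        return light if "lit" in rule_name else ("left" if light == "right" else "right")
    return "right" if "right" in rule_name else "left"


def _poisson_trains(
    rng: np.random.Generator, starts: np.ndarray, durs: np.ndarray, rates: np.ndarray
) -> dict[int, np.ndarray]:
    """Homogeneous Poisson spikes for every (interval, neuron) rate cell.

    ``rates`` has one row per interval and one column per neuron; returns a
    sorted, 0.1 ms-quantized spike train per neuron.
    """
    counts = rng.poisson(rates * durs[:, None])
    trains = {}
    for n in range(rates.shape[1]):
        reps = counts[:, n]
        total = int(reps.sum())
        t = np.repeat(starts, reps) + rng.random(total) * np.repeat(durs, reps)
        trains[n] = quantize_times(np.sort(t))
    return trains


def generate_session(config: SynthConfig, seed: int | None = None) -> tuple[SessionRecording, GroundTruth]:
    """Generate one session plus its ground truth.  Deterministic in (config, seed)."""
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    N, T = config.n_neurons, config.n_trials

    # --- implanted structure ----------------------------------------------
    baseline = _softplus(rng.normal(config.baseline_log_rate_mean, config.baseline_log_rate_sd, N))
    offset_dir = _random_unit(rng, N)
    axes_trial: dict[str, np.ndarray] = {}
    axes_iti: dict[str, np.ndarray] = {}
    for f in FEATURES:
        a_t, a_i = _axis_pair(rng, N, config.implanted_angle.get(f, math.pi / 2))
        axes_trial[f], axes_iti[f] = a_t, a_i

    # --- behavior ----------------------------------------------------------
    lights = np.where(rng.random(T) < 0.5, "left", "right")
    outcomes = np.empty(T, dtype=int)
    directions = np.empty(T, dtype=object)
    for i in range(T):
        p = config.p_before
        if config.learning_trial is not None and (i + 1) >= config.learning_trial:
            p = config.p_after
        correct = _correct_direction(config.rule_class, config.rule_name, str(lights[i]))
        wrong = "left" if correct == "right" else "right"
        o = int(rng.random() < p)
        d = correct if o == 1 else wrong
        if rng.random() < config.lapse_rate:  # occasional label-consistent flip
            d = wrong if d == correct else correct
            o = int(d == correct)
        outcomes[i], directions[i] = o, d

    # --- timeline ----------------------------------------------------------
    pre_sleep = (0.0, round(config.sleep_epoch_length, 4))
    t = pre_sleep[1] + 60.0
    rows = []
    for i in range(T):
        dur_t = max(1.0, rng.normal(config.trial_duration_mean, config.trial_duration_sd))
        dur_i = max(2.0 * config.outbound_delay + 1.0, rng.normal(config.iti_duration_mean, config.iti_duration_sd))
        t_start = round(t, 4)
        t_armend = round(t + dur_t, 4)
        t_iti_end = round(t + dur_t + dur_i, 4)
        rows.append((i + 1, t_start, t_armend, t_iti_end, directions[i], lights[i], outcomes[i]))
        t = t_iti_end
    post_sleep = (round(t + 60.0, 4), round(t + 60.0 + config.sleep_epoch_length, 4))
    trials = pd.DataFrame(rows, columns=["trial", "t_start_s", "t_armend_s", "t_iti_end_s", "direction", "light", "outcome"])

    # --- per-phase rate vectors -------------------------------------------
    def signed(feature: str, i: int) -> float:
        if feature == "direction":
            return 1.0 if directions[i] == "right" else -1.0
        if feature == "light":
            return 1.0 if lights[i] == "right" else -1.0
        return 1.0 if outcomes[i] == 1 else -1.0

    def mean_vector(phase: str, i: int) -> np.ndarray:
        sgn = 0.5 if phase == "trial" else -0.5
        axes = axes_trial if phase == "trial" else axes_iti
        v = baseline + sgn * config.phase_separation * offset_dir
        for f in FEATURES:
            v = v + config.feature_gain.get(f, 0.0) * signed(f, i) * axes[f]
        return v

    iv_starts: list[float] = []
    iv_durs: list[float] = []
    iv_rates: list[np.ndarray] = []
    for i, row in trials.iterrows():
        for phase, a, b in (
            ("trial", row["t_start_s"], row["t_armend_s"]),
            ("iti", row["t_armend_s"], row["t_iti_end_s"]),
        ):
            rates = mean_vector(phase, i) + rng.normal(0.0, config.rate_noise_sd, N)
            iv_starts.append(a)
            iv_durs.append(b - a)
            iv_rates.append(np.maximum(rates, RATE_FLOOR))

    # --- sleep -------------------------------------------------------------
    feat_means = {}
    for f in FEATURES:
        for s in (-1.0, 1.0):
            v = baseline + 0.5 * config.phase_separation * offset_dir + config.feature_gain.get(f, 0.0) * s * axes_trial[f]
            feat_means[(f, s)] = np.maximum(v, RATE_FLOOR)
    keys = sorted(feat_means, key=lambda k: (k[0], k[1]))

    sleep_intervals: dict[str, list[tuple[float, float]]] = {}
    for epoch, (a, b), rho in (("pre", pre_sleep, config.rho_pre), ("post", post_sleep, config.rho_post)):
        sleep_intervals[epoch] = [(a, b)]
        n_seg = int(math.floor(b - a))
        for k in range(n_seg):
            s0, s1 = a + k, min(a + k + 1.0, b)
            if rng.random() < rho:
                base = feat_means[keys[rng.integers(len(keys))]]
                rates = base * np.exp(rng.normal(0.0, config.reactivation_noise_sd, N))
            else:
                rates = rng.permutation(baseline)
            iv_starts.append(s0)
            iv_durs.append(s1 - s0)
            iv_rates.append(np.maximum(rates, RATE_FLOOR))

    spikes = SpikeTrainSet(
        trains=_poisson_trains(rng, np.asarray(iv_starts), np.asarray(iv_durs), np.vstack(iv_rates))
    )

    # --- position ----------------------------------------------------------
    maze = MazeGeometry()
    dt = 1.0 / config.tracking_rate_hz
    ts, xs, ys = [], [], []
    start, center = maze.start_origin(), maze.center()
    for _, row in trials.iterrows():
        arm_end = maze.arm_end(str(row["direction"]))
        t0, t1, t2 = row["t_start_s"], row["t_armend_s"], row["t_iti_end_s"]
        rev = min(t1 + config.outbound_delay, t2)
        samp = np.arange(t0, t2, dt)
        for tt in samp:
            if tt < t1:  # outward: start -> center -> arm end, uniform speed
                frac = (tt - t0) / (t1 - t0)
            elif tt < rev:  # pause at the arm end until the heading reversal
                frac = 1.0
            else:  # return leg, uniform speed back to the start origin
                frac = 1.0 - (tt - rev) / (t2 - rev)
            arc = frac * maze.path_length_cm
            if arc <= maze.arm_length_cm:
                p = start + (arc / maze.arm_length_cm) * (center - start)
            else:
                p = center + ((arc - maze.arm_length_cm) / maze.arm_length_cm) * (arm_end - center)
            ts.append(tt)
            xs.append(p[0])
            ys.append(p[1])
    tq = quantize_times(np.asarray(ts))
    keep = np.concatenate([[True], np.diff(tq) > 0])  # drop samples collapsed by quantization
    position = PositionTrack(
        t=tq[keep],
        x=np.round(np.asarray(xs), 4)[keep],
        y=np.round(np.asarray(ys), 4)[keep],
    )

    metadata = {
        "rat_id": config.rat_id,
        "rule_name": config.rule_name,
        "rule_class": config.rule_class,
        "rule_change_trial": config.rule_change_trial,
        "maze": maze.to_dict(),
        "seed": int(seed),
    }
    session = SessionRecording(
        spikes=spikes,
        position=position,
        trials=TrialTable(frame=trials),
        sleep=SleepEpochs(intervals=sleep_intervals),
        metadata=metadata,
    )
    session.validate()
    truth = GroundTruth(
        phase_offset_direction=offset_dir,
        coding_axes_trial=axes_trial,
        coding_axes_iti=axes_iti,
        baseline_rates=baseline,
        learning_trial=config.learning_trial,
        rho_pre=config.rho_pre,
        rho_post=config.rho_post,
        seed=int(seed),
    )
    return session, truth


def generate_cohort(
    config: SynthConfig | Sequence[SynthConfig],
    n_sessions: int,
    seed: int,
) -> list[tuple[SessionRecording, GroundTruth]]:
    """Generate independent sessions with per-session seeds derived from ``seed``.

    ``config`` may be a single configuration used for every session or a
    sequence of ``n_sessions`` configurations (e.g., a mix of learning and
    non-learning sessions).
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if isinstance(config, SynthConfig):
        configs = [config] * n_sessions
    else:
        configs = list(config)
        if len(configs) != n_sessions:
            raise ValueError("need one config per session")
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_sessions)
    return [generate_session(cfg, int(s)) for cfg, s in zip(configs, child_seeds)]
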