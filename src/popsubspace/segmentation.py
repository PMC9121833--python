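"""Population rate vectors, maze linearization, and phase detection.

Central objects:

* :class:`RateVectorSet` — a T x N matrix of population firing-rate vectors,
  one row per trial, for one task phase (trial / ITI / inbound / outbound),
  optionally restricted to one of five equal maze sections;
* :class:`PhaseMatrix` — the 2T x N matrix X obtained by interleaving trial
  and ITI rate vectors in temporal order, the input to the subspace analyses.

Only "active" neurons enter any rate vector: those that fired at least one
spike in every trial interval of the session.  Rates are spike counts divided
by interval durations (Hz), over half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .session import SessionRecording

__all__ = [
    "RateVectorSet",
    "PhaseMatrix",
    "SegmentationError",
    "select_active_neurons",
    "phase_intervals",
    "phase_rate_vectors",
    "linearize_position",
    "section_rate_vectors",
    "detect_outbound_starts",
    "build_phase_matrix",
    "trial_iti_rate_correlation",
]

PHASES = ("trial", "iti", "inbound", "outbound")
N_SECTIONS = 5


class SegmentationError(ValueError):
    pass


@dataclass
class RateVectorSet:
    """T x N_active firing-rate vectors (Hz) for one phase (and section).

    ``valid`` flags rows that could be computed; rows with zero occupancy of a
    requested section are flagged missing (False) and hold NaN.
    """

    rates: np.ndarray
    phase: str
    neuron_ids: list[int]
    section: int | None = None
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.ones(len(self.rates), dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]


@dataclass
class PhaseMatrix:
    """2T x N matrix of interleaved trial/ITI rate vectors in temporal order."""

    matrix: np.ndarray
    labels: np.ndarray  # "trial"/"iti" per row
    neuron_ids: list[int]


def _spike_count(train: np.ndarray, start: float, end: float) -> int:
    return int(np.searchsorted(train, end, side="left") - np.searchsorted(train, start, side="left"))


def select_active_neurons(session: SessionRecording) -> list[int]:
    """Ids of neurons with at least one spike in every trial interval.

    The criterion applies to trial intervals [t_start, t_armend) only, not to
    ITIs.  Deterministic and order-independent.
    """
    df = session.trials.frame
    active = []
    for nid in session.spikes.neuron_ids:
        train = session.spikes.trains[nid]
        if all(
            _spike_count(train, row["t_start_s"], row["t_armend_s"]) > 0
            for _, row in df.iterrows()
        ):
            active.append(nid)
    if not active:
        raise SegmentationError("no active neurons: no neuron fired in every trial")
    return active


def phase_intervals(session: SessionRecording, phase: str, outbound_starts: pd.DataFrame | None = None) -> np.ndarray:
    """Per-trial (start, end) interval for ``phase``; shape (T, 2)."""
    df = session.trials.frame
    if phase == "trial":
        return df[["t_start_s", "t_armend_s"]].to_numpy(dtype=float)
    if phase == "iti":
        return df[["t_armend_s", "t_iti_end_s"]].to_numpy(dtype=float)
    if phase in ("inbound", "outbound"):
        if outbound_starts is None:
            outbound_starts = detect_outbound_starts(session)
        ob = outbound_starts["outbound_start_s"].to_numpy(dtype=float)
        if phase == "inbound":
            return np.column_stack([df["t_start_s"].to_numpy(dtype=float), ob])
        return np.column_stack([ob, df["t_iti_end_s"].to_numpy(dtype=float)])
    raise ValueError(f"unknown phase {phase!r}")


def phase_rate_vectors(
    session: SessionRecording,
    phase: str,
    active_ids: list[int] | None = None,
    outbound_starts: pd.DataFrame | None = None,
) -> RateVectorSet:
    """Population firing-rate vector for each trial's ``phase`` interval."""
    if active_ids is None:
        active_ids = select_active_neurons(session)
    ivals = phase_intervals(session, phase, outbound_starts)
    durs = ivals[:, 1] - ivals[:, 0]
    if np.any(durs < 0):
        raise SegmentationError("degenerate interval: negative phase duration")
    rates = np.zeros((len(ivals), len(active_ids)))
    for j, nid in enumerate(active_ids):
        train = session.spikes.trains[nid]
        for i, (a, b) in enumerate(ivals):
            if b <= a:
                raise SegmentationError(f"degenerate interval: zero duration in trial {i + 1}")
            rates[i, j] = _spike_count(train, a, b) / (b - a)
    return RateVectorSet(rates=rates, phase=phase, neuron_ids=list(active_ids))


def linearize_position(session: SessionRecording, tolerance_cm: float = 8.0) -> pd.DataFrame:
    """Project tracking samples onto the linearized maze path.

    For each position sample falling inside a trial's [t_start, t_iti_end)
    window, project it onto the two-segment skeleton start-arm origin ->
    center -> chosen-arm end.  The linear coordinate is the normalized arc
    length in [0, 1]; sections are the equal fifths [0, 0.2), ..., [0.8, 1].
    Samples farther than ``tolerance_cm`` from the skeleton are flagged
    invalid and excluded from section rate vectors.

    Returns a frame with columns ``time_s, trial, coord, section, valid``.
    """
    maze = session.maze
    df = session.trials.frame
    t = session.position.t
    pts = np.column_stack([session.position.x, session.position.y])
    start, center = maze.start_origin(), maze.center()
    L = maze.arm_length_cm

    out_t, out_trial, out_coord, out_valid = [], [], [], []
    for _, row in df.iterrows():
        sel = (t >= row["t_start_s"]) & (t < row["t_iti_end_s"])
        if not sel.any():
            continue
        p = pts[sel]
        arm_end = maze.arm_end(str(row["direction"]))
        coords = np.empty(len(p))
        dists = np.empty(len(p))
        for seg_i, (a, b, arc0) in enumerate(((start, center, 0.0), (center, arm_end, L))):
            d = b - a
            tt = np.clip(((p - a) @ d) / (d @ d), 0.0, 1.0)
            proj = a + tt[:, None] * d
            dist = np.linalg.norm(p - proj, axis=1)
            arc = arc0 + tt * L
            if seg_i == 0:
                coords, dists = arc, dist
            else:
                better = dist < dists
                coords = np.where(better, arc, coords)
                dists = np.where(better, dist, dists)
        out_t.append(t[sel])
        out_trial.append(np.full(int(sel.sum()), int(row["trial"])))
        out_coord.append(coords / (2 * L))
        out_valid.append(dists <= tolerance_cm)

    if not out_t:
        raise SegmentationError("no position samples fall within any trial window")
    coord = np.concatenate(out_coord)
    section = np.minimum((coord * N_SECTIONS).astype(int), N_SECTIONS - 1) + 1
    return pd.DataFrame(
        {
            "time_s": np.concatenate(out_t),
            "trial": np.concatenate(out_trial),
            "coord": coord,
            "section": section,
            "valid": np.concatenate(out_valid),
        }
    )


def section_rate_vectors(
    session: SessionRecording,
    phase: str,
    section: int,
    active_ids: list[int] | None = None,
    linearized: pd.DataFrame | None = None,
    outbound_starts: pd.DataFrame | None = None,
) -> RateVectorSet:
    """Rate vectors over the time spent in maze ``section`` within ``phase``.

    Each inter-sample gap is attributed to the section of its leading sample;
    rates are spike counts over the union of those gaps divided by the total
    occupancy time.  Trials with zero occupancy are flagged missing.
    """
    if not (1 <= section <= N_SECTIONS):
        raise ValueError("section must be in 1..5")
    if active_ids is None:
        active_ids = select_active_neurons(session)
    if linearized is None:
        linearized = linearize_position(session)
    ivals = phase_intervals(session, phase, outbound_starts)
    df = session.trials.frame
    T = len(df)
    rates = np.full((T, len(active_ids)), np.nan)
    valid = np.zeros(T, dtype=bool)
    any_occupied = False

    for i in range(T):
        a, b = ivals[i]
        sub = linearized[(linearized["trial"] == i + 1) & linearized["valid"]]
        tt = sub["time_s"].to_numpy()
        sec = sub["section"].to_numpy()
        inside = (tt >= a) & (tt < b)
        tt, sec = tt[inside], sec[inside]
        if len(tt) == 0:
            continue
        # close each sample's gap at the next sample or the phase end
        gap_end = np.append(tt[1:], b)
        mask = sec == section
        if not mask.any():
            continue
        occ = float(np.sum(gap_end[mask] - tt[mask]))
        if occ <= 0:
            continue
        any_occupied = True
        starts, ends = tt[mask], gap_end[mask]
        for j, nid in enumerate(active_ids):
            train = session.spikes.trains[nid]
            count = int(
                np.sum(
                    np.searchsorted(train, ends, side="left")
                    - np.searchsorted(train, starts, side="left")
                )
            )
            rates[i, j] = count / occ
        valid[i] = True

    if not any_occupied:
        raise SegmentationError(f"empty section: section {section} never occupied in phase {phase}")
    return RateVectorSet(rates=rates, phase=phase, neuron_ids=list(active_ids), section=section, valid=valid)


def detect_outbound_starts(
    session: SessionRecording,
    min_run_s: float = 0.4,
    smooth_window: int = 3,
) -> pd.DataFrame:
    """Detect the start of the outbound (returning) phase in each ITI.

    The heading at each sample is the displacement between adjacent samples
    of the smoothed trajectory (moving average over ``smooth_window``
    samples, backward difference so a heading never anticipates more than
    one raw sample).  A sample points "toward the start" when the angle
    between its heading and the vector to the start-arm origin is below 90
    degrees.  The outbound start is the first sample after t_armend opening
    a run of at least ``min_run_s`` of toward-start samples.  ITIs with no
    qualifying run are flagged degenerate and assigned
    outbound_start = t_iti_end.

    Returns columns ``trial, outbound_start_s, delay_s, degenerate``.
    """
    maze = session.maze
    start = maze.start_origin()
    t = session.position.t
    n = len(t)
    if n < 3:
        raise SegmentationError("position track too short for heading estimation")
    xy = np.column_stack([session.position.x, session.position.y])
    kernel = np.ones(smooth_window) / smooth_window
    sm = np.column_stack([np.convolve(xy[:, 0], kernel, mode="same"), np.convolve(xy[:, 1], kernel, mode="same")])
    heading = np.zeros_like(sm)
    heading[1:] = sm[1:] - sm[:-1]
    heading[0] = sm[1] - sm[0]
    toward = np.einsum("ij,ij->i", heading, start - xy) > 0.0

    dt_med = float(np.median(np.diff(t)))
    min_run = max(1, int(np.ceil(min_run_s / dt_med)))

    rows = []
    for _, r in session.trials.frame.iterrows():
        sel = np.flatnonzero((t >= r["t_armend_s"]) & (t < r["t_iti_end_s"]))
        ob, degenerate = float(r["t_iti_end_s"]), True
        run = 0
        for k in sel:
            run = run + 1 if toward[k] else 0
            if run >= min_run:
                ob = float(t[k - min_run + 1])
                degenerate = False
                break
        rows.append((int(r["trial"]), ob, ob - float(r["t_armend_s"]), degenerate))
    return pd.DataFrame(rows, columns=["trial", "outbound_start_s", "delay_s", "degenerate"])


def build_phase_matrix(
    session: SessionRecording,
    active_ids: list[int] | None = None,
    split: str = "trial-iti",
    outbound_starts: pd.DataFrame | None = None,
) -> PhaseMatrix:
    """Interleave the two phases' rate vectors in temporal order (2T rows)."""
    if active_ids is None:
        active_ids = select_active_neurons(session)
    if split == "trial-iti":
        pa, pb = "trial", "iti"
    elif split == "inbound-outbound":
        pa, pb = "inbound", "outbound"
    else:
        raise ValueError("split must be 'trial-iti' or 'inbound-outbound'")
    va = phase_rate_vectors(session, pa, active_ids, outbound_starts)
    vb = phase_rate_vectors(session, pb, active_ids, outbound_starts)
    if va.neuron_ids != vb.neuron_ids:
        raise SegmentationError("internal error: active-neuron sets differ between phases")
    T = va.n_trials
    X = np.empty((2 * T, len(active_ids)))
    X[0::2] = va.rates
    X[1::2] = vb.rates
    labels = np.empty(2 * T, dtype=object)
    labels[0::2] = pa
    labels[1::2] = pb
    return PhaseMatrix(matrix=X, labels=labels, neuron_ids=list(active_ids))


def trial_iti_rate_correlation(session: SessionRecording, active_ids: list[int] | None = None) -> pd.DataFrame:
    """Spearman correlation between each trial's and its ITI's rate vector.

    Pairs with a constant vector have undefined rank correlation and are
    reported as NaN.  Requires at least 3 active neurons.
    """
    if active_ids is None:
        active_ids = select_active_neurons(session)
    if len(active_ids) < 3:
        raise SegmentationError("need at least 3 active neurons for rank correlation")
    rt = phase_rate_vectors(session, "trial", active_ids)
    ri = phase_rate_vectors(session, "iti", active_ids)
    rows = []
    for i in range(rt.n_trials):
        a, b = rt.rates[i], ri.rates[i]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            rows.append((i + 1, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(a, b)
        rows.append((i + 1, float(rho), float(p)))
    return pd.DataFrame(rows, columns=["trial", "spearman_rho", "p_value"])
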