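"""Session data model and on-disk bundle I/O.

A recording session couples four data streams from one behavioral session on a
Y-maze: spike times per neuron, position tracking, a trial event table, and
slow-wave-sleep (SWS) intervals flanking training.  All times are in seconds,
all intervals are half-open ``[start, end)``, and spike/track times are
quantized to 0.1 ms (the recording resolution).  Trials are numbered from 1.

A session bundle on disk is a directory of plain TSV files plus a JSON
metadata file::

    spikes.tsv     neuron_id <TAB> spike_time_s
    position.tsv   time_s <TAB> x_cm <TAB> y_cm
    trials.tsv     trial <TAB> t_start_s <TAB> t_armend_s <TAB> t_iti_end_s
                   <TAB> direction <TAB> light <TAB> outcome
    sleep.tsv      epoch <TAB> t_start_s <TAB> t_end_s
    session.json   rat_id, rule_name, rule_class, rule_change_trial, maze

The trial of index ``i`` occupies ``[t_start(i), t_armend(i))`` (outward run to
the chosen arm end) and its intertrial interval (ITI) occupies
``[t_armend(i), t_iti_end(i))`` (self-paced return to the start position).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TIME_DECIMALS",
    "IncompleteBundleError",
    "InvalidSessionError",
    "MazeGeometry",
    "SpikeTrainSet",
    "PositionTrack",
    "TrialTable",
    "SleepEpochs",
    "SessionRecording",
    "load_session",
    "write_session",
    "quantize_times",
]

#: Decimal places used to serialize times (0.1 ms resolution).
TIME_DECIMALS = 4

BUNDLE_FILES = ("spikes.tsv", "position.tsv", "trials.tsv", "sleep.tsv", "session.json")

TRIAL_COLUMNS = ["trial", "t_start_s", "t_armend_s", "t_iti_end_s", "direction", "light", "outcome"]


class IncompleteBundleError(FileNotFoundError):
    """A required file of the session bundle is missing."""


class InvalidSessionError(ValueError):
    """A session violates a structural invariant; the message names it."""


def quantize_times(times: np.ndarray) -> np.ndarray:
    """Round times to the 0.1 ms recording grid (ties to even)."""
    return np.round(np.asarray(times, dtype=float), TIME_DECIMALS)


@dataclass(frozen=True)
class MazeGeometry:
    """Three-arm (Y) maze: symmetric arms joined at a central platform.

    The start arm points "south"; the left and right goal arms are separated
    from it by ``arm_separation_deg``.  The canonical linearized path of one
    traversal is start-arm origin -> center -> chosen-arm end, with total
    length ``2 * arm_length_cm``.
    """

    arm_length_cm: float = 85.0
    n_arms: int = 3
    arm_separation_deg: float = 120.0

    @property
    def path_length_cm(self) -> float:
        return 2.0 * self.arm_length_cm

    def start_origin(self) -> np.ndarray:
        return np.array([0.0, -self.arm_length_cm])

    def center(self) -> np.ndarray:
        return np.zeros(2)

    def arm_end(self, direction: str) -> np.ndarray:
        """Coordinates of the goal-arm end for ``direction`` in {left, right}."""
        half = math.radians(180.0 - self.arm_separation_deg)  # 60 deg from vertical
        ang = {"left": math.pi / 2 + half, "right": math.pi / 2 - half}[direction]
        return self.arm_length_cm * np.array([math.cos(ang), math.sin(ang)])

    def to_dict(self) -> dict:
        return {
            "arm_length_cm": self.arm_length_cm,
            "n_arms": self.n_arms,
            "arm_separation_deg": self.arm_separation_deg,
        }


@dataclass
class SpikeTrainSet:
    """Spike times per neuron, seconds, nondecreasing within each neuron."""

    trains: dict[int, np.ndarray]

    @property
    def neuron_ids(self) -> list[int]:
        return sorted(self.trains)

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    def validate(self) -> None:
        if not self.trains:
            raise InvalidSessionError("invalid session: N >= 1 neurons required")
        for nid, t in self.trains.items():
            t = np.asarray(t, dtype=float)
            if t.size and not np.all(np.isfinite(t)):
                raise InvalidSessionError(f"invalid session: non-finite spike time for neuron {nid}")
            if t.size and t.min() < 0:
                raise InvalidSessionError(f"invalid session: negative spike time for neuron {nid}")
            if np.any(np.diff(t) < 0):
                raise InvalidSessionError(f"invalid session: spike times not nondecreasing for neuron {nid}")


@dataclass
class PositionTrack:
    """Position samples (nominally 30 Hz): times (s) and x/y coordinates (cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def validate(self) -> None:
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise InvalidSessionError("invalid session: position arrays have mismatched lengths")
        if np.any(np.diff(self.t) <= 0):
            raise InvalidSessionError("invalid session: position times not strictly increasing")
        for name, arr in (("t", self.t), ("x", self.x), ("y", self.y)):
            if len(arr) and not np.all(np.isfinite(arr)):
                raise InvalidSessionError(f"invalid session: non-finite position {name}")


@dataclass
class TrialTable:
    """Per-trial events and labels.

    ``frame`` has columns ``trial`` (1-based), ``t_start_s``, ``t_armend_s``,
    ``t_iti_end_s``, ``direction`` / ``light`` in {left, right}, ``outcome``
    in {0, 1}.  ``t_armend`` is both the trial end and the ITI start.
    """

    frame: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def labels(self, feature: str) -> np.ndarray:
        """Binary labels for ``feature`` in {direction, light, outcome}."""
        return self.frame[feature].to_numpy()

    def validate(self) -> None:
        df = self.frame
        if len(df) < 1:
            raise InvalidSessionError("invalid session: T >= 1 trials required")
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidSessionError(f"invalid session: trial table missing columns {missing}")
        if list(df["trial"]) != list(range(1, len(df) + 1)):
            raise InvalidSessionError("invalid session: trials must be numbered 1..T in order")
        for _, row in df.iterrows():
            if not (row["t_start_s"] < row["t_armend_s"] < row["t_iti_end_s"]):
                raise InvalidSessionError(
                    f"invalid session: trial {int(row['trial'])} violates t_start < t_armend < t_iti_end"
                )
        starts = df["t_start_s"].to_numpy()
        ends = df["t_iti_end_s"].to_numpy()
        if np.any(ends[:-1] > starts[1:]):
            raise InvalidSessionError("invalid session: trials overlap (t_iti_end(i) > t_start(i+1))")
        bad_dir = ~df["direction"].isin(["left", "right"])
        bad_light = ~df["light"].isin(["left", "right"])
        if bad_dir.any() or bad_light.any():
            raise InvalidSessionError("invalid session: direction/light labels must be 'left' or 'right'")
        if not df["outcome"].isin([0, 1]).all():
            raise InvalidSessionError("invalid session: outcome labels must be 0 or 1")


@dataclass
class SleepEpochs:
    """Slow-wave-sleep intervals for the pre- and post-training sleep epochs."""

    intervals: dict[str, list[tuple[float, float]]]

    def epoch(self, name: str) -> list[tuple[float, float]]:
        return self.intervals.get(name, [])

    def validate(self) -> None:
        for name, ivals in self.intervals.items():
            if name not in ("pre", "post"):
                raise InvalidSessionError(f"invalid session: unknown sleep epoch '{name}'")
            prev_end = -np.inf
            for s, e in ivals:
                if not (e > s):
                    raise InvalidSessionError(f"invalid session: nonpositive sleep interval in epoch '{name}'")
                if s < prev_end:
                    raise InvalidSessionError(f"invalid session: sleep intervals overlap in epoch '{name}'")
                prev_end = e


@dataclass
class SessionRecording:
    """One session: spikes + position + trials + sleep + metadata."""

    spikes: SpikeTrainSet
    position: PositionTrack
    trials: TrialTable
    sleep: SleepEpochs
    metadata: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.spikes.n_neurons

    @property
    def n_trials(self) -> int:
        return self.trials.n_trials

    @property
    def maze(self) -> MazeGeometry:
        m = self.metadata.get("maze", {})
        return MazeGeometry(
            arm_length_cm=m.get("arm_length_cm", 85.0),
            n_arms=m.get("n_arms", 3),
            arm_separation_deg=m.get("arm_separation_deg", 120.0),
        )

    def validate(self) -> None:
        self.spikes.validate()
        self.position.validate()
        self.trials.validate()
        self.sleep.validate()
        pre = self.sleep.epoch("pre")
        post = self.sleep.epoch("post")
        first_event = float(self.trials.frame["t_start_s"].iloc[0])
        last_event = float(self.trials.frame["t_iti_end_s"].iloc[-1])
        if pre and max(e for _, e in pre) > first_event:
            raise InvalidSessionError("invalid session: pre-sleep epoch overlaps trial events")
        if post and min(s for s, _ in post) < last_event:
            raise InvalidSessionError("invalid session: post-sleep epoch overlaps trial events")


def _fmt(v: float) -> str:
    return f"{v:.{TIME_DECIMALS}f}"


def write_session(session: SessionRecording, bundle_path: str | Path) -> None:
    """Write a validated session bundle; times serialized at 0.1 ms precision.

    Raises :class:`InvalidSessionError` if the session fails validation; an
    unwritable path surfaces as the underlying ``OSError``.
    """
    session.validate()
    path = Path(bundle_path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / "spikes.tsv", "w") as fh:
        fh.write("neuron_id\tspike_time_s\n")
        for nid in session.spikes.neuron_ids:
            for t in session.spikes.trains[nid]:
                fh.write(f"{nid}\t{_fmt(t)}\n")

    with open(path / "position.tsv", "w") as fh:
        fh.write("time_s\tx_cm\ty_cm\n")
        for t, x, y in zip(session.position.t, session.position.x, session.position.y):
            fh.write(f"{_fmt(t)}\t{_fmt(x)}\t{_fmt(y)}\n")

    with open(path / "trials.tsv", "w") as fh:
        fh.write("\t".join(TRIAL_COLUMNS) + "\n")
        for _, r in session.trials.frame.iterrows():
            fh.write(
                f"{int(r['trial'])}\t{_fmt(r['t_start_s'])}\t{_fmt(r['t_armend_s'])}\t"
                f"{_fmt(r['t_iti_end_s'])}\t{r['direction']}\t{r['light']}\t{int(r['outcome'])}\n"
            )

    with open(path / "sleep.tsv", "w") as fh:
        fh.write("epoch\tt_start_s\tt_end_s\n")
        for epoch in ("pre", "post"):
            for s, e in session.sleep.epoch(epoch):
                fh.write(f"{epoch}\t{_fmt(s)}\t{_fmt(e)}\n")

    meta = dict(session.metadata)
    meta.setdefault("maze", session.maze.to_dict())
    with open(path / "session.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_session(bundle_path: str | Path) -> SessionRecording:
    """Load and validate a session bundle written by :func:`write_session`."""
    path = Path(bundle_path)
    for fname in BUNDLE_FILES:
        if not (path / fname).exists():
            raise IncompleteBundleError(f"incomplete bundle: missing {fname} in {path}")

    sp = pd.read_csv(path / "spikes.tsv", sep="\t")
    trains: dict[int, np.ndarray] = {}
    for nid, grp in sp.groupby("neuron_id"):
        trains[int(nid)] = grp["spike_time_s"].to_numpy(dtype=float)

    pos = pd.read_csv(path / "position.tsv", sep="\t")
    position = PositionTrack(
        t=pos["time_s"].to_numpy(dtype=float),
        x=pos["x_cm"].to_numpy(dtype=float),
        y=pos["y_cm"].to_numpy(dtype=float),
    )

    tr = pd.read_csv(path / "trials.tsv", sep="\t")
    trials = TrialTable(frame=tr[TRIAL_COLUMNS].copy())

    sl = pd.read_csv(path / "sleep.tsv", sep="\t")
    intervals: dict[str, list[tuple[float, float]]] = {"pre": [], "post": []}
    for _, r in sl.iterrows():
        intervals[str(r["epoch"])].append((float(r["t_start_s"]), float(r["t_end_s"])))

    with open(path / "session.json") as fh:
        metadata = json.load(fh)

    session = SessionRecording(
        spikes=SpikeTrainSet(trains=trains),
        position=position,
        trials=trials,
        sleep=SleepEpochs(intervals=intervals),
        metadata=metadata,
    )
    session.validate()
    return session


def sessions_equal(a: SessionRecording, b: SessionRecording) -> bool:
    """Exact equality of two sessions (used by round-trip checks)."""
    if a.spikes.neuron_ids != b.spikes.neuron_ids:
        return False
    for nid in a.spikes.neuron_ids:
        if not np.array_equal(a.spikes.trains[nid], b.spikes.trains[nid]):
            return False
    if not (
        np.array_equal(a.position.t, b.position.t)
        and np.array_equal(a.position.x, b.position.x)
        and np.array_equal(a.position.y, b.position.y)
    ):
        return False
    fa = a.trials.frame.reset_index(drop=True)
    fb = b.trials.frame.reset_index(drop=True)
    if not fa[TRIAL_COLUMNS].equals(fb[TRIAL_COLUMNS]):
        return False
    if a.sleep.intervals != b.sleep.intervals:
        return False
    return True
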