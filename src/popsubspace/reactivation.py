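"""Reactivation of task-phase activity in slow-wave sleep.

For each task feature value (e.g., right-arm choices), the mean population
rate vector over matching trials (or ITIs) marks the region of the activity
subspace occupied by that feature.  Each slow-wave-sleep (SWS) interval is
tiled with fixed-duration bins, and the feature vector is Spearman-rank
correlated with every bin's population rate vector, separately for the
pre-training and post-training sleep epochs.  The reactivation statistic is

    M_post - M_pre  =  median(post correlations) - median(pre correlations)

Positive values mean the feature-specific activity pattern is preferentially
revisited after training.  This is rank alignment with a subspace region —
"reactivation" — not detection of repeated spike sequences ("replay").

A within-epoch control compares paired feature values (e.g., left vs right)
inside the same sleep epoch; absent artifacts it centers on zero.  A bin-size
sweep (100 ms to 10 s in 150 ms steps, 67 sizes) checks robustness across
time scales, bracketing the ~6.5 s mean trial duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decoding import FEATURES, aligned_labels, angle_between, fit_decoder_axis
from .segmentation import RateVectorSet, phase_rate_vectors, select_active_neurons
from .session import SessionRecording

__all__ = [
    "SleepVectorSet",
    "ReactivationResult",
    "SWEEP_GRID",
    "feature_mean_vector",
    "sleep_bin_vectors",
    "spearman_to_bins",
    "reactivation_distributions",
    "paired_feature_control",
    "binsize_sweep",
    "pre_post_reactivation_correlation",
    "reactivation_vs_performance",
    "mean_vector_angles",
]

#: bin-size sweep grid: 0.1 s to 10 s every 0.15 s (67 sizes)
SWEEP_GRID = np.round(np.arange(0.1, 10.0 + 1e-9, 0.15), 10)

FEATURE_VALUES = {
    "direction": ("left", "right"),
    "light": ("left", "right"),
    "outcome": (0, 1),
}


@dataclass
class SleepVectorSet:
    epoch: str
    bin_s: float
    rates: np.ndarray  # B x N_active, Hz
    bin_starts: np.ndarray
    neuron_ids: list[int]


@dataclass
class ReactivationResult:
    feature: str
    value: object
    source: str  # phase the template comes from: "trial" or "iti"
    bin_s: float
    pre_correlations: np.ndarray
    post_correlations: np.ndarray
    n_dropped_pre: int = 0
    n_dropped_post: int = 0

    @property
    def m_pre(self) -> float:
        return float(np.median(self.pre_correlations))

    @property
    def m_post(self) -> float:
        return float(np.median(self.post_correlations))

    @property
    def statistic(self) -> float:
        """M_post - M_pre: preferential post-training reactivation if > 0."""
        return self.m_post - self.m_pre

    @property
    def ks_p(self) -> float:
        return float(stats.ks_2samp(self.pre_correlations, self.post_correlations).pvalue)


def feature_mean_vector(vectors: RateVectorSet | np.ndarray, labels: np.ndarray, value) -> np.ndarray:
    """Elementwise mean of the rows whose label equals ``value``."""
    X = vectors.rates if isinstance(vectors, RateVectorSet) else np.asarray(vectors, dtype=float)
    mask = np.asarray(labels) == value
    if not mask.any():
        raise ValueError(f"no rows with label {value!r}")
    return X[mask].mean(axis=0)


def sleep_bin_vectors(
    session: SessionRecording,
    epoch: str,
    bin_s: float,
    active_ids: list[int] | None = None,
) -> SleepVectorSet:
    """Population rate vectors in contiguous ``bin_s`` bins of SWS.

    Bins are anchored at each SWS interval's start; the trailing partial bin
    of each interval is dropped so all bins have exactly equal duration.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    if active_ids is None:
        active_ids = select_active_neurons(session)
    starts = []
    for a, b in session.sleep.epoch(epoch):
        k = int(np.floor((b - a) / bin_s + 1e-9))
        starts.extend(a + np.arange(k) * bin_s)
    if not starts:
        raise ValueError(f"no usable bins: no SWS interval of epoch '{epoch}' is >= {bin_s} s")
    starts = np.asarray(starts)
    ends = starts + bin_s
    rates = np.empty((len(starts), len(active_ids)))
    for j, nid in enumerate(active_ids):
        train = session.spikes.trains[nid]
        rates[:, j] = (
            np.searchsorted(train, ends, side="left") - np.searchsorted(train, starts, side="left")
        ) / bin_s
    return SleepVectorSet(epoch=epoch, bin_s=bin_s, rates=rates, bin_starts=starts, neuron_ids=list(active_ids))


def spearman_to_bins(feature_vector: np.ndarray, bins: np.ndarray) -> tuple[np.ndarray, int]:
    """Spearman correlation (average ranks) of one vector with every bin row.

    Vectorized rank-then-Pearson; rows with constant rates have undefined
    rank correlation and are dropped (their count is returned).
    """
    v = np.asarray(feature_vector, dtype=float)
    if np.ptp(v) == 0:
        raise ValueError("constant feature vector: Spearman correlation undefined")
    B = np.asarray(bins, dtype=float)
    keep = np.ptp(B, axis=1) > 0
    dropped = int(np.sum(~keep))
    B = B[keep]
    if len(B) == 0:
        return np.empty(0), dropped
    rv = stats.rankdata(v)
    rB = stats.rankdata(B, axis=1)
    rv_c = rv - rv.mean()
    rB_c = rB - rB.mean(axis=1, keepdims=True)
    denom = np.sqrt((rv_c @ rv_c) * np.sum(rB_c**2, axis=1))
    return (rB_c @ rv_c) / denom, dropped


def reactivation_distributions(
    session: SessionRecording,
    feature: str,
    value,
    source: str = "trial",
    bin_s: float = 1.0,
    active_ids: list[int] | None = None,
    min_bins: int = 5,
    phase_vectors: RateVectorSet | None = None,
    sleep_bins: dict | None = None,
) -> ReactivationResult:
    """Pre/post correlation distributions for one feature value.

    The template is the mean rate vector over rows of the ``source`` phase
    whose (phase-convention-aligned) label equals ``value``.  Requires at
    least 3 active neurons and ``min_bins`` usable bins per epoch.
    """
    if active_ids is None:
        active_ids = select_active_neurons(session)
    if len(active_ids) < 3:
        raise ValueError("need at least 3 active neurons for rank correlation")
    if phase_vectors is None:
        phase_vectors = phase_rate_vectors(session, source, active_ids)
    ref = "current" if source == "trial" else "previous"
    idx, lab = aligned_labels(session.trials.labels(feature), source, ref)
    template = feature_mean_vector(phase_vectors.rates[idx], lab, value)

    cors = {}
    dropped = {}
    for epoch in ("pre", "post"):
        sv = (
            sleep_bins[epoch]
            if sleep_bins is not None
            else sleep_bin_vectors(session, epoch, bin_s, active_ids)
        )
        c, d = spearman_to_bins(template, sv.rates)
        if len(c) < min_bins:
            raise ValueError(f"no usable bins: fewer than {min_bins} valid bins in epoch '{epoch}'")
        cors[epoch], dropped[epoch] = c, d
    return ReactivationResult(
        feature=feature, value=value, source=source, bin_s=bin_s,
        pre_correlations=cors["pre"], post_correlations=cors["post"],
        n_dropped_pre=dropped["pre"], n_dropped_post=dropped["post"],
    )


def paired_feature_control(
    session: SessionRecording,
    feature: str,
    epoch: str,
    source: str = "trial",
    bin_s: float = 1.0,
    active_ids: list[int] | None = None,
) -> float:
    """Within-epoch control: median correlation difference between the two
    values of ``feature`` against the SAME sleep epoch.

    Antisymmetric under swapping the values; centers on zero when neither
    value's pattern is preferentially present in that epoch.
    """
    if active_ids is None:
        active_ids = select_active_neurons(session)
    pv = phase_rate_vectors(session, source, active_ids)
    ref = "current" if source == "trial" else "previous"
    idx, lab = aligned_labels(session.trials.labels(feature), source, ref)
    sv = sleep_bin_vectors(session, epoch, bin_s, active_ids)
    va, vb = FEATURE_VALUES[feature]
    med = {}
    for val in (va, vb):
        template = feature_mean_vector(pv.rates[idx], lab, val)
        c, _ = spearman_to_bins(template, sv.rates)
        med[val] = float(np.median(c))
    return med[vb] - med[va]


def binsize_sweep(
    session: SessionRecording,
    source: str = "trial",
    features: tuple[str, ...] = FEATURES,
    grid: np.ndarray = SWEEP_GRID,
    active_ids: list[int] | None = None,
) -> pd.DataFrame:
    """Reactivation statistic per feature value across the bin-size grid.

    Bin sizes with too few usable bins are skipped.  Returns one row per
    (bin size, feature, value) with the medians and the statistic.
    """
    if active_ids is None:
        active_ids = select_active_neurons(session)
    pv = phase_rate_vectors(session, source, active_ids)
    rows = []
    for bin_s in grid:
        try:
            sleep = {e: sleep_bin_vectors(session, e, float(bin_s), active_ids) for e in ("pre", "post")}
        except ValueError:
            continue
        for f in features:
            for val in FEATURE_VALUES[f]:
                try:
                    res = reactivation_distributions(
                        session, f, val, source=source, bin_s=float(bin_s),
                        active_ids=active_ids, phase_vectors=pv, sleep_bins=sleep,
                    )
                except ValueError:
                    continue
                rows.append(
                    {
                        "bin_s": float(bin_s),
                        "feature": f,
                        "value": val,
                        "m_pre": res.m_pre,
                        "m_post": res.m_post,
                        "statistic": res.statistic,
                    }
                )
    return pd.DataFrame(rows)


def pre_post_reactivation_correlation(results: pd.DataFrame) -> pd.DataFrame:
    """Across sessions, Spearman correlation of median pre vs post correlations.

    ``results`` needs columns session, source, feature, value, m_pre, m_post.
    Requires >= 5 sessions per group; constant inputs give NaN.
    """
    rows = []
    for (source, f, val), grp in results.groupby(["source", "feature", "value"]):
        if grp["session"].nunique() < 5:
            raise ValueError("need >= 5 sessions")
        if np.ptp(grp["m_pre"]) == 0 or np.ptp(grp["m_post"]) == 0:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(grp["m_pre"], grp["m_post"])
        rows.append({"source": source, "feature": f, "value": val, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows)


def reactivation_vs_performance(statistics: np.ndarray, delta_r: np.ndarray) -> tuple[float, float]:
    """Spearman correlation between reward-rate change and reactivation.

    ``delta_r`` is r_after - r_before per session (behavior module);
    ``statistics`` the matched M_post - M_pre values.  Sessions with missing
    delta_r must be excluded by the caller; constant inputs give NaN.
    """
    s = np.asarray(statistics, dtype=float)
    d = np.asarray(delta_r, dtype=float)
    keep = np.isfinite(s) & np.isfinite(d)
    s, d = s[keep], d[keep]
    if len(s) < 5:
        raise ValueError("need >= 5 sessions with delta_r available")
    if np.ptp(s) == 0 or np.ptp(d) == 0:
        return np.nan, np.nan
    rho, p = stats.spearmanr(d, s)
    return float(rho), float(p)


def mean_vector_angles(
    session: SessionRecording, active_ids: list[int] | None = None
) -> pd.DataFrame:
    """Angles between trial and ITI mean activity vectors per feature value,
    paired with the corresponding decoding-axis angles.

    Mean activity vectors can be closely aligned between phases even when
    the decoding axes are near orthogonal; this table makes that contrast.
    """
    if active_ids is None:
        active_ids = select_active_neurons(session)
    pv = {p: phase_rate_vectors(session, p, active_ids) for p in ("trial", "iti")}
    refs = {"trial": "current", "iti": "previous"}
    rows = []
    for f in FEATURES:
        lab_idx = {}
        for p in ("trial", "iti"):
            lab_idx[p] = aligned_labels(session.trials.labels(f), p, refs[p])
        ax = {}
        for p in ("trial", "iti"):
            idx, lab = lab_idx[p]
            ax[p] = fit_decoder_axis(pv[p].rates[idx], lab, feature=f, phase=p)
        axis_angle = angle_between(ax["trial"].weights, ax["iti"].weights)
        for val in FEATURE_VALUES[f]:
            means = {}
            for p in ("trial", "iti"):
                idx, lab = lab_idx[p]
                means[p] = feature_mean_vector(pv[p].rates[idx], lab, val)
            rows.append(
                {
                    "feature": f,
                    "value": val,
                    "mean_vector_angle": angle_between(means["trial"], means["iti"]),
                    "decoding_axis_angle": axis_angle,
                }
            )
    return pd.DataFrame(rows)
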