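"""Linear decoding of task features from population rate vectors.

The decoder throughout is L2-regularized logistic regression (inverse penalty
C = 1.0) on per-fold standardized rates.  Accuracy is assessed by
leave-one-out (LOO) cross-validation, with chance estimated by refitting on
label permutations ("shuffle null", 50 repetitions by default) so that
unbalanced label distributions (e.g., outcome in a high-performing session)
get the correct baseline.

Decoding-axis geometry: for each feature the full-data decoder weight
vectors of the two phases, w_t(f) and w_I(f), subtend the angle

    theta = arccos( w_t(f) . w_I(f) / (||w_t(f)|| ||w_I(f)||) )

Angles near pi/2 mean a readout of one phase's feature state is blind to the
other phase's — the two phases are independently decodable.  Cross-decoding
(train on one phase, test on the other) probes the same question
behaviorally: orthogonal axes drive cross-accuracy to chance.

Label-reference conventions: trial rows can be labeled by the current
(offset 0), previous (-1), or following (+1) trial.  ITI rows follow the
trial they complete, so the "previous" trial of ITI(i) is trial i (offset 0)
and the "following" trial is trial i+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .segmentation import (
    N_SECTIONS,
    RateVectorSet,
    linearize_position,
    phase_rate_vectors,
    section_rate_vectors,
    select_active_neurons,
)
from .session import SessionRecording

__all__ = [
    "FEATURES",
    "DecodingResult",
    "DecoderAxis",
    "AngleSet",
    "CrossDecodingResult",
    "aligned_labels",
    "loo_decode",
    "shuffled_chance",
    "decode_with_null",
    "DegenerateLabelsError",
    "fit_decoder_axis",
    "angle_between",
    "angle_analysis",
    "cross_decode",
    "position_decoding_profile",
    "decoding_vs_performance",
]

FEATURES = ("direction", "light", "outcome")

#: inverse L2 penalty of the logistic decoder
LOGREG_C = 1.0

_LABEL_OFFSETS = {
    "trial": {"current": 0, "previous": -1, "following": +1},
    # ITI(i) follows trial i: its "previous" trial is trial i itself
    "iti": {"current": 0, "previous": 0, "following": +1},
}


class DegenerateLabelsError(ValueError):
    """Only one label value present: the feature cannot be decoded."""


@dataclass
class DecodingResult:
    feature: str
    phase: str
    reference: str
    accuracy: float
    predictions: np.ndarray
    null_accuracies: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def relative_accuracy(self) -> float:
        """Accuracy minus the mean of the shuffle-null accuracies."""
        if self.null_accuracies.size == 0:
            return np.nan
        return self.accuracy - float(np.mean(self.null_accuracies))


@dataclass
class DecoderAxis:
    """Full-data decoder weights in the original (unstandardized) rate frame."""

    feature: str
    phase: str
    weights: np.ndarray
    intercept: float


@dataclass
class AngleSet:
    between_phase: dict  # feature -> radians
    between_phase_shuffled: dict  # feature -> array of reference angles
    within_phase: dict  # (phase, f1, f2) -> radians
    fold_axis_sd: dict  # (phase, feature) -> SD of fold-axis angles


@dataclass
class CrossDecodingResult:
    train_phase: str
    test_phase: str
    mode: str
    feature: str
    accuracy: float
    null_accuracies: np.ndarray

    @property
    def relative_accuracy(self) -> float:
        if self.null_accuracies.size == 0:
            return np.nan
        return self.accuracy - float(np.mean(self.null_accuracies))


# ---------------------------------------------------------------------------
# label plumbing


def _encode(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise DegenerateLabelsError(f"degenerate labels: found classes {list(uniq)}")
    return (labels == uniq[1]).astype(int), uniq


def aligned_labels(labels: np.ndarray, phase: str, reference: str) -> tuple[np.ndarray, np.ndarray]:
    """Row indices kept and the labels attached to them, for one reference.

    ``labels`` is the per-trial label sequence (index i = trial i+1).  Row i
    of a phase's rate-vector set receives the label of trial i + offset; rows
    whose referenced trial falls outside the session are dropped.
    """
    offset = _LABEL_OFFSETS[phase][reference]
    T = len(labels)
    idx = np.array([i for i in range(T) if 0 <= i + offset < T], dtype=int)
    return idx, np.asarray(labels)[idx + offset]


# ---------------------------------------------------------------------------
# the decoder


def _standardize(Xtr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _fit(Xtr: np.ndarray, ytr: np.ndarray) -> tuple[LogisticRegression, np.ndarray, np.ndarray]:
    mu, sd = _standardize(Xtr)
    clf = LogisticRegression(C=LOGREG_C, solver="lbfgs", max_iter=2000)  # L2 penalty
    clf.fit((Xtr - mu) / sd, ytr)
    return clf, mu, sd


def _predict(clf: LogisticRegression, mu, sd, X: np.ndarray) -> np.ndarray:
    p = clf.predict_proba((X - mu) / sd)[:, 1]
    return (p >= 0.5).astype(int)  # ties at 0.5 go to the positive class


def loo_decode(
    vectors: RateVectorSet | np.ndarray,
    labels: np.ndarray,
    feature: str = "",
    phase: str = "",
    reference: str = "current",
) -> DecodingResult:
    """Leave-one-out decoding accuracy of binary ``labels`` from rate vectors.

    For each held-out row, the decoder is fit on the remaining rows (features
    standardized with the training fold's mean/SD) and predicts the held-out
    label at the 0.5 probability threshold.
    """
    X = vectors.rates if isinstance(vectors, RateVectorSet) else np.asarray(vectors, dtype=float)
    y, _ = _encode(labels)
    if len(X) != len(y):
        raise ValueError("vectors and labels must align")
    if len(y) < 4:
        raise ValueError("need at least 4 trials for leave-one-out decoding")
    preds = np.empty(len(y), dtype=int)
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise DegenerateLabelsError("degenerate labels: training fold has one class")
        clf, mu, sd = _fit(X[mask], y[mask])
        preds[i] = _predict(clf, mu, sd, X[i : i + 1])[0]
    acc = float(np.mean(preds == y))
    return DecodingResult(feature=feature, phase=phase, reference=reference, accuracy=acc, predictions=preds)


def shuffled_chance(
    vectors: RateVectorSet | np.ndarray,
    labels: np.ndarray,
    reps: int = 50,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """LOO accuracies under ``reps`` uniform label permutations (seeded)."""
    X = vectors.rates if isinstance(vectors, RateVectorSet) else np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accs = np.empty(reps)
    for r in range(reps):
        perm = rng.permutation(len(labels))
        accs[r] = loo_decode(X, labels[perm]).accuracy
    return accs


def decode_with_null(
    vectors, labels, reps: int = 50, seed: int | np.random.Generator = 0, **meta
) -> DecodingResult:
    """LOO decoding plus its shuffle null in one result."""
    res = loo_decode(vectors, labels, **meta)
    res.null_accuracies = shuffled_chance(vectors, labels, reps=reps, seed=seed)
    return res


def fit_decoder_axis(
    vectors: RateVectorSet | np.ndarray, labels: np.ndarray, feature: str = "", phase: str = ""
) -> DecoderAxis:
    """Decoder weight vector fit on ALL rows, mapped back to rate units.

    The model is fit on standardized features; the returned weights are
    rescaled so that ``w . r + b`` in raw rate coordinates reproduces the
    fitted decision function.
    """
    X = vectors.rates if isinstance(vectors, RateVectorSet) else np.asarray(vectors, dtype=float)
    y, _ = _encode(labels)
    clf, mu, sd = _fit(X, y)
    w_std = clf.coef_.ravel()
    w = w_std / sd
    b = float(clf.intercept_[0] - np.sum(w_std * mu / sd))
    if not np.all(np.isfinite(w)) or np.allclose(w, 0):
        raise ValueError("decoder axis fit produced no usable weights")
    return DecoderAxis(feature=feature, phase=phase, weights=w, intercept=b)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in [0, pi] between two weight vectors (cosine clipped)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("undefined angle: zero vector")
    return float(np.arccos(np.clip(u @ v / (nu * nv), -1.0, 1.0)))


def angle_analysis(
    session: SessionRecording,
    active_ids: list[int] | None = None,
    shuffle_reps: int = 20,
    seed: int = 0,
) -> AngleSet:
    """Decoding-axis geometry of one session.

    Trial axes decode the current trial's labels; ITI axes decode the
    just-completed (preceding) trial's labels.  Reports the between-phase
    angle per feature (with shuffled-label reference angles), all
    within-phase feature-pair angles, and the fold-axis variability: the SD
    over LOO folds of the angle between each fold's axis and the full-data
    axis.
    """
    if active_ids is None:
        active_ids = select_active_neurons(session)
    rng = np.random.default_rng(seed)
    sets = {
        "trial": phase_rate_vectors(session, "trial", active_ids),
        "iti": phase_rate_vectors(session, "iti", active_ids),
    }
    refs = {"trial": "current", "iti": "previous"}
    axes: dict[tuple[str, str], DecoderAxis] = {}
    labels_by_phase: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for phase in ("trial", "iti"):
        for f in FEATURES:
            idx, lab = aligned_labels(session.trials.labels(f), phase, refs[phase])
            labels_by_phase[(phase, f)] = (idx, lab)
            axes[(phase, f)] = fit_decoder_axis(sets[phase].rates[idx], lab, feature=f, phase=phase)

    between = {f: angle_between(axes[("trial", f)].weights, axes[("iti", f)].weights) for f in FEATURES}

    between_shuffled = {}
    for f in FEATURES:
        arr = np.empty(shuffle_reps)
        for r in range(shuffle_reps):
            ws = {}
            for phase in ("trial", "iti"):
                idx, lab = labels_by_phase[(phase, f)]
                ws[phase] = fit_decoder_axis(sets[phase].rates[idx], lab[rng.permutation(len(lab))]).weights
            arr[r] = angle_between(ws["trial"], ws["iti"])
        between_shuffled[f] = arr

    within = {}
    for phase in ("trial", "iti"):
        for i, f1 in enumerate(FEATURES):
            for f2 in FEATURES[i + 1 :]:
                within[(phase, f1, f2)] = angle_between(axes[(phase, f1)].weights, axes[(phase, f2)].weights)

    fold_sd = {}
    for phase in ("trial", "iti"):
        for f in FEATURES:
            idx, lab = labels_by_phase[(phase, f)]
            X = sets[phase].rates[idx]
            y, _ = _encode(lab)
            full = axes[(phase, f)].weights
            angs = []
            for i in range(len(y)):
                mask = np.ones(len(y), dtype=bool)
                mask[i] = False
                if len(np.unique(y[mask])) < 2:
                    continue
                angs.append(angle_between(fit_decoder_axis(X[mask], y[mask]).weights, full))
            fold_sd[(phase, f)] = float(np.std(angs)) if angs else np.nan
    return AngleSet(
        between_phase=between,
        between_phase_shuffled=between_shuffled,
        within_phase=within,
        fold_axis_sd=fold_sd,
    )


def cross_decode(
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    mode: str = "full",
    feature: str = "",
    train_phase: str = "",
    test_phase: str = "",
    null_reps: int = 0,
    seed: int | np.random.Generator = 0,
) -> CrossDecodingResult:
    """Train a decoder on one phase's vectors and score it on the other's.

    ``full``: fit on all training rows, score all test rows.  ``loo``: for
    each matched pair i, fit on training rows != i and predict test row i
    (guards against training-set optimism).  The null permutes trial indices
    and applies the SAME permutation to both sides, preserving the pairing.
    """
    Xtr, ytr_raw = np.asarray(train[0], dtype=float), np.asarray(train[1])
    Xte, yte_raw = np.asarray(test[0], dtype=float), np.asarray(test[1])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def run(ytr_r, yte_r) -> float:
        ytr, uniq = _encode(ytr_r)
        yte = (np.asarray(yte_r) == uniq[1]).astype(int)
        if mode == "full":
            clf, mu, sd = _fit(Xtr, ytr)
            return float(np.mean(_predict(clf, mu, sd, Xte) == yte))
        if mode == "loo":
            if len(Xtr) != len(Xte):
                raise ValueError("loo cross-decoding needs matched trial counts")
            preds = np.empty(len(yte), dtype=int)
            for i in range(len(yte)):
                mask = np.ones(len(ytr), dtype=bool)
                mask[i] = False
                if len(np.unique(ytr[mask])) < 2:
                    raise DegenerateLabelsError("degenerate labels in training fold")
                clf, mu, sd = _fit(Xtr[mask], ytr[mask])
                preds[i] = _predict(clf, mu, sd, Xte[i : i + 1])[0]
            return float(np.mean(preds == yte))
        raise ValueError("mode must be 'full' or 'loo'")

    acc = run(ytr_raw, yte_raw)
    nulls = np.empty(null_reps)
    for r in range(null_reps):
        perm = rng.permutation(len(ytr_raw))
        nulls[r] = run(ytr_raw[perm], yte_raw[perm] if len(yte_raw) == len(ytr_raw) else yte_raw)
    return CrossDecodingResult(
        train_phase=train_phase, test_phase=test_phase, mode=mode, feature=feature,
        accuracy=acc, null_accuracies=nulls,
    )


def position_decoding_profile(
    session: SessionRecording,
    feature: str,
    reference: str = "current",
    reps: int = 50,
    seed: int = 0,
    min_rows: int = 4,
    active_ids: list[int] | None = None,
    include_cross: bool = True,
) -> pd.DataFrame:
    """Decoding accuracy per maze section and phase, with shuffle nulls.

    One row per (phase, section): LOO accuracy, null mean, relative accuracy,
    and (optionally) the full-mode cross-phase accuracy at the matched
    section.  Sections with fewer than ``min_rows`` usable rows are skipped.
    """
    if active_ids is None:
        active_ids = select_active_neurons(session)
    lin = linearize_position(session)
    rng = np.random.default_rng(seed)
    labels_all = session.trials.labels(feature)
    rows = []
    sec_data: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
    for phase in ("trial", "iti"):
        for p in range(1, N_SECTIONS + 1):
            rv = section_rate_vectors(session, phase, p, active_ids, linearized=lin)
            idx, lab = aligned_labels(labels_all, phase, reference)
            keep = rv.valid[idx]
            X, y = rv.rates[idx][keep], lab[keep]
            if len(y) < min_rows or len(np.unique(y)) < 2:
                continue
            sec_data[(phase, p)] = (X, y)
            try:
                res = loo_decode(X, y, feature=feature, phase=phase, reference=reference)
                nulls = shuffled_chance(X, y, reps=reps, seed=rng)
            except DegenerateLabelsError:
                continue
            rows.append(
                {
                    "phase": phase,
                    "section": p,
                    "n_rows": len(y),
                    "accuracy": res.accuracy,
                    "null_mean": float(np.mean(nulls)),
                    "relative_accuracy": res.accuracy - float(np.mean(nulls)),
                    "null_q975": float(np.quantile(nulls, 0.975)),
                }
            )
    df = pd.DataFrame(rows)
    if include_cross and not df.empty:
        cross_rows = []
        for p in range(1, N_SECTIONS + 1):
            if ("trial", p) in sec_data and ("iti", p) in sec_data:
                Xt, yt = sec_data[("trial", p)]
                Xi, yi = sec_data[("iti", p)]
                try:
                    cr = cross_decode((Xt, yt), (Xi, yi), mode="full", feature=feature)
                    cross_rows.append({"section": p, "cross_accuracy": cr.accuracy})
                except (DegenerateLabelsError, ValueError):
                    continue
        if cross_rows:
            df = df.merge(pd.DataFrame(cross_rows), on="section", how="left")
    return df


def decoding_vs_performance(
    relative_accuracies: np.ndarray, performances: np.ndarray
) -> tuple[float, float, float]:
    """Cohort-level link between behavior and decoding.

    Spearman correlation (with two-sided p) between per-session proportion
    correct and per-session relative decoding accuracy, plus the slope of the
    least-squares line.  Requires >= 5 sessions; constant inputs give NaN.
    """
    acc = np.asarray(relative_accuracies, dtype=float)
    perf = np.asarray(performances, dtype=float)
    if len(acc) != len(perf) or len(acc) < 5:
        raise ValueError("need >= 5 paired sessions")
    if np.ptp(acc) == 0 or np.ptp(perf) == 0:
        return np.nan, np.nan, np.nan
    rho, p = stats.spearmanr(perf, acc)
    slope = float(np.polyfit(perf, acc, 1)[0])
    return float(rho), float(p), slope
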