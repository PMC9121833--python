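"""Linear separability of population activity in low-dimensional projections.

The question: do the population rate vectors of two task phases (trial vs
ITI, or inbound vs outbound) occupy different subspaces of rate space?  The
measure: project all vectors onto the top ``d`` principal axes of the pooled
data and report the training-set misclassification proportion of a linear
maximum-margin classifier — a geometric separability score, not a
generalization estimate.  Perfectly separated phases give error 0;
indistinguishable phases give error near the majority-class proportion
(0.5 for the balanced trial/ITI design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from .segmentation import (
    N_SECTIONS,
    PhaseMatrix,
    build_phase_matrix,
    detect_outbound_starts,
    linearize_position,
    section_rate_vectors,
    select_active_neurons,
)
from .session import SessionRecording

__all__ = [
    "SeparabilityResult",
    "SectionSeparabilityMaps",
    "pca_axes",
    "separability_error",
    "phase_separability",
    "section_separability",
    "inbound_outbound_separability",
]

#: soft-margin penalty; large enough to act as a hard margin when separable
#: while still letting libsvm converge on heavily overlapping data
SVM_C = 1e3


@dataclass
class SeparabilityResult:
    """Misclassification per projection dimensionality, with the axes used."""

    errors: dict[int, float]  # d -> misclassification proportion
    axes: dict[int, np.ndarray]  # d -> (d, N) orthonormal projection axes
    normals: dict[int, np.ndarray]  # d -> classifier normal in projected space
    chance: float
    split: str = "trial-iti"


@dataclass
class SectionSeparabilityMaps:
    """5x5 misclassification maps between maze sections (d = 2 projections).

    ``within_trial`` and ``within_iti`` compare two sections within one
    phase (diagonal undefined); ``cross_phase[i, j]`` compares trial-phase
    section i+1 against ITI-phase section j+1; its (5, 5) cell is the
    arm-end transition where the two phases meet in space and time.
    """

    within_trial: np.ndarray
    within_iti: np.ndarray
    cross_phase: np.ndarray


def pca_axes(matrix: np.ndarray, d: int, center: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Top-``d`` principal axes and the projected vectors.

    Columns are mean-centered before the eigendecomposition (switchable for
    sensitivity checks).  Axes are ordered by descending eigenvalue with a
    deterministic sign convention: the largest-magnitude component of each
    axis is positive.  Raises if ``d`` exceeds the matrix rank.
    """
    X = np.asarray(matrix, dtype=float)
    if d < 1 or X.shape[0] <= d:
        raise ValueError("require row count > d >= 1")
    Xc = X - X.mean(axis=0) if center else X.copy()
    rank = np.linalg.matrix_rank(Xc)
    if d > rank:
        raise ValueError(f"rank deficient: d={d} exceeds rank {rank}")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    axes = vt[:d]
    for k in range(d):
        j = np.argmax(np.abs(axes[k]))
        if axes[k, j] < 0:
            axes[k] = -axes[k]
    return axes, Xc @ axes.T


def _best_threshold_error(u: np.ndarray, y: np.ndarray) -> float:
    """Minimal 0-1 error over all thresholds and both orientations along u."""
    zs = np.unique(u)
    cuts = np.concatenate([[zs[0] - 1.0], (zs[:-1] + zs[1:]) / 2.0, [zs[-1] + 1.0]])
    pred = u[None, :] > cuts[:, None]
    errs = np.mean(pred != y[None, :].astype(bool), axis=1)
    return float(min(errs.min(), (1.0 - errs).min()))


def separability_error(projected: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Misclassification of the best linear separator along the margin direction.

    A linear maximum-margin classifier (soft margin, large fixed penalty)
    supplies the separating direction; the reported error is the minimal
    training-set misclassification over intercepts along that direction, so
    the score reflects geometric separability rather than hinge loss.  On 1-D
    projections this is exactly the optimal-threshold error.

    Returns (error proportion, classifier normal vector).  Requires at least
    two vectors of each of exactly two label values.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("degenerate labels: need exactly two classes")
    if min(np.sum(labels == u) for u in uniq) < 2:
        raise ValueError("degenerate labels: need >= 2 vectors per class")
    Z = np.asarray(projected, dtype=float)
    if Z.ndim == 1:
        Z = Z.reshape(-1, 1)
    y = (labels == uniq[1]).astype(int)
    # one global scale keeps the geometry but makes the margin fit (and hence
    # the reported error) invariant to common rescaling of the rate vectors
    Zc = Z - Z.mean(axis=0)
    scale = np.sqrt(np.mean(Zc**2))
    Zs = Zc / scale if scale > 0 else Zc
    clf = SVC(kernel="linear", C=SVM_C, max_iter=1_000_000)
    with warnings.catch_warnings():
        # the intercept rescan below absorbs residual solver imprecision
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Zs, y)
    w = clf.coef_.ravel().copy()
    if np.linalg.norm(w) < 1e-12:  # e.g. identical clouds: fall back to mean axis
        w = Zs[y == 1].mean(axis=0) - Zs[y == 0].mean(axis=0)
    if np.linalg.norm(w) < 1e-12:
        return float(min(np.mean(y == 1), np.mean(y == 0))), w
    err = _best_threshold_error(Zs @ w, y)
    return err, w


def phase_separability(
    session: SessionRecording,
    dims: tuple[int, ...] = (1, 2, 3, 4),
    split: str = "trial-iti",
    active_ids: list[int] | None = None,
    outbound_starts=None,
) -> SeparabilityResult:
    """Separability of the two phases' rate vectors at each dimensionality."""
    pm = build_phase_matrix(session, active_ids, split=split, outbound_starts=outbound_starts)
    return _matrix_separability(pm.matrix, pm.labels, dims, split)


def _matrix_separability(X: np.ndarray, labels: np.ndarray, dims, split: str) -> SeparabilityResult:
    errors, axes_d, normals = {}, {}, {}
    counts = [np.mean(labels == u) for u in np.unique(labels)]
    for d in dims:
        axes, Z = pca_axes(X, d)
        err, w = separability_error(Z, labels)
        errors[d], axes_d[d], normals[d] = err, axes, w
    return SeparabilityResult(errors=errors, axes=axes_d, normals=normals, chance=float(max(counts)), split=split)


def section_separability(
    session: SessionRecording,
    d: int = 2,
    min_rows: int = 3,
    active_ids: list[int] | None = None,
) -> SectionSeparabilityMaps:
    """Pairwise misclassification maps between maze sections (d = 2).

    Builds per-section rate vectors for both phases, then for every section
    pair stacks the two sets, projects to ``d`` dimensions, and scores the
    linear classifier.  Pairs with fewer than ``min_rows`` usable rows per
    side are left NaN, as are the within-map diagonals.
    """
    if active_ids is None:
        active_ids = select_active_neurons(session)
    lin = linearize_position(session)
    vecs = {}
    for phase in ("trial", "iti"):
        for p in range(1, N_SECTIONS + 1):
            rv = section_rate_vectors(session, phase, p, active_ids, linearized=lin)
            vecs[(phase, p)] = rv.rates[rv.valid]

    def pair_error(A: np.ndarray, B: np.ndarray) -> float:
        if len(A) < min_rows or len(B) < min_rows:
            return np.nan
        X = np.vstack([A, B])
        y = np.concatenate([np.zeros(len(A)), np.ones(len(B))])
        try:
            _, Z = pca_axes(X, d)
        except ValueError:
            return np.nan
        err, _ = separability_error(Z, y)
        return err

    within = {}
    for phase in ("trial", "iti"):
        M = np.full((N_SECTIONS, N_SECTIONS), np.nan)
        for i in range(1, N_SECTIONS + 1):
            for j in range(i + 1, N_SECTIONS + 1):
                e = pair_error(vecs[(phase, i)], vecs[(phase, j)])
                M[i - 1, j - 1] = M[j - 1, i - 1] = e
        within[phase] = M
    cross = np.full((N_SECTIONS, N_SECTIONS), np.nan)
    for i in range(1, N_SECTIONS + 1):
        for j in range(1, N_SECTIONS + 1):
            cross[i - 1, j - 1] = pair_error(vecs[("trial", i)], vecs[("iti", j)])
    return SectionSeparabilityMaps(within_trial=within["trial"], within_iti=within["iti"], cross_phase=cross)


def inbound_outbound_separability(
    session: SessionRecording,
    dims: tuple[int, ...] = (1, 2, 3, 4),
    active_ids: list[int] | None = None,
) -> dict:
    """Separability under the inbound/outbound split, paired with trial/ITI.

    The inbound phase runs from trial start to the detected outbound start
    (heading reversal); the outbound phase from there to the ITI end.  Returns
    both splits' errors and their per-dimension difference, the inputs to a
    cohort-level paired signed-rank comparison.
    """
    ob = detect_outbound_starts(session)
    res_io = phase_separability(session, dims, split="inbound-outbound", active_ids=active_ids, outbound_starts=ob)
    res_ti = phase_separability(session, dims, split="trial-iti", active_ids=active_ids)
    diff = {d: res_io.errors[d] - res_ti.errors[d] for d in dims}
    return {"inbound_outbound": res_io, "trial_iti": res_ti, "difference": diff, "outbound_starts": ob}
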