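"""Behavioral classification of sessions and reward-rate change points.

A session is one block of trials under a fixed (possibly mid-session
changing) rule.  Sessions are classed as:

* ``learning`` — the outcome sequence contains three consecutive correct
  trials followed by at least 80% correct through the session end; the first
  of the three is the learning trial;
* ``rule-change`` — no learning criterion met but the metadata records the
  trial at which the rule switched;
* ``other`` — neither; the split is placed where the increase in reward
  rate, r_after - r_before, is maximized (earliest trial on ties), with at
  least ``min_side`` trials on each side.

Reward rates are the slopes of robust (bisquare IRLS) line fits to the
cumulative reward curve on each side of the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .session import SessionRecording

__all__ = [
    "LearningAssessment",
    "find_learning_trial",
    "reward_rates",
    "classify_session",
    "session_performance",
]

#: bisquare tuning constant (95% Gaussian efficiency) and iteration cap
BISQUARE_C = 4.685
MAX_ITER = 50


@dataclass
class LearningAssessment:
    session_class: str  # {"learning", "rule-change", "other"}
    split_trial: int | None  # 1-based
    r_before: float
    r_after: float

    @property
    def delta_r(self) -> float:
        return self.r_after - self.r_before


def find_learning_trial(outcomes: np.ndarray) -> int | None:
    """First trial t (1-based) with o_t = o_{t+1} = o_{t+2} = 1 and
    mean(o_t..o_T) >= 0.8, or None.

    The >= 80% window includes the three-trial run itself and extends to the
    session end.
    """
    o = np.asarray(outcomes, dtype=int)
    T = len(o)
    if T < 3:
        raise ValueError("need at least 3 trials")
    for t in range(T - 2):
        if o[t] and o[t + 1] and o[t + 2] and o[t:].mean() >= 0.8:
            return t + 1
    return None


def _robust_slope(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        raise ValueError("need at least 2 trials on each side of the split")
    if len(x) == 2 or np.ptp(y) == 0:
        # exact or degenerate line: IRLS adds nothing
        return float(np.polyfit(x, y, 1)[0])
    X = sm.add_constant(x.astype(float))
    with warnings.catch_warnings():
        # perfect fits drive the IRLS scale to zero; the slope is still exact
        warnings.simplefilter("ignore")
        fit = sm.RLM(y.astype(float), X, M=sm.robust.norms.TukeyBiweight(BISQUARE_C)).fit(maxiter=MAX_ITER)
    return float(fit.params[1])


def reward_rates(outcomes: np.ndarray, split_trial: int) -> tuple[float, float]:
    """Reward-accumulation slopes before/after ``split_trial`` (1-based).

    Robust lines are fit to the cumulative reward curve on trials
    [1, split-1] and [split, T]; the slopes are in units of correct trials
    per trial, so they live in [0, 1] up to regression tolerance.
    """
    o = np.asarray(outcomes, dtype=float)
    T = len(o)
    if not (1 <= split_trial <= T):
        raise ValueError("split trial out of range")
    cum = np.cumsum(o)
    x = np.arange(1, T + 1, dtype=float)
    before = slice(0, split_trial - 1)
    after = slice(split_trial - 1, T)
    r_before = _robust_slope(x[before], cum[before])
    r_after = _robust_slope(x[after], cum[after])
    return r_before, r_after


def classify_session(
    session_or_outcomes: SessionRecording | np.ndarray,
    rule_change_trial: int | None = None,
    min_side: int = 5,
) -> LearningAssessment:
    """Classify a session and locate its performance split.

    Accepts a full session (metadata supplies the rule-change trial) or a
    bare outcome sequence.  For "other" sessions the split maximizes
    r_after - r_before over trials with at least ``min_side`` trials on each
    side; sessions too short for any feasible split get class "other" with
    no split.
    """
    if isinstance(session_or_outcomes, SessionRecording):
        outcomes = session_or_outcomes.trials.labels("outcome")
        rule_change_trial = session_or_outcomes.metadata.get("rule_change_trial", rule_change_trial)
    else:
        outcomes = np.asarray(session_or_outcomes)
    T = len(outcomes)

    learn = find_learning_trial(outcomes) if T >= 3 else None
    if learn is not None and learn >= 3:
        rb, ra = reward_rates(outcomes, learn)
        return LearningAssessment("learning", learn, rb, ra)
    if learn is not None:
        # learning at the very start leaves < 2 pre-split trials for a line;
        # report slope 0 before (no rewards yet) and the fitted slope after
        _, ra = 0.0, _robust_slope(np.arange(learn, T + 1, dtype=float), np.cumsum(outcomes)[learn - 1 :])
        return LearningAssessment("learning", learn, 0.0, ra)
    if rule_change_trial is not None:
        rb, ra = reward_rates(outcomes, int(rule_change_trial))
        return LearningAssessment("rule-change", int(rule_change_trial), rb, ra)

    lo, hi = min_side + 1, T - min_side
    if lo > hi:
        if T >= 4:  # single feasible split at the midpoint-ish fallback
            mid = T // 2 + 1
            try:
                rb, ra = reward_rates(outcomes, mid)
                return LearningAssessment("other", mid, rb, ra)
            except ValueError:
                pass
        return LearningAssessment("other", None, np.nan, np.nan)
    best_t, best_delta, best = None, -np.inf, (np.nan, np.nan)
    for t in range(lo, hi + 1):
        rb, ra = reward_rates(outcomes, t)
        if ra - rb > best_delta + 1e-12:
            best_t, best_delta, best = t, ra - rb, (rb, ra)
    return LearningAssessment("other", best_t, best[0], best[1])


def session_performance(outcomes: np.ndarray) -> float:
    """Proportion of correct trials."""
    o = np.asarray(outcomes, dtype=float)
    if len(o) < 1:
        raise ValueError("need at least one trial")
    return float(o.mean())
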