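"""Cohort-synchronous dose recommendation, stopping rules and MTD declaration.

After each complete cohort the posterior is updated and the next cohort
is assigned the level whose estimated DLT probability is closest to the
target, subject to a no-skip restriction when escalating (never more
than one level above the highest level administered so far;
de-escalation is unrestricted).  Two early-stopping rules apply, in
order:

1. stop for toxicity (no MTD) when the posterior probability that the
   lowest dose's DLT rate exceeds theta_L passes the threshold;
2. stop and confirm the MTD when the most recent ``consecutive_cohorts``
   cohorts all sat at one level and that level is also the next
   recommendation.

If neither rule fires by the maximum sample size, the declared MTD is
the model argmin over all levels (the no-skip cap governs assignment,
not declaration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignSpec, ToxicityHistory, ValidationError
from .model import posterior_summary

__all__ = ["TrialStatus", "recommend_next_dose", "check_stopping"]

CONTINUE = "continue"
STOPPED_TOXIC = "stopped_toxic"
STOPPED_MTD_CONFIRMED = "stopped_mtd_confirmed"
STOPPED_MAX_N = "stopped_max_n"


@dataclass(frozen=True)
class TrialStatus:
    """Outcome of the stopping-rule evaluation after a complete cohort."""

    state: str
    recommended_level: int | None = None  # next assignment if continuing (1-based)
    mtd_level: int | None = None  # declared MTD on stop; None on toxic stop


def _model_argmin(history: ToxicityHistory, spec: DesignSpec) -> int:
    """Uncapped model recommendation: level closest to target, ties lower."""
    summ = posterior_summary(history, spec)
    dist = np.abs(np.asarray(summ.tox_hat) - spec.target_theta)
    return int(np.argmin(dist)) + 1  # np.argmin takes the first (lower) on ties


def recommend_next_dose(history: ToxicityHistory, spec: DesignSpec) -> int:
    """Dose level for the next cohort (1-based), no-skip cap applied.

    An empty history returns the fixed starting level.
    """
    history.validate(n_levels=spec.n_levels)
    if history.n_patients == 0:
        return spec.start_level
    history.require_complete_cohorts(spec.cohort_size)
    uncapped = _model_argmin(history, spec)
    return min(uncapped, history.highest_level_administered() + 1)


def check_stopping(history: ToxicityHistory, spec: DesignSpec) -> TrialStatus:
    """Evaluate both stopping rules and the sample-size cap, in order.

    Returns the trial state after the last complete cohort, with the
    recommended next level when continuing, or the declared MTD when
    stopping.  A toxic signal (rule 1) dominates MTD confirmation.
    """
    history.validate(n_levels=spec.n_levels)
    history.require_complete_cohorts(spec.cohort_size)
    if history.n_patients == 0:
        return TrialStatus(state=CONTINUE, recommended_level=spec.start_level)

    summ = posterior_summary(history, spec)
    if summ.prob_lowest_toxic > spec.stop_prob_threshold:
        return TrialStatus(state=STOPPED_TOXIC, mtd_level=None)

    recommendation = recommend_next_dose(history, spec)

    levels = history.cohort_levels()
    m = spec.consecutive_cohorts
    if (
        len(levels) >= m
        and len(set(levels[-m:])) == 1
        and recommendation == levels[-1]
    ):
        return TrialStatus(state=STOPPED_MTD_CONFIRMED, mtd_level=levels[-1])

    if history.n_patients >= spec.max_n:
        mtd = _model_argmin(history, spec)
        if spec.restrict_mtd_to_tested:
            tested = {rec.dose_level for rec in history.records}
            mtd = min(tested, key=lambda k: (abs(k - mtd), k))
        return TrialStatus(state=STOPPED_MAX_N, mtd_level=mtd)

    return TrialStatus(state=CONTINUE, recommended_level=recommendation)
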