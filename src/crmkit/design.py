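"""Design configuration and trial-history containers.

A phase I CRM design is fully specified by the dose set, the skeleton of
prior DLT probabilities, the target DLT rate, the prior SD of the slope
parameter, the cohort structure, and the two early-stopping rules.  The
default configuration is the final calibrated design of a five-level
seliciclib dose-finding study (200-1000 mg, target 35%, cohorts of 3,
maximum 21 patients); see :func:`crmkit.calibration.default_design`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


class ValidationError(ValueError):
    """Raised when a design, history or configuration violates its invariants."""


@dataclass(frozen=True)
class DesignSpec:
    """Complete configuration of a one-parameter Bayesian logistic CRM design.

    Parameters
    ----------
    doses_mg:
        Administered dose amounts in mg, strictly increasing.  Labels only:
        the model sees the scaled doses derived from the skeleton.
    skeleton:
        Prior DLT probability at each dose level, strictly increasing,
        each in (0, 1).
    target_theta:
        Target DLT rate; the MTD is the level whose estimated DLT
        probability is closest to this value.
    sigma_beta:
        Prior SD of the slope parameter beta (prior is N(0, sigma_beta^2)).
    intercept:
        Fixed intercept of the logistic dose-toxicity model.
    start_level:
        1-based dose level of the first cohort.
    cohort_size:
        Patients per cohort; the design is cohort-synchronous.
    max_n:
        Maximum number of patients; must be a multiple of ``cohort_size``.
    stop_prob_threshold:
        Rule-1 cutoff: stop for toxicity when the posterior probability
        that the lowest dose's DLT rate exceeds ``theta_L`` is above this.
    consecutive_cohorts:
        Rule-2 count: stop and declare the MTD once this many consecutive
        cohorts sat at one level and that level is also the next
        recommendation.
    theta_L:
        Comparison rate for rule 1; defaults to ``target_theta``.
    tox_estimate:
        ``"plugin"`` evaluates the dose-toxicity curve at the posterior
        mean of beta (the dfcrm convention); ``"posterior_mean"`` uses the
        posterior mean of the toxicity probability itself.
    restrict_mtd_to_tested:
        If True, the MTD declared at ``max_n`` is restricted to levels
        actually administered; by default the model argmin over all levels
        is reported.
    """

    doses_mg: tuple[float, ...]
    skeleton: tuple[float, ...]
    target_theta: float = 0.35
    sigma_beta: float = 0.265
    intercept: float = 3.0
    start_level: int = 2
    cohort_size: int = 3
    max_n: int = 21
    stop_prob_threshold: float = 0.7
    consecutive_cohorts: int = 4
    theta_L: float | None = None
    tox_estimate: str = "plugin"
    restrict_mtd_to_tested: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses_mg", tuple(float(d) for d in self.doses_mg))
        object.__setattr__(self, "skeleton", tuple(float(p) for p in self.skeleton))
        if len(self.doses_mg) != len(self.skeleton):
            raise ValidationError("doses_mg and skeleton must have equal length")
        if len(self.skeleton) == 0:
            raise ValidationError("at least one dose level is required")
        if any(b <= a for a, b in zip(self.doses_mg, self.doses_mg[1:])):
            raise ValidationError("doses_mg must be strictly increasing")
        if any(not (0.0 < p < 1.0) for p in self.skeleton):
            raise ValidationError("skeleton entries must lie in (0, 1)")
        if any(b <= a for a, b in zip(self.skeleton, self.skeleton[1:])):
            raise ValidationError("skeleton must be strictly increasing")
        if not (0.0 < self.target_theta < 1.0):
            raise ValidationError("target_theta must lie in (0, 1)")
        if not (0.0 < self.stop_prob_threshold < 1.0):
            raise ValidationError("stop_prob_threshold must lie in (0, 1)")
        if self.sigma_beta <= 0.0:
            raise ValidationError("sigma_beta must be positive")
        if not (1 <= self.start_level <= self.n_levels):
            raise ValidationError("start_level out of range")
        if self.cohort_size < 1 or self.max_n < 1:
            raise ValidationError("cohort_size and max_n must be positive")
        if self.max_n % self.cohort_size != 0:
            raise ValidationError("max_n must be a multiple of cohort_size")
        if self.consecutive_cohorts < 1:
            raise ValidationError("consecutive_cohorts must be positive")
        if self.theta_L is not None and not (0.0 < self.theta_L < 1.0):
            raise ValidationError("theta_L must lie in (0, 1)")
        if self.tox_estimate not in ("plugin", "posterior_mean"):
            raise ValidationError("tox_estimate must be 'plugin' or 'posterior_mean'")

    @property
    def n_levels(self) -> int:
        return len(self.skeleton)

    @property
    def theta_L_effective(self) -> float:
        return self.target_theta if self.theta_L is None else self.theta_L

    @property
    def max_cohorts(self) -> int:
        return self.max_n // self.cohort_size

    def with_(self, **changes) -> "DesignSpec":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    cohort: int
    dose_level: int  # 1-based
    dlt: int  # 0 or 1


@dataclass
class ToxicityHistory:
    """Ordered per-patient dosing and DLT records of a cohort-synchronous trial.

    Invariants: dose levels are 1-based; all members of a cohort share one
    dose level; DLT outcomes are 0/1.
    """

    records: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, n_levels: int | None = None) -> None:
        cohort_level: dict[int, int] = {}
        for rec in self.records:
            if rec.dlt not in (0, 1):
                raise ValidationError(
                    f"patient {rec.patient_id}: dlt must be 0 or 1, got {rec.dlt}"
                )
            if rec.dose_level < 1:
                raise ValidationError(
                    f"patient {rec.patient_id}: dose_level must be >= 1"
                )
            if n_levels is not None and rec.dose_level > n_levels:
                raise ValidationError(
                    f"patient {rec.patient_id}: dose_level {rec.dose_level} "
                    f"exceeds the {n_levels}-level design"
                )
            seen = cohort_level.setdefault(rec.cohort, rec.dose_level)
            if seen != rec.dose_level:
                raise ValidationError(
                    f"cohort {rec.cohort} mixes dose levels {seen} and {rec.dose_level}"
                )

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_cohorts(
        cls, cohorts: Iterable[tuple[int, int]], cohort_size: int = 3
    ) -> "ToxicityHistory":
        """Build a history from ``(dose_level, dlt_count)`` pairs, one per cohort."""
        records: list[PatientRecord] = []
        pid = 0
        for c, (level, n_dlt) in enumerate(cohorts, start=1):
            if not (0 <= n_dlt <= cohort_size):
                raise ValidationError(
                    f"cohort {c}: dlt count {n_dlt} outside 0..{cohort_size}"
                )
            for j in range(cohort_size):
                pid += 1
                records.append(
                    PatientRecord(str(pid), c, level, 1 if j < n_dlt else 0)
                )
        return cls(records)

    # -- views ------------------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.records)

    def counts_by_level(self, n_levels: int) -> tuple[tuple[int, int], ...]:
        """Sufficient statistics: ``(n_treated, n_dlt)`` per dose level."""
        n = [0] * n_levels
        t = [0] * n_levels
        for rec in self.records:
            if rec.dose_level > n_levels:
                raise ValidationError(
                    f"dose_level {rec.dose_level} exceeds the {n_levels}-level design"
                )
            n[rec.dose_level - 1] += 1
            t[rec.dose_level - 1] += rec.dlt
        return tuple(zip(n, t))

    def cohort_levels(self) -> list[int]:
        """Dose level of each complete cohort in enrolment order."""
        levels: list[int] = []
        seen: list[int] = []
        for rec in self.records:
            if rec.cohort not in seen:
                seen.append(rec.cohort)
                levels.append(rec.dose_level)
        return levels

    def cohort_sizes(self) -> list[int]:
        sizes: dict[int, int] = {}
        order: list[int] = []
        for rec in self.records:
            if rec.cohort not in sizes:
                order.append(rec.cohort)
            sizes[rec.cohort] = sizes.get(rec.cohort, 0) + 1
        return [sizes[c] for c in order]

    def require_complete_cohorts(self, cohort_size: int) -> None:
        bad = [s for s in self.cohort_sizes() if s != cohort_size]
        if bad:
            raise ValidationError(
                f"history contains incomplete cohorts (sizes {bad}, "
                f"expected {cohort_size})"
            )

    def highest_level_administered(self) -> int:
        """Highest 1-based dose level given so far; 0 for an empty history."""
        return max((rec.dose_level for rec in self.records), default=0)

    def extended(
        self, dose_level: int, dlt_count: int, cohort_size: int
    ) -> "ToxicityHistory":
        """A new history with one additional complete cohort appended."""
        next_cohort = max((r.cohort for r in self.records), default=0) + 1
        base = self.n_patients
        extra = [
            PatientRecord(
                str(base + j + 1), next_cohort, dose_level, 1 if j < dlt_count else 0
            )
            for j in range(cohort_size)
        ]
        return ToxicityHistory(self.records + extra)


def scale_doses(skeleton: Sequence[float], intercept: float = 3.0) -> tuple[float, ...]:
    """Back-transform a skeleton to scaled doses.

    The scaled dose of level k is the value x_k at which the dose-toxicity
    model with the prior-modal slope (beta = 0) returns the skeleton
    probability: ``x_k = logit(skeleton_k) - intercept``.
    """
    import math

    xs = []
    for p in skeleton:
        if not (0.0 < p < 1.0):
            raise ValidationError(f"skeleton entry {p} outside (0, 1)")
        xs.append(math.log(p / (1.0 - p)) - intercept)
    return tuple(xs)
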