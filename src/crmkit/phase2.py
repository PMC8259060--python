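"""Fleming-A'Hern single-stage phase II design and composite response rule.

The single-arm design recruits n patients and declares the treatment
worth further study iff at least r respond, where (n, r) is the smallest
design whose exact binomial error rates satisfy

    P(X >= r | n, p0) <= alpha_max   (type I, under the unacceptable rate)
    P(X >= r | n, p1) >= 1 - beta_max  (power, under the desirable rate).

Response here is a composite: a patient is a responder iff assessable at
12 weeks and meeting at least two of the three criteria — clinical
(EULAR moderate or ACR20), histological (>= 20% reduction of sub-lining
synovial macrophages), imaging (RAMRIS reduction >= 0.5 or osteitis
>= 0.2).  Missing or non-assessable patients count as non-responders,
and the response rate denominator is every patient who started
treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom

from .design import ValidationError

__all__ = [
    "AHernDesign",
    "PatientResponse",
    "Phase2Result",
    "ahern_design",
    "composite_response",
    "evaluate_phase2",
]


@dataclass(frozen=True)
class AHernDesign:
    n: int
    r: int  # critical minimum number of responses
    p0: float
    p1: float
    alpha_max: float
    beta_max: float
    alpha_attained: float  # P(X >= r | n, p0)
    power_attained: float  # P(X >= r | n, p1)


@dataclass(frozen=True)
class PatientResponse:
    """Pre-computed criterion flags for one patient; None means missing."""

    clinical: bool | None = None
    histological: bool | None = None
    imaging: bool | None = None
    assessable_at_12w: bool = True
    patient_id: str = ""


@dataclass(frozen=True)
class Phase2Result:
    n_patients: int
    n_responders: int
    response_rate: float
    go: bool  # further investigation warranted (responders >= r)


def ahern_design(
    p0: float,
    p1: float,
    alpha_max: float,
    beta_max: float,
    n_cap: int = 500,
) -> AHernDesign:
    """Smallest exact single-stage design meeting both error bounds.

    Exhaustive search over n = 1..n_cap and r = 0..n; returns the first
    feasible (n, r) — minimal n, and minimal r at that n — with the
    attained exact binomial error rates.
    """
    if not (0.0 < p0 < p1 < 1.0):
        raise ValidationError("require 0 < p0 < p1 < 1")
    if not (0.0 < alpha_max < 1.0 and 0.0 < beta_max < 1.0):
        raise ValidationError("error bounds must lie in (0, 1)")
    for n in range(1, n_cap + 1):
        # P(X >= r) decreases in r; find the smallest r meeting alpha,
        # then check power there (larger r only lowers power).
        for r in range(0, n + 1):
            alpha = float(binom.sf(r - 1, n, p0))
            if alpha <= alpha_max:
                power = float(binom.sf(r - 1, n, p1))
                if power >= 1.0 - beta_max:
                    return AHernDesign(
                        n=n,
                        r=r,
                        p0=p0,
                        p1=p1,
                        alpha_max=alpha_max,
                        beta_max=beta_max,
                        alpha_attained=alpha,
                        power_attained=power,
                    )
                break
    raise ValidationError(f"no feasible design with n <= {n_cap}")


def composite_response(p: PatientResponse) -> bool:
    """Responder iff assessable at 12 weeks and >= 2 of 3 criteria met.

    Missing criterion flags count as not met.
    """
    if not p.assessable_at_12w:
        return False
    return sum(bool(f) for f in (p.clinical, p.histological, p.imaging)) >= 2


def evaluate_phase2(patients: list[PatientResponse], design: AHernDesign) -> Phase2Result:
    """Go/no-go decision over all patients who started treatment.

    No-go iff the responder count is strictly below the critical number r.
    """
    if not patients:
        raise ValidationError("patients must be non-empty")
    n_resp = sum(composite_response(p) for p in patients)
    return Phase2Result(
        n_patients=len(patients),
        n_responders=n_resp,
        response_rate=n_resp / len(patients),
        go=n_resp >= design.r,
    )
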