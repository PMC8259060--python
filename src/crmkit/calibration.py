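"""Skeleton construction and prior calibration.

The skeleton is built from an indifference-interval half-width delta by
the standard recursion for the one-parameter logistic model (the
``getprior`` construction): the prior-MTD level nu is pinned at the
target rate theta, and neighbouring levels are placed so that adjacent
doses sit exactly theta -/+ delta apart on the model scale.  The prior SD
of the slope is then chosen "least informative": the value at which the
induced prior distribution of the MTD level has the SD of a discrete
uniform on 1..K, sqrt((K^2 - 1)/12).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .design import DesignSpec, ValidationError, scale_doses
from .model import dose_toxicity

__all__ = [
    "CalibrationSpec",
    "PriorMtdDistribution",
    "build_skeleton",
    "prior_mtd_distribution",
    "least_informative_sigma",
    "default_design",
]

#: Dose amounts (mg) of the reference five-level design.
DEFAULT_DOSES_MG = (200.0, 400.0, 600.0, 800.0, 1000.0)


@dataclass(frozen=True)
class CalibrationSpec:
    """Inputs of the skeleton construction.

    delta is the indifference-interval half-width: asymptotically the DLT
    probability of the selected dose falls in target_theta +/- delta.
    nu is the 1-based prior-MTD dose level.
    """

    delta: float
    target_theta: float = 0.35
    nu: int = 3
    K: int = 5
    intercept: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 < self.delta < min(self.target_theta, 1.0 - self.target_theta)):
            raise ValidationError(
                "delta must lie in (0, min(target_theta, 1 - target_theta))"
            )
        if not (1 <= self.nu <= self.K):
            raise ValidationError("nu must lie in 1..K")
        if self.K < 1:
            raise ValidationError("K must be >= 1")


@dataclass(frozen=True)
class PriorMtdDistribution:
    """Prior probability that each dose level is the MTD, and its index SD."""

    probs: tuple[float, ...]
    sd_mtd: float


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def build_skeleton(cal: CalibrationSpec) -> tuple[float, ...]:
    """Skeleton of prior DLT probabilities for the logistic CRM model.

    Level nu carries exactly ``target_theta``.  Going up from level k the
    slope b is chosen so that level k sits at theta - delta, and level
    k+1 is placed where that same curve reaches theta + delta; going down
    the roles of theta - delta and theta + delta are exchanged.  The
    skeleton entry is the placed dose evaluated at the prior mode beta=0.
    """
    theta, delta, a = cal.target_theta, cal.delta, cal.intercept
    lo, hi = _logit(theta - delta) - a, _logit(theta + delta) - a
    if lo >= 0.0 or hi >= 0.0:
        raise ValidationError(
            "construction requires theta +/- delta below expit(intercept)"
        )
    x = [0.0] * cal.K
    x[cal.nu - 1] = _logit(theta) - a
    for k in range(cal.nu - 1, cal.K - 1):
        slope = lo / x[k]  # exp(b) solving theta(x_k, b) = theta - delta
        x[k + 1] = hi / slope
    for k in range(cal.nu - 1, 0, -1):
        slope = hi / x[k]  # exp(b) solving theta(x_k, b) = theta + delta
        x[k - 1] = lo / slope
    skeleton = tuple(float(dose_toxicity(xk, 0.0, a)) for xk in x)
    if any(not (0.0 < p < 1.0) for p in skeleton) or any(
        q <= p for p, q in zip(skeleton, skeleton[1:])
    ):
        raise ValidationError(
            f"delta={delta} produces an invalid skeleton for K={cal.K}"
        )
    return skeleton


def _mtd_thresholds(
    skeleton, target_theta: float, intercept: float
) -> np.ndarray:
    """Slope values at which the MTD (argmin |theta_k - target|) switches level.

    Every dose's toxicity is decreasing in beta (scaled doses are
    negative), so the argmin is nondecreasing in beta and the selection
    region of each level is an interval.  The switch between levels k and
    k+1 is where theta_k and theta_{k+1} straddle the target equally:
    theta(x_k, b) + theta(x_{k+1}, b) = 2 * target_theta.
    """
    xs = scale_doses(skeleton, intercept)
    if any(x >= 0.0 for x in xs):
        raise ValidationError(
            "prior MTD integration requires all skeleton entries below expit(intercept)"
        )
    thresholds = []
    for k in range(len(xs) - 1):
        f = lambda b: (
            dose_toxicity(xs[k], b, intercept)
            + dose_toxicity(xs[k + 1], b, intercept)
            - 2.0 * target_theta
        )
        thresholds.append(brentq(f, -40.0, 40.0, xtol=1e-12))
    t = np.asarray(thresholds)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("MTD switch thresholds are not ordered")
    return t


def prior_mtd_distribution(
    skeleton,
    sigma_beta: float,
    target_theta: float = 0.35,
    intercept: float = 3.0,
) -> PriorMtdDistribution:
    """Exact prior distribution of the MTD level under beta ~ N(0, sigma^2).

    MTD(beta) = argmin_k |theta(x_k, beta) - target_theta| with ties to
    the lower (safer) level; the probabilities are normal-CDF differences
    between the switch thresholds.
    """
    if sigma_beta <= 0.0:
        raise ValidationError("sigma_beta must be positive")
    t = _mtd_thresholds(skeleton, target_theta, intercept)
    cdf = norm.cdf(t / sigma_beta)
    probs = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    idx = np.arange(1, len(skeleton) + 1)
    mean = float(probs @ idx)
    sd = math.sqrt(max(float(probs @ idx**2) - mean**2, 0.0))
    return PriorMtdDistribution(probs=tuple(float(p) for p in probs), sd_mtd=sd)


def least_informative_sigma(
    skeleton,
    target_theta: float = 0.35,
    intercept: float = 3.0,
    bracket: tuple[float, float] = (0.01, 5.0),
) -> float:
    """Prior slope SD at which the prior MTD-level SD equals the uniform SD.

    Solves sd_mtd(sigma) = sqrt((K^2 - 1)/12) by bisection on ``bracket``
    after checking that sd_mtd is increasing across it.
    """
    K = len(skeleton)
    if K < 2:
        raise ValidationError("least-informative sigma requires K >= 2")
    target_sd = math.sqrt((K**2 - 1) / 12.0)

    def sd_at(s: float) -> float:
        return prior_mtd_distribution(skeleton, s, target_theta, intercept).sd_mtd

    lo, hi = bracket
    grid = np.geomspace(lo, hi, 8)
    vals = [sd_at(s) for s in grid]
    if any(b < a for a, b in zip(vals, vals[1:])):
        raise ValidationError("sd_mtd is not monotone on the bracket")
    if not (vals[0] < target_sd < vals[-1]):
        raise ValidationError(
            f"target MTD-level SD {target_sd:.4f} not attained on bracket "
            f"[{lo}, {hi}] (range {vals[0]:.4f}..{vals[-1]:.4f})"
        )
    return float(brentq(lambda s: sd_at(s) - target_sd, lo, hi, xtol=1e-8))


def default_design(
    delta: float = 0.06,
    sigma_beta: float | None = 0.265,
    doses_mg=DEFAULT_DOSES_MG,
    **overrides,
) -> DesignSpec:
    """The final calibrated five-level design.

    The skeleton comes from the delta=0.06 indifference-interval
    construction (prior MTD at level 3); the prior slope SD defaults to
    the published rounded value 0.265 (the exact least-informative root
    is 0.2648).  Pass ``sigma_beta=None`` to recompute it.
    """
    cal = CalibrationSpec(delta=delta, K=len(doses_mg))
    skeleton = build_skeleton(cal)
    if sigma_beta is None:
        sigma_beta = least_informative_sigma(skeleton, cal.target_theta, cal.intercept)
    return DesignSpec(
        doses_mg=tuple(doses_mg),
        skeleton=skeleton,
        sigma_beta=sigma_beta,
        **overrides,
    )
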