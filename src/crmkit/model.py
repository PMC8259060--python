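"""One-parameter Bayesian logistic dose-toxicity model and posterior summaries.

The model is

    theta(x, beta) = expit(a + exp(beta) * x),

with fixed intercept ``a`` (default 3) and a single slope parameter beta
with prior N(0, sigma_beta^2).  Writing the slope as exp(beta) keeps the
dose-toxicity curve monotone increasing for every beta.  The scaled doses
x_k are negative for any skeleton entry below expit(a), so the curve at
every level is decreasing in beta: large beta means a safe drug.

All posterior quantities are one-dimensional integrals over beta and are
evaluated by adaptive quadrature; the posterior is analytically
intractable.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import expit

from .design import DesignSpec, ToxicityHistory, ValidationError, scale_doses

__all__ = [
    "dose_toxicity",
    "scale_doses",
    "posterior_summary",
    "posterior_beta_cdf",
    "posterior_beta_quantile",
    "PosteriorSummary",
    "QuadratureError",
]


class QuadratureError(RuntimeError):
    """Numerical integration failed to reach the requested accuracy."""


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior summaries of a CRM model given accumulated DLT data.

    Attributes
    ----------
    beta_mean:
        Posterior mean of the slope parameter beta.
    tox_hat:
        Per-level DLT probability estimates (plug-in at ``beta_mean`` or
        posterior means, per the design's ``tox_estimate`` convention).
    prob_lowest_toxic:
        Posterior probability that the DLT rate at the lowest dose exceeds
        ``theta_L`` (rule-1 statistic).
    normalizer:
        Normalising constant of the unnormalised posterior density.
    """

    beta_mean: float
    tox_hat: tuple[float, ...]
    prob_lowest_toxic: float
    normalizer: float


def dose_toxicity(x, beta, intercept: float = 3.0):
    """Probability of a DLT at scaled dose ``x`` given slope parameter ``beta``.

    Vectorised over ``x`` and ``beta``.  Strictly increasing in ``x`` and,
    for x < 0, strictly decreasing in ``beta``.
    """
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(beta))):
        raise ValidationError("dose_toxicity requires finite x and beta")
    out = expit(intercept + np.exp(beta) * x)
    return float(out) if out.ndim == 0 else out


def integration_bound(sigma_beta: float) -> float:
    """Half-width L of the beta integration interval.

    The likelihood involves exp(beta), decaying super-exponentially on the
    right, and is prior-dominated on the left; L = max(10*sigma, 8) leaves
    prior tail mass below 1e-12.
    """
    return max(10.0 * sigma_beta, 8.0)


def beta_lower_threshold(x1: float, theta_L: float, intercept: float = 3.0) -> float:
    """The slope value below which the lowest dose's DLT rate exceeds theta_L.

    theta(x_1, beta) > theta_L  iff  beta < log((logit(theta_L) - a) / x_1),
    valid when both logit(theta_L) - a and x_1 are negative.
    """
    num = math.log(theta_L / (1.0 - theta_L)) - intercept
    if not (num < 0.0 and x1 < 0.0):
        raise ValidationError(
            "rule-1 threshold requires theta_L < expit(intercept) and x_1 < 0"
        )
    return math.log(num / x1)


def _log_unnorm_posterior(beta, xs, ns, ts, sigma_beta, intercept):
    """log of prior(beta) * likelihood(beta), vectorised over beta."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    lp = -(beta**2) / (2.0 * sigma_beta**2)
    if len(xs):
        eta = intercept + np.exp(beta)[:, None] * np.asarray(xs)[None, :]
        # log(theta) = -log1p(exp(-eta)); log(1-theta) = -log1p(exp(eta))
        log_th = -np.logaddexp(0.0, -eta)
        log_1m = -np.logaddexp(0.0, eta)
        lp = lp + log_th @ np.asarray(ts, dtype=float) + log_1m @ (
            np.asarray(ns, dtype=float) - np.asarray(ts, dtype=float)
        )
    return lp


@functools.lru_cache(maxsize=100_000)
def _posterior_core(
    spec: DesignSpec, counts: tuple[tuple[int, int], ...]
) -> PosteriorSummary:
    """Posterior summaries from per-level sufficient statistics (cached).

    The likelihood depends on the history only through the per-level
    counts, so the cache makes cohort-by-cohort simulation cheap: distinct
    count states across thousands of simulated trials number in the
    hundreds.
    """
    xs_all = scale_doses(spec.skeleton, spec.intercept)
    ns = tuple(n for n, _ in counts)
    ts = tuple(t for _, t in counts)
    used = [k for k in range(len(counts)) if ns[k] > 0]
    xs = tuple(xs_all[k] for k in used)
    ns_u = tuple(ns[k] for k in used)
    ts_u = tuple(ts[k] for k in used)

    L = integration_bound(spec.sigma_beta)

    def unnorm(beta):
        return float(
            np.exp(
                _log_unnorm_posterior(
                    beta, xs, ns_u, ts_u, spec.sigma_beta, spec.intercept
                )
            )[0]
        )

    opts = dict(epsabs=1e-12, epsrel=1e-10, limit=200)
    Z, err_z = integrate.quad(unnorm, -L, L, **opts)
    if Z <= 0.0 or not math.isfinite(Z) or err_z > max(1e-9, 1e-6 * Z):
        raise QuadratureError(
            f"posterior normaliser unreliable: Z={Z!r}, abserr={err_z!r}"
        )
    m1, err_m = integrate.quad(lambda b: b * unnorm(b), -L, L, **opts)
    if err_m > max(1e-9, 1e-6 * abs(m1) + 1e-9):
        raise QuadratureError(f"posterior mean unreliable: abserr={err_m!r}")
    beta_mean = m1 / Z

    b_L = beta_lower_threshold(xs_all[0], spec.theta_L_effective, spec.intercept)
    if b_L <= -L:
        p_low = 0.0
    else:
        num, _ = integrate.quad(unnorm, -L, min(b_L, L), **opts)
        p_low = min(max(num / Z, 0.0), 1.0)

    if spec.tox_estimate == "plugin":
        tox_hat = tuple(
            float(dose_toxicity(x, beta_mean, spec.intercept)) for x in xs_all
        )
    else:
        tox_hat = tuple(
            integrate.quad(
                lambda b, xk=xk: dose_toxicity(xk, b, spec.intercept) * unnorm(b),
                -L,
                L,
                **opts,
            )[0]
            / Z
            for xk in xs_all
        )
    return PosteriorSummary(
        beta_mean=beta_mean,
        tox_hat=tox_hat,
        prob_lowest_toxic=p_low,
        normalizer=Z,
    )


def posterior_summary(history: ToxicityHistory, spec: DesignSpec) -> PosteriorSummary:
    """Posterior slope mean, per-dose toxicity estimates and rule-1 probability.

    An empty history returns prior quantities: ``beta_mean = 0`` and
    ``tox_hat`` equal to the skeleton (the prior is symmetric about 0).
    """
    history.validate(n_levels=spec.n_levels)
    return _posterior_core(spec, history.counts_by_level(spec.n_levels))


def posterior_beta_cdf(history: ToxicityHistory, spec: DesignSpec, b: float) -> float:
    """Posterior CDF of beta at ``b``, by quadrature."""
    history.validate(n_levels=spec.n_levels)
    counts = history.counts_by_level(spec.n_levels)
    summ = _posterior_core(spec, counts)
    xs_all = scale_doses(spec.skeleton, spec.intercept)
    used = [k for k in range(spec.n_levels) if counts[k][0] > 0]
    xs = tuple(xs_all[k] for k in used)
    ns = tuple(counts[k][0] for k in used)
    ts = tuple(counts[k][1] for k in used)
    L = integration_bound(spec.sigma_beta)
    if b <= -L:
        return 0.0
    if b >= L:
        return 1.0

    def unnorm(beta):
        return float(
            np.exp(
                _log_unnorm_posterior(beta, xs, ns, ts, spec.sigma_beta, spec.intercept)
            )[0]
        )

    num, _ = integrate.quad(unnorm, -L, b, epsabs=1e-12, epsrel=1e-10, limit=200)
    return min(max(num / summ.normalizer, 0.0), 1.0)


def posterior_beta_quantile(
    history: ToxicityHistory, spec: DesignSpec, q: float
) -> float:
    """Posterior quantile of beta, by root-finding on the quadrature CDF."""
    from scipy.optimize import brentq

    if not (0.0 < q < 1.0):
        raise ValidationError("quantile level must lie in (0, 1)")
    L = integration_bound(spec.sigma_beta)
    return float(
        brentq(
            lambda b: posterior_beta_cdf(history, spec, b) - q,
            -L,
            L,
            xtol=1e-10,
        )
    )
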