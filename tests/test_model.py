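"""Dose-toxicity model and posterior quadrature.

The Monte-Carlo checks use importance sampling with the N(0, sigma^2)
prior as proposal and the likelihood as weight — an oracle fully
independent of the quadrature path.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit
from scipy.stats import norm

import crmkit as ck
from crmkit.model import beta_lower_threshold, integration_bound

from conftest import random_history


def mc_weights(history, spec, betas):
    """Likelihood weights for prior draws (independent oracle)."""
    xs = np.asarray(ck.scale_doses(spec.skeleton, spec.intercept))
    w = np.ones_like(betas)
    for rec in history.records:
        th = expit(spec.intercept + np.exp(betas) * xs[rec.dose_level - 1])
        w *= th if rec.dlt else (1.0 - th)
    return w


def batch_ratio_se(num, den, n_batches=20):
    """SE of a ratio estimator sum(num)/sum(den) by batch means."""
    nb = len(num) // n_batches
    vals = [
        num[i * nb : (i + 1) * nb].sum() / den[i * nb : (i + 1) * nb].sum()
        for i in range(n_batches)
    ]
    return float(np.std(vals, ddof=1) / math.sqrt(n_batches))


class TestDoseToxicity:
    @pytest.mark.parametrize(
        "x, beta, expected",
        [
            (0.0, 0.0, expit(3.0)),
            (0.0, 1.7, expit(3.0)),  # x=0 eliminates the slope
            (-3.6190, 0.0, 0.35),
            (-4.8533, 0.0, 0.1355),
        ],
    )
    def test_known_values(self, x, beta, expected):
        assert ck.dose_toxicity(x, beta) == pytest.approx(expected, abs=5e-4)

    def test_rejects_nonfinite(self):
        with pytest.raises(ck.ValidationError):
            ck.dose_toxicity(float("nan"), 0.0)
        with pytest.raises(ck.ValidationError):
            ck.dose_toxicity(0.0, float("inf"))

    @given(
        x=st.floats(-10, 0),
        beta=st.floats(-3, 2),
        dx=st.floats(1e-6, 1),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_strictly_increasing_in_x_and_bounded(self, x, beta, dx):
        # ranges chosen to stay clear of float saturation of the logistic
        lo, hi = ck.dose_toxicity(x, beta), ck.dose_toxicity(x + dx, beta)
        assert 0.0 < lo < hi < 1.0


class TestScaleDoses:
    def test_roundtrip_through_model(self, skeleton):
        xs = ck.scale_doses(skeleton)
        back = [ck.dose_toxicity(x, 0.0) for x in xs]
        assert back == pytest.approx(list(skeleton), abs=1e-12)

    def test_target_entry(self):
        (x,) = ck.scale_doses([0.35])
        assert x == pytest.approx(math.log(0.35 / 0.65) - 3.0)
        (x0,) = ck.scale_doses([expit(3.0)])
        assert x0 == pytest.approx(0.0, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ck.ValidationError):
            ck.scale_doses([0.2, 1.0])


class TestPosterior:
    def test_empty_history_returns_prior(self, design):
        summ = ck.posterior_summary(ck.ToxicityHistory(), design)
        assert summ.beta_mean == pytest.approx(0.0, abs=1e-8)
        assert summ.tox_hat == pytest.approx(design.skeleton, abs=1e-9)

    def test_prior_rule1_probability_closed_form(self, design):
        # With no data the rule-1 statistic is the prior normal tail below beta_L.
        x1 = ck.scale_doses(design.skeleton)[0]
        b_L = beta_lower_threshold(x1, design.target_theta)
        expected = norm.cdf(b_L / design.sigma_beta)
        summ = ck.posterior_summary(ck.ToxicityHistory(), design)
        assert summ.prob_lowest_toxic == pytest.approx(expected, abs=1e-8)
        assert expected == pytest.approx(0.134, abs=5e-3)

    def test_density_normalised_on_independent_grid(self, design):
        # Trapezoid integration of prior*likelihood on a dense grid must
        # match the quadrature normaliser to ~1e-6 relative.
        hist = ck.ToxicityHistory.from_cohorts(
            [(2, 0), (3, 1), (4, 2), (4, 1), (3, 0), (3, 1), (3, 2)]
        )
        summ = ck.posterior_summary(hist, design)
        L = integration_bound(design.sigma_beta)
        betas = np.linspace(-L, L, 400_001)
        w = mc_weights(hist, design, betas) * np.exp(
            -(betas**2) / (2 * design.sigma_beta**2)
        )
        z_grid = np.trapezoid(w, betas)
        assert summ.normalizer == pytest.approx(z_grid, rel=1e-6)

    def test_quadrature_matches_importance_sampling(self, design):
        rng = np.random.default_rng(20260926)
        n_draws = 1_000_000
        for _ in range(20):
            hist = random_history(rng)
            summ = ck.posterior_summary(hist, design)
            betas = rng.normal(0.0, design.sigma_beta, n_draws)
            w = mc_weights(hist, design, betas)
            x1 = ck.scale_doses(design.skeleton)[0]
            b_L = beta_lower_threshold(x1, design.target_theta)
            ind = (betas < b_L).astype(float)

            bm = (betas * w).sum() / w.sum()
            se_bm = batch_ratio_se(betas * w, w)
            assert abs(summ.beta_mean - bm) <= 3 * se_bm + 1e-6

            pl = (ind * w).sum() / w.sum()
            se_pl = batch_ratio_se(ind * w, w)
            assert abs(summ.prob_lowest_toxic - pl) <= 3 * se_pl + 1e-6

    def test_tox_hat_increases_with_any_added_dlt(self, design):
        # One-parameter monotone model: a DLT anywhere raises every
        # estimated toxicity.  Exhaustive over two-cohort allocations.
        for l1 in range(1, 6):
            for l2 in range(1, 6):
                for d1 in range(4):
                    for d2 in range(3):
                        lo = ck.posterior_summary(
                            ck.ToxicityHistory.from_cohorts([(l1, d1), (l2, d2)]),
                            design,
                        )
                        hi = ck.posterior_summary(
                            ck.ToxicityHistory.from_cohorts([(l1, d1), (l2, d2 + 1)]),
                            design,
                        )
                        assert all(
                            h >= l - 1e-10 for l, h in zip(lo.tox_hat, hi.tox_hat)
                        )

    def test_rule1_probability_nondecreasing_in_level1_dlts(self, design):
        probs = [
            ck.posterior_summary(
                ck.ToxicityHistory.from_cohorts([(1, d)]), design
            ).prob_lowest_toxic
            for d in range(4)
        ]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_posterior_mean_convention_also_monotone(self, design):
        spec = design.with_(tox_estimate="posterior_mean")
        summ = ck.posterior_summary(
            ck.ToxicityHistory.from_cohorts([(2, 1), (2, 1)]), spec
        )
        assert all(b > a for a, b in zip(summ.tox_hat, summ.tox_hat[1:]))
        # and differs (slightly) from the plug-in convention
        plug = ck.posterior_summary(
            ck.ToxicityHistory.from_cohorts([(2, 1), (2, 1)]), design
        )
        assert summ.tox_hat != pytest.approx(plug.tox_hat, abs=1e-12)

    def test_beta_quantiles_invert_cdf(self, design):
        from crmkit.model import posterior_beta_cdf, posterior_beta_quantile

        hist = ck.ToxicityHistory.from_cohorts([(2, 1), (3, 2)])
        for q in (0.05, 0.5, 0.95):
            b = posterior_beta_quantile(hist, design, q)
            assert posterior_beta_cdf(hist, design, b) == pytest.approx(q, abs=1e-7)
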