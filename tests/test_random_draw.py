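import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate as sp_integrate
from scipy.stats import binom, beta as beta_dist

from tadard.classdn import ClassifierPerformance
from tadard.random_draw import (
    RDPriors,
    misclassified_param,
    priors_from_mutation_rate,
    rd_bayes_factor,
    rd_likelihood,
    rd_log_bayes_factor,
    rd_log_bf_array,
)
from tadard.variant_io import GeneCounts, GeneEntry


def perf(w1, w2, c=0.7):
    return ClassifierPerformance(c, w1, w2, 0, 0)


def brute_force_bf(x_d, x_h, w1, w2, p1, p0):
    """Independent oracle: explicit binomial pmf ratio."""
    q1 = w1 * p1 + (1 - w2) * (1 - p1)
    q0 = w1 * p0 + (1 - w2) * (1 - p0)
    return binom.pmf(x_d, x_d + x_h, q1) / binom.pmf(x_d, x_d + x_h, q0)


class TestMisclassifiedParam:
    def test_perfect_classifier_returns_p(self):
        assert misclassified_param(0.5, 1.0, 1.0) == 0.5

    @pytest.mark.parametrize("p", [0.0, 0.026, 0.5, 1.0])
    def test_uninformative_classifier_ignores_p(self, p):
        assert misclassified_param(p, 0.3, 0.7) == pytest.approx(0.3)

    def test_worked_value(self):
        assert misclassified_param(0.026, 0.376, 0.943) == pytest.approx(
            0.065294, abs=1e-6
        )

    def test_domain_check(self):
        with pytest.raises(ValueError):
            misclassified_param(1.2, 0.5, 0.5)


class TestLikelihood:
    def test_empty_draw_is_certain(self):
        assert rd_likelihood(0, 0, q=0.37) == 1.0

    def test_small_example(self):
        assert rd_likelihood(1, 1, q=0.5) == pytest.approx(0.5)

    @pytest.mark.parametrize("q", [0.0, 0.1, 0.5, 0.9, 1.0])
    def test_matches_scipy_binomial(self, q):
        for x_d in range(6):
            for x_h in range(6):
                assert rd_likelihood(x_d, x_h, q=q) == pytest.approx(
                    binom.pmf(x_d, x_d + x_h, q), abs=1e-14
                )

    @pytest.mark.parametrize("a, b", [(0.8, 30.0), (2.0, 2.0), (5.0, 1.5)])
    def test_beta_marginal_matches_quadrature(self, a, b):
        """Beta-binomial marginal equals numeric quadrature of the point
        likelihood against the Beta density, to 1e-10 relative error."""
        for x_d in range(11):
            for x_h in range(11 - x_d):
                marginal = rd_likelihood(x_d, x_h, beta=(a, b))
                oracle, _ = sp_integrate.quad(
                    lambda q: rd_likelihood(x_d, x_h, q=q) * beta_dist.pdf(q, a, b),
                    0.0,
                    1.0,
                    epsabs=1e-14,
                    epsrel=1e-13,
                )
                assert marginal == pytest.approx(oracle, rel=1e-10)


class TestBayesFactor:
    def test_equal_priors_give_unit_bf(self):
        priors = RDPriors(kind="point", p1=0.3, p0=0.3)
        for x_d, x_h in [(0, 0), (3, 1), (0, 7), (10, 10)]:
            res = rd_bayes_factor(GeneCounts("g", x_d, x_h), perf(0.376, 0.943), priors)
            assert res.bf_rd == pytest.approx(1.0)

    def test_no_variants_give_unit_bf(self):
        res = rd_bayes_factor(GeneCounts("g", 0, 0), perf(0.376, 0.943), RDPriors())
        assert res.bf_rd == 1.0

    def test_uninformative_classifier_gives_unit_bf(self):
        for x_d, x_h in [(2, 3), (8, 0), (0, 5)]:
            res = rd_bayes_factor(GeneCounts("g", x_d, x_h), perf(0.3, 0.7), RDPriors())
            assert res.bf_rd == pytest.approx(1.0)

    def test_worked_power_simulation_value(self):
        """x_d=2, x_h=3 at the c=0.7 operating point with the risk and
        non-risk de novo fractions gives BF ~ 7.55."""
        res = rd_bayes_factor(GeneCounts("g", 2, 3), perf(0.376, 0.943), RDPriors())
        assert res.bf_rd == pytest.approx(7.5539, rel=1e-3)
        assert res.bf_rd == pytest.approx(
            brute_force_bf(2, 3, 0.376, 0.943, 0.603, 0.026), rel=1e-12
        )

    def test_perfect_classifier_reduces_to_binomial_bf(self):
        """With w1=w2=1 the Random Draw BF is the plain binomial Bayes
        factor in (x_d, x_h) with parameters (p1, p0)."""
        priors = RDPriors(kind="point", p1=0.603, p0=0.026)
        for x_d in range(8):
            for x_h in range(8):
                res = rd_bayes_factor(GeneCounts("g", x_d, x_h), perf(1.0, 1.0), priors)
                oracle = binom.pmf(x_d, x_d + x_h, 0.603) / binom.pmf(
                    x_d, x_d + x_h, 0.026
                )
                if x_d + x_h:
                    assert res.bf_rd == pytest.approx(oracle, rel=1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        total=st.integers(1, 20),
        w1=st.floats(0.4, 1.0),
        w2=st.floats(0.7, 1.0),
    )
    def test_monotone_in_xd_and_matches_oracle(self, total, w1, w2):
        """With an informative classifier (w1+w2 > 1) and p1 > p0, the BF
        increases strictly with the de novo count at fixed total, and
        agrees with the brute-force pmf ratio everywhere."""
        if w1 + w2 <= 1.0:
            return
        priors = RDPriors()
        prev = None
        for x_d in range(total + 1):
            x_h = total - x_d
            res = rd_bayes_factor(GeneCounts("g", x_d, x_h), perf(w1, w2), priors)
            oracle = brute_force_bf(x_d, x_h, w1, w2, 0.603, 0.026)
            assert res.bf_rd == pytest.approx(oracle, rel=1e-9)
            if prev is not None:
                assert res.bf_rd > prev
            prev = res.bf_rd

    def test_anti_informative_classifier_flips_and_warns(self):
        """With w1+w2 < 1 the evidence direction reverses."""
        with pytest.warns(UserWarning, match="anti-informative"):
            lo = rd_bayes_factor(GeneCounts("g", 1, 4), perf(0.2, 0.3), RDPriors())
        with pytest.warns(UserWarning, match="anti-informative"):
            hi = rd_bayes_factor(GeneCounts("g", 4, 1), perf(0.2, 0.3), RDPriors())
        assert hi.bf_rd < lo.bf_rd

    def test_large_counts_no_overflow(self):
        """Log-space evaluation extends the small-count oracle to counts
        of order 1e4 without under/overflow."""
        res = rd_log_bayes_factor(4000, 6000, 0.376, 0.943, RDPriors())
        log_bf = res[0]
        q1 = misclassified_param(0.603, 0.376, 0.943)
        q0 = misclassified_param(0.026, 0.376, 0.943)
        oracle = 4000 * (math.log(q1) - math.log(q0)) + 6000 * (
            math.log1p(-q1) - math.log1p(-q0)
        )
        assert math.isfinite(log_bf)
        assert log_bf == pytest.approx(oracle, rel=1e-12)

    def test_degenerate_parameter_warns_not_crashes(self):
        priors = RDPriors(kind="point", p1=1.0, p0=0.0)
        with pytest.warns(UserWarning, match="degenerate"):
            res = rd_bayes_factor(GeneCounts("g", 2, 0), perf(1.0, 1.0), priors)
        assert res.bf_rd == math.inf

    def test_vectorized_path_agrees_with_scalar(self, rng):
        x_d = rng.integers(0, 12, size=50)
        x_h = rng.integers(0, 12, size=50)
        logs = rd_log_bf_array(x_d, x_h, 0.376, 0.943, RDPriors())
        for i in range(50):
            scalar, _, _ = rd_log_bayes_factor(
                int(x_d[i]), int(x_h[i]), 0.376, 0.943, RDPriors()
            )
            assert logs[i] == pytest.approx(scalar, rel=1e-12, abs=1e-12)

    def test_beta_prior_bf_with_perfect_classifier(self):
        """Beta-prior BF = ratio of beta-binomial marginals when w1=w2=1."""
        priors = RDPriors(kind="beta", p1=None, p0=None, a1=3.0, b1=2.0, a0=0.5, b0=18.0)
        res = rd_bayes_factor(GeneCounts("g", 2, 3), perf(1.0, 1.0), priors)
        oracle = rd_likelihood(2, 3, beta=(3.0, 2.0)) / rd_likelihood(
            2, 3, beta=(0.5, 18.0)
        )
        assert res.bf_rd == pytest.approx(oracle, rel=1e-10)

    def test_beta_prior_bf_with_imperfect_classifier(self):
        """The misclassification correction inside the Beta integral
        matches direct quadrature of the corrected point likelihood."""
        a1, b1, a0, b0 = 3.0, 2.0, 0.5, 18.0
        w1, w2 = 0.376, 0.943

        def marginal(a, b):
            val, _ = sp_integrate.quad(
                lambda p: binom.pmf(2, 5, misclassified_param(p, w1, w2))
                * beta_dist.pdf(p, a, b),
                0.0,
                1.0,
                epsabs=1e-14,
            )
            return val

        priors = RDPriors(kind="beta", p1=None, p0=None, a1=a1, b1=b1, a0=a0, b0=b0)
        res = rd_bayes_factor(GeneCounts("g", 2, 3), perf(w1, w2), priors)
        assert res.bf_rd == pytest.approx(marginal(a1, b1) / marginal(a0, b0), rel=1e-8)


class TestPriorsFromMu:
    def test_worked_example(self):
        g = GeneEntry("g", mu=1e-5)
        priors = priors_from_mutation_rate(g, gamma=20.0, inherited_rate=3e-4)
        assert priors.p0 == pytest.approx(1 / 31)
        assert priors.p1 == pytest.approx(0.4)

    def test_gamma_limit_and_scale_invariance(self):
        g = GeneEntry("g", mu=1e-5)
        near = priors_from_mutation_rate(g, gamma=1 + 1e-9, inherited_rate=3e-4)
        assert near.p1 == pytest.approx(near.p0, rel=1e-6)
        doubled = priors_from_mutation_rate(
            GeneEntry("g", mu=2e-5), gamma=20.0, inherited_rate=6e-4
        )
        base = priors_from_mutation_rate(g, gamma=20.0, inherited_rate=3e-4)
        assert doubled.p0 == pytest.approx(base.p0)
        assert doubled.p1 == pytest.approx(base.p1)

    def test_invalid_inputs(self):
        g = GeneEntry("g", mu=1e-5)
        with pytest.raises(ValueError):
            priors_from_mutation_rate(g, gamma=1.0, inherited_rate=3e-4)
        with pytest.raises(ValueError):
            priors_from_mutation_rate(g, gamma=2.0, inherited_rate=0.0)


class TestPriorValidation:
    def test_point_ordering_enforced(self):
        with pytest.raises(ValueError):
            RDPriors(kind="point", p1=0.2, p0=0.3)

    def test_beta_hyperparameters_positive(self):
        with pytest.raises(ValueError):
            RDPriors(kind="beta", p1=None, p0=None, a1=1.0, b1=-1.0, a0=1.0, b0=1.0)

    def test_gamma_must_exceed_one(self):
        with pytest.raises(ValueError):
            RDPriors(kind="point", p1=0.6, p0=0.1, gamma=0.9)
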