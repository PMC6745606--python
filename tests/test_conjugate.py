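"""Conjugate posterior machinery under the default shrinkage prior."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from defaultprior import (
    Estimate,
    ShrinkagePrior,
    conditional_coverage,
    coverage_vs_pvalue,
    credible_interval,
    implied_se,
    p_to_absz,
    prior_tail_flag,
    shrink_posterior,
    sign_probability,
)


def grid_posterior_moments(b, se, g, n=80_001):
    """Brute-force posterior moments by normalizing prior x likelihood on a grid."""
    half = 10.0 * se * math.sqrt(g + 1.0)
    beta = np.linspace(-half + b * g / (g + 1), half + b * g / (g + 1), n)
    dens = norm.pdf(beta, 0.0, math.sqrt(g) * se) * norm.pdf(b, beta, se)
    mass = np.trapezoid(dens, beta)
    mean = np.trapezoid(beta * dens, beta) / mass
    var = np.trapezoid((beta - mean) ** 2 * dens, beta) / mass
    return mean, math.sqrt(var)


class TestShrinkPosterior:
    @pytest.mark.parametrize(
        "b, se, g, mean, sd",
        [
            (2.0, 1.0, 1.0, 1.0, 1.0 / math.sqrt(2.0)),
            (0.0, 3.0, 1.0, 0.0, 3.0 / math.sqrt(2.0)),
        ],
    )
    def test_halfway_shrinkage_at_default_g(self, b, se, g, mean, sd):
        post = shrink_posterior(Estimate(b, se), ShrinkagePrior(g))
        assert post.mean == pytest.approx(mean, abs=1e-12)
        assert post.sd == pytest.approx(sd, abs=1e-12)

    def test_flat_prior_limit(self):
        post = shrink_posterior(Estimate(2.0, 1.0), ShrinkagePrior(1e6))
        assert post.mean == pytest.approx(2.0, abs=1e-5)
        assert post.sd == pytest.approx(1.0, abs=1e-5)

    def test_agrees_with_grid_integration_oracle(self):
        rng = np.random.default_rng(20240917)
        for _ in range(100):
            b = rng.uniform(-5, 5)
            se = rng.uniform(0.2, 3.0)
            g = rng.uniform(0.1, 10.0)
            post = shrink_posterior(Estimate(b, se), ShrinkagePrior(g))
            mean, sd = grid_posterior_moments(b, se, g)
            assert post.mean == pytest.approx(mean, abs=1e-8)
            assert post.sd == pytest.approx(sd, abs=1e-8)

    @pytest.mark.parametrize("se, g", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_invalid_inputs_raise(self, se, g):
        with pytest.raises(ValueError):
            shrink_posterior(Estimate(1.0, se), ShrinkagePrior(g))


class TestSignProbability:
    def test_half_at_zero(self):
        assert sign_probability(Estimate(0.0, 1.0)) == pytest.approx(0.5, abs=1e-15)

    def test_matches_quadrature_of_posterior_density(self):
        # integrate the posterior density over (0, inf)
        from scipy.integrate import quad

        post = shrink_posterior(Estimate(1.96, 1.0))
        expected, _ = quad(lambda x: norm.pdf(x, post.mean, post.sd), 0, np.inf)
        assert sign_probability(Estimate(1.96, 1.0)) == pytest.approx(expected, abs=1e-10)
        assert sign_probability(Estimate(1.96, 1.0)) == pytest.approx(0.9171, abs=5e-5)

    def test_antisymmetry_and_complement(self):
        p_plus = sign_probability(Estimate(1.0, 1.0))
        p_minus = sign_probability(Estimate(-1.0, 1.0))
        assert p_plus + p_minus == pytest.approx(1.0, abs=1e-15)

    def test_strictly_increasing_in_b(self):
        bs = np.linspace(-4, 4, 41)
        vals = [sign_probability(Estimate(float(b), 1.0)) for b in bs]
        assert np.all(np.diff(vals) > 0)


class TestCredibleInterval:
    def test_default_g_endpoints(self):
        lo, hi = credible_interval(Estimate(2.0, 1.0), level=0.95)
        z = norm.ppf(0.975)
        assert lo == pytest.approx(1.0 - z / math.sqrt(2.0), abs=1e-12)
        assert hi == pytest.approx(1.0 + z / math.sqrt(2.0), abs=1e-12)

    def test_posterior_mass_equals_level(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            b, se, g = rng.uniform(-4, 4), rng.uniform(0.1, 3), rng.uniform(0.2, 5)
            level = rng.uniform(0.5, 0.99)
            est, prior = Estimate(b, se), ShrinkagePrior(g)
            lo, hi = credible_interval(est, prior, level)
            post = shrink_posterior(est, prior)
            mass = norm.cdf(hi, post.mean, post.sd) - norm.cdf(lo, post.mean, post.sd)
            assert mass == pytest.approx(level, abs=1e-12)

    def test_symmetric_about_zero_for_null_estimate(self):
        lo, hi = credible_interval(Estimate(0.0, 1.0))
        assert lo == pytest.approx(-hi, abs=1e-14)

    def test_scale_equivariance(self):
        c = 3.7
        lo, hi = credible_interval(Estimate(1.2, 0.8))
        lo_c, hi_c = credible_interval(Estimate(1.2 * c, 0.8 * c))
        assert lo_c == pytest.approx(c * lo, rel=1e-12)
        assert hi_c == pytest.approx(c * hi, rel=1e-12)

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_level_raises(self, level):
        with pytest.raises(ValueError):
            credible_interval(Estimate(1.0, 1.0), level=level)


class TestConditionalCoverage:
    def quadrature_coverage(self, b, se, g=1.0, level=0.95):
        from scipy.integrate import quad

        post = shrink_posterior(Estimate(b, se), ShrinkagePrior(g))
        z = norm.ppf(0.5 * (1 + level))
        val, _ = quad(lambda x: norm.pdf(x, post.mean, post.sd), b - z * se, b + z * se)
        return val

    @pytest.mark.parametrize("b, approx", [(0.0, 0.9944), (1.96, 0.917), (-1.96, 0.917)])
    def test_matches_quadrature_oracle(self, b, approx):
        got = conditional_coverage(Estimate(b, 1.0))
        assert got == pytest.approx(self.quadrature_coverage(b, 1.0), abs=1e-10)
        assert got == pytest.approx(approx, abs=5e-4)

    def test_decreasing_in_abs_b(self):
        bs = np.linspace(0, 6, 25)
        vals = [conditional_coverage(Estimate(float(b), 1.0)) for b in bs]
        assert np.all(np.diff(vals) < 0)

    def test_flat_prior_limit_recovers_nominal_level(self):
        for b in (0.0, 1.0, 3.0):
            got = conditional_coverage(Estimate(b, 1.0), ShrinkagePrior(1e8))
            assert got == pytest.approx(0.95, abs=1e-3)


class TestCoverageVsPvalue:
    def test_p_of_one_matches_null_estimate(self):
        assert coverage_vs_pvalue(1.0) == pytest.approx(
            conditional_coverage(Estimate(0.0, 1.0)), abs=1e-14
        )

    def test_monotone_increasing_in_p(self):
        ps = np.geomspace(0.001, 1.0, 30)
        vals = [coverage_vs_pvalue(float(p)) for p in ps]
        assert np.all(np.diff(vals) > 0)

    def test_value_at_p_05(self):
        assert coverage_vs_pvalue(0.05) == pytest.approx(0.917, abs=5e-4)


class TestPvalueConversions:
    def test_threshold_z_value(self):
        assert p_to_absz(0.001) == pytest.approx(3.2905, abs=5e-5)
        assert p_to_absz(1.0) == 0.0
        assert p_to_absz(0.05) == pytest.approx(1.9600, abs=5e-5)

    def test_round_trip_identity(self):
        zs = np.linspace(0.0, 10.0, 101)
        ps = 2.0 * norm.cdf(-zs)
        back = np.array([p_to_absz(float(p)) for p in ps])
        assert np.max(np.abs(back - zs)) < 1e-10

    @pytest.mark.parametrize("p", [0.0, -0.5, 1.0001])
    def test_invalid_p_raises(self, p):
        with pytest.raises(ValueError):
            p_to_absz(p)

    def test_implied_se(self):
        assert implied_se(2.0, 0.05) == pytest.approx(2.0 / p_to_absz(0.05), abs=1e-12)
        assert implied_se(2.0, 0.05) == pytest.approx(1.0204, abs=5e-4)
        assert implied_se(-2.0, 0.05) == implied_se(2.0, 0.05)
        assert implied_se(3.29, 0.001) == pytest.approx(1.0, abs=1e-3)

    def test_implied_se_undefined_cases(self):
        with pytest.raises(ValueError):
            implied_se(0.0, 0.05)
        with pytest.raises(ValueError):
            implied_se(2.0, 1.0)


class TestPriorDataConflict:
    def test_flagging_rule(self):
        assert prior_tail_flag(0.0005).flagged
        assert not prior_tail_flag(0.5).flagged
        assert not prior_tail_flag(0.001).flagged  # boundary is kept

    def test_tail_probability_about_two_percent(self):
        tail = prior_tail_flag(0.5).tail_probability
        expected = 2.0 * norm.cdf(-p_to_absz(0.001) / math.sqrt(2.0))
        assert tail == pytest.approx(expected, abs=1e-12)
        assert tail == pytest.approx(0.0200, abs=5e-4)
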