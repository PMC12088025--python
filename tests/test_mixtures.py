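"""Truncated-normal-mixture construction, moments and calibration."""

import numpy as np
import pytest
from scipy.stats import truncnorm

import sbarisk as sk
from sbarisk.mixtures import _trunc_mean_var


def mix(weights, means, sds, support):
    return sk.TruncatedNormalMixture(tuple(weights), tuple(means), tuple(sds), tuple(support))


class TestConstruction:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(weights=(0.6, 0.6), means=(0, 1), sds=(1, 1), support=(-5, 5)),
            dict(weights=(-0.1, 1.1), means=(0, 1), sds=(1, 1), support=(-5, 5)),
            dict(weights=(0.5, 0.5), means=(0, 1), sds=(1, 0.0), support=(-5, 5)),
            dict(weights=(1.0,), means=(0,), sds=(1,), support=(5, -5)),
            dict(weights=(0.5, 0.5), means=(0,), sds=(1, 1), support=(-5, 5)),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sk.TruncatedNormalMixture(**kwargs)

    def test_cdf_hits_bounds_and_is_monotone(self):
        m = mix([0.3, 0.7], [-2, 3], [1, 4], (-10, 10))
        grid = np.linspace(-10, 10, 10_001)
        c = m.cdf(grid)
        assert c[0] == 0.0 and c[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(c) >= 0)

    def test_mass_conserved_by_quadrature(self):
        from scipy.integrate import quad

        m = mix([0.5, 0.5], [-1, 4], [2, 6], (-8, 12))
        total, _ = quad(m.pdf, -8, 12, limit=200)
        assert total == pytest.approx(1.0, abs=1e-9)


class TestMoments:
    def test_half_normal_closed_form(self):
        # N(0,1) truncated to [0, 30]: mean sqrt(2/pi)
        m = mix([1.0], [0.0], [1.0], (0.0, 30.0))
        mean, sd = m.mean_sd()
        assert mean == pytest.approx(np.sqrt(2 / np.pi), abs=1e-9)

    def test_mild_truncation_leaves_moments(self):
        m = mix([1.0], [0.0], [1.0], (-30.0, 30.0))
        mean, sd = m.mean_sd()
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert sd == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_mixture_mean_zero(self):
        m = mix([0.5, 0.5], [-2.0, 2.0], [1.0, 1.0], (-30.0, 30.0))
        mean, _ = m.mean_sd()
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_matches_scipy_truncnorm(self):
        # independent oracle for the hand-coded truncated moments
        mu, s, lo, hi = 1.3, 2.7, -2.0, 6.0
        a, b = (lo - mu) / s, (hi - mu) / s
        m_ref, v_ref = truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        m_ours, v_ours = _trunc_mean_var(mu, s, lo, hi)
        assert m_ours == pytest.approx(float(m_ref), rel=1e-10)
        assert v_ours == pytest.approx(float(v_ref), rel=1e-10)

    def test_quadrature_moments_match_monte_carlo(self, rng):
        m = mix([0.7, 0.3], [2.0, 8.0], [1.5, 3.0], (0.0, 15.0))
        mean_q, sd_q, _, _ = sk.mixture_moments(m)
        draws = m.rvs(1_000_000, rng)
        se_mean = draws.std(ddof=1) / 1000
        assert mean_q == pytest.approx(draws.mean(), abs=3 * se_mean)
        # SE of the SD of ~normal-ish data: sd / sqrt(2n)
        assert sd_q == pytest.approx(draws.std(ddof=1), abs=3 * sd_q / np.sqrt(2e6))

    def test_cdf_matches_quadrature_of_density(self):
        from scipy.integrate import quad

        m = mix([1.0], [1.0], [2.0], (-4.0, 7.0))
        for x in (-2.0, 0.5, 3.0, 6.0):
            num, _ = quad(m.pdf, -4.0, x, limit=200)
            assert m.cdf(x) == pytest.approx(num, abs=1e-9)


class TestQuantile:
    def test_symmetric_median_is_zero(self):
        m = mix([0.5, 0.5], [-3.0, 3.0], [1.0, 1.0], (-20.0, 20.0))
        assert m.quantile(0.5) == pytest.approx(0.0, abs=1e-6)

    def test_flat_mixture_quartile(self):
        # wide components on [0, 10] approach a uniform: q(0.25) near 2.5
        m = mix([0.5, 0.5], [3.0, 7.0], [40.0, 40.0], (0.0, 10.0))
        assert m.quantile(0.25) == pytest.approx(2.5, abs=0.05)

    @pytest.mark.parametrize("p", [0.01, 0.05, 0.5, 0.95, 0.99])
    def test_cdf_quantile_round_trip(self, p):
        m = mix([0.6, 0.4], [-1.0, 5.0], [2.0, 4.0], (-10.0, 20.0))
        assert m.cdf(m.quantile(p)) == pytest.approx(p, abs=1e-6)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.4])
    def test_invalid_level_rejected(self, p):
        m = mix([1.0], [0.0], [1.0], (-5.0, 5.0))
        with pytest.raises(ValueError):
            m.quantile(p)


class TestCalibration:
    def test_standard_normal_single_component(self):
        spec = sk.CalibrationSpec(target_mean=0.0, target_sd=1.0, support=(-30.0, 30.0))
        m = sk.calibrate_mixture(spec)
        mean, sd = m.mean_sd()
        assert mean == pytest.approx(0.0, abs=1e-6)
        assert sd == pytest.approx(1.0, abs=1e-6)
        assert m.means[0] == pytest.approx(0.0, abs=1e-6)

    def test_onset_mass_constraint_fixed_point(self):
        spec = sk.CalibrationSpec(
            target_mean=-1.48,
            target_sd=9.21,
            support=(-30.0, 30.0),
            n_components=2,
            target_interval_mass=(-7.0, 7.0, 0.66),
        )
        m = sk.calibrate_mixture(spec)
        mean, sd, masses, _ = sk.mixture_moments(m, intervals=[(-7.0, 7.0)])
        assert mean == pytest.approx(-1.48, abs=1e-3 * 9.21)
        assert sd == pytest.approx(9.21, rel=1e-3)
        assert masses[0] == pytest.approx(0.66, rel=1e-3)

    def test_latent_quantile_constraint_fixed_point(self):
        spec = sk.CalibrationSpec(
            target_mean=5.3,
            target_sd=4.1,
            support=(0.0, 30.0),
            n_components=2,
            target_quantile=(0.95, 14.0),
        )
        m = sk.calibrate_mixture(spec)
        assert m.quantile(0.95) == pytest.approx(14.0, rel=1e-3)
        mean, sd = m.mean_sd()
        assert mean == pytest.approx(5.3, rel=1e-3)
        assert sd == pytest.approx(4.1, rel=1e-3)

    def test_infeasible_constraints_raise(self):
        # nearly all mass inside [-1, 1] is impossible with SD 10
        spec = sk.CalibrationSpec(
            target_mean=0.0,
            target_sd=10.0,
            support=(-30.0, 30.0),
            n_components=2,
            target_interval_mass=(-1.0, 1.0, 0.999),
        )
        with pytest.raises(sk.CalibrationError):
            sk.calibrate_mixture(spec)

    def test_deterministic_given_spec(self):
        spec = sk.CalibrationSpec(
            target_mean=7.1,
            target_sd=4.0,
            support=(0.0, 30.0),
            n_components=2,
            target_quantile=(0.95, 20.0),
        )
        a, b = sk.calibrate_mixture(spec), sk.calibrate_mixture(spec)
        assert a == b

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(target_mean=0.0, target_sd=-1.0, support=(-5.0, 5.0)),
            dict(target_mean=9.0, target_sd=1.0, support=(-5.0, 5.0)),
            dict(target_mean=0.0, target_sd=1.0, support=(-5.0, 5.0), n_components=3),
            dict(
                target_mean=0.0,
                target_sd=1.0,
                support=(-5.0, 5.0),
                n_components=1,
                target_quantile=(0.95, 2.0),
            ),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sk.CalibrationSpec(**kwargs)
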