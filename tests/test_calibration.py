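"""Calibration densities: closed forms, mixtures, interpolation contracts."""

import numpy as np
import pytest
from scipy.stats import ks_1samp

import cladecal as cc
from cladecal._errors import InvalidGridError, InvalidWeightsError
from cladecal.calibration import GridSpec

from oracles import naive_conditioned_mean_integrand


@pytest.fixture(scope="module")
def exp_limit_density():
    """d -> 0 collapses the model to a shifted exponential with rate psi."""
    bd = cc.BDParams(1e-9, 0.0, 0.05)
    fossil = cc.FossilRecord("point", 100.0, 100.0)
    return cc.single_calibration_density(bd, fossil, n_reps=50_000, seed=42)


class TestSingleDensity:
    def test_exponential_limit_closed_form(self, exp_limit_density):
        d = exp_limit_density
        psi = 0.05
        expect = psi * np.exp(-psi * (d.age_grid - 100.0))
        expect /= np.trapezoid(expect, d.age_grid)
        assert np.abs(d.density_values - expect).max() < 0.003

    def test_zero_below_fossil_age(self, exp_limit_density):
        assert exp_limit_density.evaluate(99.0) == 0.0
        assert exp_limit_density.evaluate(50.0) == 0.0
        assert exp_limit_density.logpdf(99.0) == -np.inf

    def test_normalization_and_mode_with_ranges(self, teleost_bd):
        fossil = cc.FossilRecord("Plectocretacicus", 98.0, 100.3)
        d = cc.single_calibration_density(teleost_bd, fossil,
                                          n_reps=30_000, seed=1)
        assert np.trapezoid(d.density_values, d.age_grid) == pytest.approx(
            1.0, abs=0.01
        )
        assert all(m >= 98.0 for m in d.modes())

    def test_grid_below_fossil_rejected(self):
        with pytest.raises(InvalidGridError):
            cc.single_calibration_density(
                cc.BDParams(0.05, 0.0, 0.05),
                cc.FossilRecord("f", 100.0, 100.0),
                GridSpec(n_points=1),
            )

    def test_seed_reproducibility(self, teleost_bd):
        fossil = cc.FossilRecord("f", 90.0, 95.0)
        a = cc.single_calibration_density(teleost_bd, fossil, n_reps=5000,
                                          seed=9)
        b = cc.single_calibration_density(teleost_bd, fossil, n_reps=5000,
                                          seed=9)
        np.testing.assert_array_equal(a.density_values, b.density_values)

    def test_monotonic_response_to_sampling_rate(self):
        """Higher fossil-recovery rates pull the clade age toward the fossil."""
        means = []
        for psi in (0.01, 0.03, 0.09):
            bd = cc.BDParams(0.05, 0.1, psi)
            d = cc.single_calibration_density(
                bd, cc.FossilRecord("f", 100.0, 100.0), n_reps=30_000, seed=3
            )
            means.append(d.mean())
        assert means[0] > means[1] > means[2]

    def test_against_independent_brute_force_estimator(self, rng):
        """Unnormalized density values agree with a per-lineage simulation
        oracle within 3 combined Monte-Carlo standard errors."""
        lam, mu, psi = 0.1, 0.02, 0.05
        d_rate = lam - mu
        eps = mu / lam
        bd = cc.BDParams(d_rate, eps, psi)
        fossil = cc.FossilRecord("f", 10.0, 10.0)
        n_reps = 30_000
        dens = cc.single_calibration_density(bd, fossil, n_reps=n_reps,
                                             seed=21)
        # recover the unnormalized scale by comparing shapes at grid ages
        from cladecal.bd_process import _grid_accumulate
        probe = np.array([12.0, 17.0, 25.0, 33.0])
        num, den = _grid_accumulate(
            probe, d_rate, d_rate, eps, eps, psi, psi, 10.0, 10.0, n_reps, 21
        )
        impl = num / den
        for t, val in zip(probe, impl):
            est, se_o = naive_conditioned_mean_integrand(
                rng, lam, mu, psi, t - 10.0, 4000
            )
            se_impl = se_o * np.sqrt(4000 / n_reps)
            tol = 3 * np.sqrt(se_o**2 + se_impl**2)
            assert abs(val - est) < tol, (t, val, est, tol)


@pytest.fixture(scope="module")
def tetraodontiform():
    bd = cc.BDParams((0.041, 0.081), (0.0011, 0.37), (0.0066, 0.01806))
    younger = cc.FossilRecord("Cretatriacanthus", 83.0, 89.8, 2 / 3)
    older = cc.FossilRecord("Plectocretacicus", 98.0, 100.3, 1 / 3)
    return cc.mixture_calibration_density(younger, older, bd,
                                          n_reps=30_000, seed=5)


class TestMixtureDensity:
    def test_tetraodontiform_example_normalizes(self, tetraodontiform):
        m = tetraodontiform
        assert np.trapezoid(m.density_values, m.age_grid) == pytest.approx(
            1.0, abs=0.01
        )
        assert m.support[0] == 83.0
        assert m.evaluate(80.0) == 0.0

    def test_piecewise_identity(self, tetraodontiform):
        m = tetraodontiform
        younger, f_y = m.components["younger"]
        older, f_o = m.components["older"]
        p_y, p_o = m.components["p_younger"], m.components["p_older"]
        assert p_y == pytest.approx(2 / 3)
        grid = m.age_grid
        below = grid < older.age_min
        np.testing.assert_allclose(
            m.density_values[below], p_y * f_y[below], rtol=1e-9
        )
        np.testing.assert_allclose(
            m.density_values, p_y * f_y + p_o * f_o, rtol=1e-9
        )

    def test_degenerate_mixture_reduces_to_single(self):
        bd = cc.BDParams(0.06, 0.1, 0.02)
        younger = cc.FossilRecord("y", 50.0, 52.0, 1.0)
        older = cc.FossilRecord("o", 80.0, 82.0, 0.0)
        m = cc.mixture_calibration_density(younger, older, bd,
                                           n_reps=20_000, seed=6)
        # exact: the mixture IS its younger component when p_older = 0
        _, f_y = m.components["younger"]
        np.testing.assert_allclose(m.density_values, f_y, rtol=1e-12)
        # statistical: agrees with an independently simulated single-fossil
        # density in the bulk of the distribution
        s = cc.single_calibration_density(bd, younger, n_reps=20_000, seed=99)
        probe = m.age_grid
        vals = s.evaluate(probe)
        got = m.evaluate(probe)
        bulk = vals > 0.1 * vals.max()
        np.testing.assert_allclose(got[bulk], vals[bulk], rtol=0.1)

    def test_bimodality_grows_with_separation(self):
        bd = cc.BDParams(0.061, 0.1856, 0.01233)
        y = cc.FossilRecord("y", 50.0, 50.0, 0.5)
        near = cc.FossilRecord("o", 80.0, 80.0, 0.5)
        far = cc.FossilRecord("o", 170.0, 170.0, 0.5)
        m_far = cc.mixture_calibration_density(y, far, bd, n_reps=30_000,
                                               seed=7)
        assert len(m_far.modes(rel_prominence=0.05)) == 2
        m_near = cc.mixture_calibration_density(y, near, bd, n_reps=30_000,
                                                seed=7)
        assert len(m_near.modes(rel_prominence=0.05)) <= 2

    def test_weights_must_sum_to_one(self):
        bd = cc.BDParams(0.06, 0.1, 0.02)
        with pytest.raises(InvalidWeightsError):
            cc.mixture_calibration_density(
                cc.FossilRecord("y", 50, 51, 0.5),
                cc.FossilRecord("o", 80, 81, 0.6),
                bd,
            )

    def test_overlapping_intervals_warn(self):
        bd = cc.BDParams(0.06, 0.1, 0.02)
        with pytest.warns(UserWarning, match="overlap"):
            cc.CladeConstraint(
                "c", frozenset({"A", "B"}),
                (cc.FossilRecord("y", 50, 60, 0.5),
                 cc.FossilRecord("o", 55, 65, 0.5)),
            )


class TestDensityContracts:
    def test_cdf_quantile_inverse_identity(self, exp_limit_density):
        for q in (0.025, 0.5, 0.975):
            assert exp_limit_density.cdf(
                exp_limit_density.quantile(q)
            ) == pytest.approx(q, abs=1e-3)

    def test_exponential_quantiles_closed_form(self, exp_limit_density):
        psi = 0.05
        for q in (0.1, 0.5, 0.9):
            expect = 100.0 - np.log(1 - q) / psi
            assert exp_limit_density.quantile(q) == pytest.approx(
                expect, abs=0.5
            )

    def test_negative_age_rejected(self, exp_limit_density):
        with pytest.raises(ValueError):
            exp_limit_density.evaluate(-1.0)

    def test_sampling_matches_cdf(self, exp_limit_density):
        x = exp_limit_density.sample(100_000, seed=8)
        assert ks_1samp(x, exp_limit_density.cdf).statistic < 0.01

    def test_sampling_reproducible(self, exp_limit_density):
        assert exp_limit_density.sample(1, seed=3) == pytest.approx(
            exp_limit_density.sample(1, seed=3)
        )

    def test_exponential_sample_mean(self, exp_limit_density):
        x = exp_limit_density.sample(100_000, seed=9)
        se = x.std(ddof=1) / np.sqrt(len(x))
        # finite-grid truncation biases the mean slightly below t_f + 1/psi
        assert abs(x.mean() - (100.0 + 1 / 0.05)) < 3 * se + 0.1

    def test_mixture_component_mass(self):
        bd = cc.BDParams(1e-9, 0.0, 0.05)
        y = cc.FossilRecord("y", 50.0, 50.0, 0.5)
        o = cc.FossilRecord("o", 170.0, 170.0, 0.5)
        m = cc.mixture_calibration_density(y, o, bd, n_reps=20_000, seed=10)
        x = m.sample(100_000, seed=11)
        frac_below = (x < 170.0).mean()
        mass_below = m.cdf(170.0)
        se = np.sqrt(mass_below * (1 - mass_below) / len(x))
        assert abs(frac_below - mass_below) < 3 * se + 1e-3
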