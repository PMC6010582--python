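"""Generative model: defaults, event-time inversion, calibration, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad as scipy_quad
from scipy.optimize import brentq

from jointsnp.simulate import (DEFAULT_D_GRID, GenerativeParams, ScenarioSpec,
                               calibrate_lambda, cumulative_hazard,
                               event_probability, event_time_inverse,
                               params_for_scenario, scenario_grid,
                               simulate_cohort, simulate_genotypes,
                               simulate_random_effects, table1_defaults,
                               table1_scenario)


class TestDefaults:
    def test_reference_values(self, base_params):
        p = base_params
        assert p.gamma == 0.0229
        assert p.beta == 3.17
        assert p.alpha == 0.265
        assert p.sigma_e == 0.305
        assert p.f == 0.244
        np.testing.assert_allclose(p.mu, [4.55, 0.0108])
        np.testing.assert_allclose(
            p.Sigma, [[0.143, -0.00109], [-0.00109, 6.8e-4]])
        assert p.horizon == 9.0 and p.m == 4

    def test_sigma_symmetric_psd(self, base_params):
        S = base_params.Sigma
        np.testing.assert_array_equal(S, S.T)
        assert np.linalg.eigvalsh(S).min() > 0

    def test_reference_scenario(self):
        s = table1_scenario()
        assert (s.n, s.m, s.f, s.d) == (4352, 4, 0.244, 0.0384)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GenerativeParams(mu=[0, 0], Sigma=[[1, 2], [2, 1]], sigma_e=0.3,
                             gamma=0, alpha=0, beta=0, f=0.5)


class TestGenotypes:
    def test_f_zero_all_reference(self):
        assert (simulate_genotypes(500, 0.0, 1) == 0).all()

    def test_symmetric_frequency(self):
        z = simulate_genotypes(100_000, 0.5, 2)
        se = np.sqrt(0.5 * 0.5 / (2 * z.size))
        assert abs(z.mean() / 2 - 0.5) < 3 * se

    def test_reference_frequency(self):
        f = 0.244
        z = simulate_genotypes(100_000, f, 3)
        se = np.sqrt(f * (1 - f) / (2 * z.size))
        assert abs(z.mean() / 2 - f) < 3 * se


class TestRandomEffects:
    def test_zero_covariance_degenerate(self):
        th = simulate_random_effects(10, [4.55, 0.01], np.zeros((2, 2)), 0)
        np.testing.assert_allclose(th, np.tile([4.55, 0.01], (10, 1)))

    def test_sample_covariance(self, base_params):
        th = simulate_random_effects(100_000, base_params.mu,
                                     base_params.Sigma, 4)
        np.testing.assert_allclose(np.cov(th.T), base_params.Sigma,
                                   rtol=0.05, atol=2e-5)

    def test_negative_intercept_slope_correlation(self, base_params):
        th = simulate_random_effects(100_000, base_params.mu,
                                     base_params.Sigma, 5)
        assert np.corrcoef(th.T)[0, 1] < 0  # sign of -0.00109


class TestEventTimeInverse:
    def test_u_to_zero_gives_time_zero(self, params_d0384):
        t = event_time_inverse(4.55, 0.01, 1.0, params_d0384, 1e-12)
        assert 0 < t < 1e-2

    def test_plain_exponential_limit(self):
        p = GenerativeParams(mu=[0, 0], Sigma=np.zeros((2, 2)), sigma_e=0.3,
                             gamma=0.0, alpha=0.0, beta=0.0, f=0.5,
                             lambda0=0.2)
        u = 0.37
        assert event_time_inverse(1.0, 1.0, 0.0, p, u) == pytest.approx(
            -np.log(1 - u) / 0.2, rel=1e-12)

    def test_matches_root_finding_oracle(self, params_d0384):
        """The closed form solves H(T) = -log(1-u): cross-check the returned
        time against 1-D root finding on the cumulative hazard."""
        p = params_d0384
        t = float(event_time_inverse(4.55, 0.0108, 1.0, p, 0.5))
        assert cumulative_hazard(t, 4.55, 0.0108, 1.0, p) == pytest.approx(
            np.log(2), abs=1e-10)
        t_oracle = brentq(
            lambda s: cumulative_hazard(s, 4.55, 0.0108, 1.0, p) - np.log(2),
            1e-9, 1e6, xtol=1e-12)
        assert t == pytest.approx(t_oracle, rel=1e-8)

    def test_bounded_hazard_returns_infinity(self):
        # strongly negative slope with beta > 0: cumulative hazard plateaus
        p = GenerativeParams(mu=[0, 0], Sigma=np.zeros((2, 2)), sigma_e=0.3,
                             gamma=0.0, alpha=0.0, beta=2.0, f=0.5,
                             lambda0=0.01)
        t = event_time_inverse(0.0, -1.0, 0.0, p, 0.99)
        assert np.isinf(t)

    def test_u_out_of_range(self, params_d0384):
        with pytest.raises(ValueError):
            event_time_inverse(4.5, 0.01, 0.0, params_d0384, 1.0)


class TestCalibration:
    def test_closed_form_when_no_effects(self):
        p = GenerativeParams(mu=[4.55, 0.0108],
                             Sigma=[[0.143, -0.00109], [-0.00109, 6.8e-4]],
                             sigma_e=0.305, gamma=0.0, alpha=0.0, beta=0.0,
                             f=0.244)
        lam = calibrate_lambda(p, 0.025)
        assert lam == pytest.approx(-np.log(1 - 0.025) / 9.0, rel=1e-8)

    def test_monotone_in_target(self, base_params):
        assert calibrate_lambda(base_params, 0.10) > calibrate_lambda(
            base_params, 0.025)

    def test_calibrated_probability_hits_target(self, params_d0384):
        assert event_probability(params_d0384) == pytest.approx(0.0384,
                                                                abs=1e-6)


class TestSimulatedCohort:
    def test_even_schedule(self, base_params):
        np.testing.assert_allclose(base_params.schedule, [0.0, 3.0, 6.0, 9.0])

    def test_truncation_rule(self, params_d10):
        spec = ScenarioSpec(m=4, n=600, f=0.244, d=0.1, base_seed=11)
        sim = simulate_cohort(spec, params_d10, replicate=0)
        merged = sim.cohort.longitudinal.merge(
            sim.cohort.survival.rename(columns={"time": "t_obs"})[["id", "t_obs"]])
        assert (merged["time"] <= merged["t_obs"]).all()
        # an individual failing in (3, 6) keeps exactly the 0 and 3 visits
        mid = sim.cohort.survival.query("3 < time < 6 and status == 1")["id"]
        assert len(mid) > 0
        counts = sim.cohort.longitudinal[
            sim.cohort.longitudinal["id"].isin(mid)].groupby("id").size()
        assert (counts == 2).all()

    def test_baseline_visit_always_kept(self, params_d10):
        spec = ScenarioSpec(m=4, n=600, f=0.244, d=0.1, base_seed=12)
        sim = simulate_cohort(spec, params_d10, replicate=0)
        per_id = sim.cohort.longitudinal.groupby("id")["time"].min()
        assert (per_id == 0.0).all()
        assert len(per_id) == 600

    def test_noise_free_limit(self):
        p = GenerativeParams(mu=[4.55, 0.0108], Sigma=np.zeros((2, 2)),
                             sigma_e=1e-12, gamma=0.0, alpha=0.0, beta=0.0,
                             f=0.0, lambda0=0.01)
        spec = ScenarioSpec(m=4, n=50, f=0.0, d=0.05, base_seed=13)
        sim = simulate_cohort(spec, p, replicate=0)
        lon = sim.cohort.longitudinal
        np.testing.assert_allclose(lon["value"],
                                   4.55 + 0.0108 * lon["time"], atol=1e-9)

    def test_bit_identical_replication(self, params_d10):
        spec = ScenarioSpec(m=4, n=200, f=0.244, d=0.1, base_seed=14)
        a = simulate_cohort(spec, params_d10, replicate=3)
        b = simulate_cohort(spec, params_d10, replicate=3)
        pd.testing.assert_frame_equal(a.cohort.longitudinal,
                                      b.cohort.longitudinal)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_spec_params_mismatch(self, params_d10):
        spec = ScenarioSpec(m=5, n=50, f=0.244, d=0.1, base_seed=1)
        with pytest.raises(ValueError, match="m="):
            simulate_cohort(spec, params_d10)

    def test_per_draw_cumulative_hazard_identity(self, params_d10):
        """For each finite event time, numerically integrating the hazard
        from 0 to T reproduces -log(1-u) to 1e-8."""
        spec = ScenarioSpec(m=4, n=150, f=0.244, d=0.1, base_seed=15)
        sim = simulate_cohort(spec, params_d10, replicate=0)
        tr = sim.truth[np.isfinite(sim.truth["true_time"])].head(40)
        p = sim.params
        for _, row in tr.iterrows():
            H, _ = scipy_quad(
                lambda s: p.lambda0 * np.exp(
                    p.beta * (row.theta0 + row.theta1 * s + p.gamma * row.z)
                    + p.alpha * row.z),
                0.0, row.true_time, epsabs=1e-12, epsrel=1e-12)
            assert H == pytest.approx(-np.log1p(-row.u), abs=1e-8)

    def test_event_fraction_monotone_in_lambda(self, base_params):
        spec = ScenarioSpec(m=4, n=2000, f=0.244, d=0.5, base_seed=16)
        fractions = []
        for lam in (1e-10, 1e-9, 1e-8):
            sim = simulate_cohort(spec, base_params.with_lambda(lam),
                                  replicate=0)
            fractions.append(sim.cohort.survival["status"].mean())
        assert fractions == sorted(fractions)


class TestScenarioGrid:
    def test_default_grid_has_240_cells(self):
        assert len(scenario_grid()) == 240

    def test_restricted_m_grid(self):
        assert len(scenario_grid(m_grid=(2,))) == 60

    def test_singleton_grid(self):
        specs = scenario_grid((4,), (500,), (0.25,), (0.05,))
        assert len(specs) == 1 and specs[0].index == 0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            scenario_grid(m_grid=())

    def test_deterministic_ordering_and_seeds(self):
        a = scenario_grid(base_seed=9)
        b = scenario_grid(base_seed=9)
        assert a == b
        assert [s.index for s in a] == list(range(240))
        assert a[0].d == DEFAULT_D_GRID[0]  # d varies fastest

    def test_params_for_scenario_recalibrates(self, base_params):
        spec = ScenarioSpec(m=3, n=100, f=0.1, d=0.05, base_seed=0)
        p = params_for_scenario(base_params, spec)
        assert p.m == 3 and p.f == 0.1
        assert event_probability(p) == pytest.approx(0.05, abs=1e-6)
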