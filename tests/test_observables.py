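"""Analysis-layer estimators against closed-form and synthetic oracles."""

import numpy as np
import pytest

from polcpm.energetics import ModelParams, equilibrium_area
from polcpm.engine import Simulation, place_single_cell
from polcpm.hexgrid import build_lattice
from polcpm.observables import (cell_pressure, cluster_angular_velocity,
                                correlation_time, density_profile, dominant_period,
                                first_crossing_times, fit_prw, front_profile,
                                front_roughness, furth_msd, msd, msd_loglog_slope,
                                orientations, rotation_stats, roughness_of_profile,
                                shape_metrics, stress_profile, trajectory_curvature,
                                vacf, velocities)
from polcpm.synthetic import (generate_ballistic, generate_circle, generate_prw,
                              generate_random_walk)

from conftest import random_blob


class TestMsd:
    def test_static_point_has_zero_msd(self):
        pos = np.zeros((50, 2))
        assert np.all(msd(pos, [1, 5, 10]) == 0.0)

    def test_uniform_motion_msd_is_v_tau_squared(self):
        pos = generate_ballistic(0.3, 0.7, 200)
        lags = np.array([1, 5, 20, 50])
        assert msd(pos, lags) == pytest.approx((0.3 * lags) ** 2)

    def test_prw_matches_furth_formula(self):
        # dense ensemble vs the closed form at the generator's parameters
        pos = generate_prw(v=0.4, tau_p=40.0, n_steps=4000, n_walkers=60, seed=1)
        lags = np.unique(np.geomspace(1, 1000, 25).astype(int))
        expected = furth_msd(lags, 0.4, 40.0)
        assert msd(pos, lags) == pytest.approx(expected, rel=0.12)

    def test_invalid_lags_rejected(self):
        pos = np.zeros((10, 2))
        with pytest.raises(ValueError):
            msd(pos, [])
        with pytest.raises(ValueError):
            msd(pos, [20])


class TestVacf:
    def test_ballistic_motion_fully_correlated(self):
        pos = generate_ballistic(0.5, 1.2, 100)
        v = velocities(pos, window=1)
        assert vacf(v, [0, 3, 10, 50]) == pytest.approx(np.ones(4))

    def test_zero_lag_is_exactly_one(self):
        pos = generate_prw(0.2, 30.0, 500, 4, seed=2)
        v = velocities(pos, window=1)
        assert vacf(v, [0])[0] == pytest.approx(1.0)

    def test_prw_orientation_decays_with_tau_p(self):
        tau = 60.0
        pos = generate_prw(0.3, tau, 6000, 40, seed=3)
        v = velocities(pos, window=1)
        lags = np.arange(0, 300, 5)
        C = vacf(v, lags)
        assert C == pytest.approx(np.exp(-lags / tau), abs=0.05)
        assert correlation_time(lags, C, tail_tau=tau) == pytest.approx(tau, rel=0.15)

    def test_all_zero_velocities_rejected(self):
        with pytest.raises(ValueError):
            vacf(np.zeros((1, 50, 2)), [1, 2])


class TestPrwFit:
    def test_noiseless_furth_data_recovered_exactly(self):
        lags = np.unique(np.geomspace(1, 2000, 30).astype(int))
        fit = fit_prw(lags, furth_msd(lags, 0.1, 50.0))
        assert fit.converged
        assert fit.v == pytest.approx(0.1, abs=1e-6)
        assert fit.tau_p == pytest.approx(50.0, rel=1e-5)

    def test_synthetic_ensemble_recovered_within_ten_percent(self):
        pos = generate_prw(v=0.1, tau_p=50.0, n_steps=5000, n_walkers=100, seed=4)
        lags = np.unique(np.geomspace(1, 1600, 30).astype(int))
        fit = fit_prw(lags, msd(pos, lags))
        assert fit.converged
        assert fit.v == pytest.approx(0.1, rel=0.10)
        assert fit.tau_p == pytest.approx(50.0, rel=0.10)

    def test_pure_diffusion_drives_tau_p_to_zero(self):
        pos = generate_random_walk(0.5, 4000, 50, seed=5)
        lags = np.unique(np.geomspace(1, 1200, 25).astype(int))
        fit = fit_prw(lags, msd(pos, lags))
        assert fit.converged
        assert fit.tau_p < 2.0  # no resolvable ballistic regime

    def test_too_few_points_flagged_not_silent(self):
        fit = fit_prw(np.array([1, 2, 3]), np.array([1.0, 2.0, 3.0]))
        assert not fit.converged
        assert fit.message

    def test_loglog_slopes_of_limit_cases(self):
        lags = np.unique(np.geomspace(1, 500, 20).astype(int))
        ball = msd(generate_ballistic(0.4, 0.3, 600), lags)
        assert msd_loglog_slope(lags, ball) == pytest.approx(2.0, abs=0.01)
        diff = msd(generate_random_walk(0.5, 6000, 40, seed=6), lags)
        assert msd_loglog_slope(lags, diff) == pytest.approx(1.0, abs=0.1)


class TestShape:
    def test_hexagonally_symmetric_cluster_is_round(self):
        lat = build_lattice(20, 20)
        p = ModelParams(kappa_A=0.3, kappa_P=0.1, eps0=10.0, delta_eps=4.0,
                        R=1, mu=0.1)
        sim = Simulation(lat, p, max_cells=2)
        center = lat.site_index(10, 10)
        cid = sim.add_cell(sites=list(lat.disk_neighborhood(center, 2)))
        ratio, (lp, lm), _ = shape_metrics(sim.config, cid)
        assert ratio == pytest.approx(1.0, abs=1e-9)

    def test_straight_line_reports_degenerate_sentinel(self):
        lat = build_lattice(20, 20)
        p = ModelParams(kappa_A=0.3, kappa_P=0.1, eps0=10.0, delta_eps=4.0,
                        R=1, mu=0.1)
        sim = Simulation(lat, p, max_cells=2)
        a = lat.site_index(5, 10)
        sites = [a]
        for _ in range(4):
            sites.append(int(lat.neigh[sites[-1], 0]))
        cid = sim.add_cell(sites)
        ratio, _, _ = shape_metrics(sim.config, cid)
        assert np.isinf(ratio)

    def test_eigendecomposition_matches_covariance_oracle(self, rng):
        lat = build_lattice(30, 30)
        p = ModelParams(kappa_A=0.3, kappa_P=0.1, eps0=10.0, delta_eps=4.0,
                        R=1, mu=0.1)
        for trial in range(10):
            sim = Simulation(lat, p, max_cells=2)
            cid = sim.add_cell(random_blob(lat, rng, 40))
            ratio, (lp, lm), axes = shape_metrics(sim.config, cid)
            sites = sim.config.sites_of(cid)
            pts = np.stack([sim.config.ux[sites], sim.config.uy[sites]], axis=1)
            evals = np.linalg.eigvalsh(np.cov(pts.T, bias=True))
            assert lp == pytest.approx(np.sqrt(evals[1]), rel=1e-9)
            assert lm == pytest.approx(np.sqrt(evals[0]), rel=1e-9)
            assert ratio >= 1.0


class TestCurvature:
    def test_dense_circle_curvature_is_inverse_radius(self):
        pos = generate_circle(radius=40.0, omega=0.01, n_steps=5000)
        assert trajectory_curvature(pos, window=10) == pytest.approx(1 / 40.0,
                                                                     rel=0.02)

    def test_straight_line_has_zero_curvature(self):
        pos = generate_ballistic(0.5, 0.9, 500)
        assert trajectory_curvature(pos, window=10) == pytest.approx(0.0, abs=1e-12)

    def test_noisy_circle_converges_with_smoothing(self):
        pos = generate_circle(radius=40.0, omega=0.01, n_steps=8000,
                              noise=0.5, seed=7)
        rough = trajectory_curvature(pos, window=5)
        smooth = trajectory_curvature(pos, window=40)
        assert abs(smooth - 1 / 40.0) < abs(rough - 1 / 40.0)
        assert smooth == pytest.approx(1 / 40.0, rel=0.2)


class TestRotation:
    @staticmethod
    def rigid_rotation(omega0, n_cells=4, d=10.0, T=50):
        t = np.arange(T)[:, None]
        ang = omega0 * t + 2 * np.pi * np.arange(n_cells)[None, :] / n_cells
        pos = d * np.dstack([np.cos(ang), np.sin(ang)])
        vel = omega0 * d * np.dstack([-np.sin(ang), np.cos(ang)])
        return pos, vel

    def test_rigid_ccw_rotation_gives_plus_omega(self):
        pos, vel = self.rigid_rotation(0.02)
        w = cluster_angular_velocity(pos, vel)
        assert w == pytest.approx(np.full(len(w), 0.02))

    def test_pure_radial_expansion_gives_zero(self):
        pos, _ = self.rigid_rotation(0.0)
        vel = 0.1 * pos / np.linalg.norm(pos, axis=-1, keepdims=True)
        assert cluster_angular_velocity(pos, vel) == pytest.approx(
            np.zeros(pos.shape[0]), abs=1e-12)

    def test_random_velocities_average_to_zero(self, rng):
        pos = rng.normal(0, 5, size=(400, 6, 2))
        vel = rng.normal(0, 1, size=(400, 6, 2))
        w = cluster_angular_velocity(pos, vel)
        assert np.nanmean(w) == pytest.approx(0.0, abs=3 * np.nanstd(w) / 20)

    def test_rotation_stats_constant_rotation(self):
        w = np.full(200, -0.03)
        mean_w, sd_w, sd_p = rotation_stats(w, np.full(200, 80.0))
        assert mean_w == pytest.approx(0.03)
        assert sd_w == pytest.approx(0.0)
        assert sd_p == pytest.approx(0.0)

    def test_alternating_sense_increases_sigma_omega(self):
        steady = np.full(400, 0.03)
        alternating = np.where(np.arange(400) % 80 < 40, 0.05, -0.05)
        m1, s1, _ = rotation_stats(steady, signed=True)
        m2, s2, _ = rotation_stats(alternating, signed=True)
        assert m2 == pytest.approx(0.05)
        assert s2 > s1


class TestTissueFields:
    def test_pressure_vanishes_at_solitary_equilibrium(self):
        """Virtual-dilation stress ~0 for a resting cell at its equilibrium area."""
        p = ModelParams(kappa_A=0.18, kappa_P=0.12, eps0=35.0, delta_eps=0.0,
                        R=2, mu=0.1)
        a_star = equilibrium_area(p)
        lat = build_lattice(40, 40)
        sim = Simulation(lat, p, seed=13, max_cells=2)
        cid = place_single_cell(sim, area=a_star)
        sim.step(400)
        pis = []
        for _ in range(200):
            sim.step(2)
            pis.append(float(cell_pressure(
                sim.config.area[cid], sim.config.perim[cid],
                p.eps0, p.kappa_A, p.kappa_P)))
        # zero within the scale of the stress of a +-10% area perturbation
        scale = 2 * p.kappa_A * a_star * 0.1
        assert abs(np.mean(pis)) < scale

    def test_compressed_cells_report_pressure(self):
        p = ModelParams(kappa_A=0.18, kappa_P=0.12, eps0=35.0, delta_eps=0.0,
                        R=2, mu=0.1)
        a_star = equilibrium_area(p)
        pi = cell_pressure(0.7 * a_star, 6.93 * np.sqrt(0.7 * a_star),
                           p.eps0, p.kappa_A, p.kappa_P)
        assert pi < 0

    def test_profiles_and_crossing_times(self):
        lat = build_lattice(30, 10)
        owner = np.zeros(lat.n_sites, dtype=np.int64)
        owner[lat.cx < 10] = 1
        edges = np.linspace(0, 30, 7)
        dens = density_profile(lat, owner, edges)
        assert dens[0] == pytest.approx(1.0)
        assert dens[-1] == pytest.approx(0.0)
        sig = stress_profile(lat, owner, edges, np.array([np.nan, -2.0]))
        assert sig[0] == pytest.approx(-2.0)
        assert sig[-1] == pytest.approx(0.0)  # vacuum is stress-free
        field = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0]])
        tc = first_crossing_times(field, np.array([0.0, 10.0, 20.0]))
        assert list(tc) == [10.0, 20.0]


class TestFronts:
    def test_flat_front_has_zero_roughness(self):
        lat = build_lattice(20, 10)
        owner = np.zeros(lat.n_sites, dtype=np.int64)
        owner[lat.q < 8] = 1  # offset-coordinate column cut
        h = front_profile(lat, owner, "right")
        # offset rows alternate by half a site; remove that parity ripple
        assert roughness_of_profile(h - 0.5 * (np.arange(10) % 2)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_symmetric_sawtooth_roughness_closed_form(self):
        # triangle wave of amplitude a has standard deviation a / sqrt(3)
        n = 400
        a = 3.0
        tri = a * (2 * np.abs(np.arange(n) / n * 4 % 2 - 1) - 1)
        assert roughness_of_profile(tri) == pytest.approx(a / np.sqrt(3.0),
                                                          rel=0.01)

    def test_empty_rows_excluded(self):
        lat = build_lattice(10, 6)
        owner = np.zeros(lat.n_sites, dtype=np.int64)
        owner[lat.site_index(3, 2)] = 1
        h = front_profile(lat, owner, "right")
        assert np.sum(np.isfinite(h)) == 1
        assert front_roughness(type("C", (), {"lattice": lat, "owner": owner})(),
                               "right") == 0.0


class TestPeriodogram:
    def test_dominant_period_of_a_sine_with_trend(self):
        t = np.arange(0, 2000, 10.0)
        y = 0.3 * t / 2000 + np.sin(2 * np.pi * t / 200.0)
        assert dominant_period(y, dt=10.0) == pytest.approx(200.0, rel=0.05)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            dominant_period(np.ones(5))
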