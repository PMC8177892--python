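"""Generator contracts: frozen dynamics, determinism, and distributional
recovery of the parameters the downstream estimators are meant to measure."""

import numpy as np
import pytest
from scipy import stats

from wntbead import bead_dynamics as bd
from wntbead import simulate, spindle
from wntbead.config import SimulationConfig


def radius_series(track):
    return (np.linalg.norm(track.p_bead - track.p_cell, axis=1)
            / np.linalg.norm(track.p_membrane - track.p_cell, axis=1))


class TestBeadTrack:
    def test_frozen_radial_dynamics(self):
        # k_reloc=0, sigma_r=0: the radius fraction never moves off r0
        cfg = SimulationConfig(k_reloc=0.0, sigma_r=0.0, r0=0.9,
                               contact_hazard=1.0, drop_hazard=0.0)
        tr = simulate.simulate_bead_track(cfg, "c0")
        r = radius_series(tr)[tr.in_contact]
        assert np.allclose(r, 0.9, atol=1e-12)

    def test_one_step_convergence(self):
        # k_reloc=1 jumps straight to the equilibrium radius at t=1
        cfg = SimulationConfig(k_reloc=1.0, sigma_r=0.0, r0=0.9, r_eq=0.5,
                               contact_hazard=1.0, drop_hazard=0.0)
        tr = simulate.simulate_bead_track(cfg, "c0")
        r = radius_series(tr)
        assert np.allclose(r[tr.t >= 1][np.isfinite(r[tr.t >= 1])], 0.5)

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=42)
        a = simulate.simulate_bead_track(cfg, "c0")
        b = simulate.simulate_bead_track(cfg, "c0")
        np.testing.assert_array_equal(a.p_cell, b.p_cell)
        np.testing.assert_array_equal(a.p_bead, b.p_bead)
        np.testing.assert_array_equal(a.in_contact, b.in_contact)
        assert a.divided_at == b.divided_at

    def test_radius_fraction_stays_in_unit_interval(self):
        cfg = SimulationConfig(sigma_r=0.5, r0=0.05, r_eq=0.05,
                               contact_hazard=1.0, drop_hazard=0.0, seed=7)
        tr = simulate.simulate_bead_track(cfg, "c0")
        r = radius_series(tr)[tr.in_contact]
        assert np.all(r > 0) and np.all(r <= 1.0 + 1e-12)

    def test_membrane_on_unit_radius(self):
        cfg = SimulationConfig(cell_radius_um=8.0, seed=1)
        tr = simulate.simulate_bead_track(cfg, "c0")
        radii = np.linalg.norm(tr.p_membrane - tr.p_cell, axis=1)
        assert np.allclose(radii, 8.0)

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(sigma_r=float("nan"))

    def test_no_contact_before_uptake(self):
        cfg = SimulationConfig(contact_hazard=0.05, seed=11)
        tr = simulate.simulate_bead_track(cfg, "c0")
        if tr.in_contact.any():
            first = np.flatnonzero(tr.in_contact)[0]
            assert not tr.in_contact[:first].any()
            assert np.all(np.isnan(tr.p_bead[:first]))


class TestCohortRecovery:
    @pytest.mark.parametrize("r_eq", [0.5, 0.7])
    def test_late_window_mean_recovers_r_eq(self, r_eq):
        # cohort of 50 cells: mean radius fraction in the 121-180 min
        # window sits within +-0.05 of the configured equilibrium
        cfg = SimulationConfig(
            n_cells=50, k_reloc=0.1, sigma_r=0.02, r_eq=r_eq, r0=1.0,
            contact_hazard=1.0, drop_hazard=0.0, division_hazard=0.0,
            seed=5,
        )
        means = []
        for tr in simulate.simulate_cohort(cfg):
            series = bd.position_series(tr)
            wm = bd.window_means(series)[2]
            assert wm.window == (121, 180)
            means.append(wm.mean)
        assert abs(np.mean(means) - r_eq) <= 0.05

    def test_late_window_mean_monotone_in_r_eq(self):
        recovered = []
        for r_eq in (0.3, 0.5, 0.7, 0.9):
            cfg = SimulationConfig(
                n_cells=20, k_reloc=0.1, sigma_r=0.02, r_eq=r_eq, r0=1.0,
                contact_hazard=1.0, drop_hazard=0.0, division_hazard=0.0,
                seed=9,
            )
            means = [bd.window_means(bd.position_series(tr))[2].mean
                     for tr in simulate.simulate_cohort(cfg)]
            recovered.append(np.mean(means))
        assert all(a < b for a, b in zip(recovered, recovered[1:]))

    def test_msd_cell_recovers_step_variance(self):
        # E|dP|^2 = 2 sigma^2 for an isotropic Gaussian walk
        sigma = 1.0
        cfg = SimulationConfig(n_cells=100, cell_step_sigma=sigma, seed=3)
        msds = [bd.msd_cell(tr) for tr in simulate.simulate_cohort(cfg)]
        se = np.std(msds, ddof=1) / np.sqrt(len(msds))
        assert abs(np.mean(msds) - 2 * sigma**2) <= 3 * se


class TestPopulation:
    def test_certain_cytonemes_from_minute_one(self):
        cfg = SimulationConfig(n_cells=10, cytoneme_hazard=1.0, seed=2)
        pop = simulate.simulate_population(cfg, 2)
        after = pop[pop["t_min"] >= 1]
        assert (after["n_with_cytonemes"] == after["n_total"]).all()

    def test_zero_hazard_no_contact(self):
        cfg = SimulationConfig(n_cells=10, contact_hazard=0.0, seed=2)
        pop = simulate.simulate_population(cfg, 2)
        assert (pop["n_with_beads"] == 0).all()

    def test_contact_times_follow_geometric_cdf(self):
        h = 0.05
        cfg = SimulationConfig(n_cells=400, contact_hazard=h,
                               duration_min=60, seed=8)
        pop = simulate.simulate_population(cfg, 1)
        n = 400
        for t in (10, 30, 60):
            frac = pop.loc[pop["t_min"] == t, "n_with_beads"].iloc[0] / n
            expect = 1 - (1 - h) ** t
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(frac - expect) <= 3 * se

    def test_counts_monotone_when_events_irreversible(self):
        cfg = SimulationConfig(n_cells=30, seed=4)
        pop = simulate.simulate_population(cfg, 2)
        for _, grp in pop.groupby("position_id"):
            assert (grp["n_with_beads"].diff().dropna() >= 0).all()
            assert (grp["n_with_cytonemes"].diff().dropna() >= 0).all()

    def test_zero_positions_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_population(SimulationConfig(), 0)


class TestDivisions:
    def test_uniform_mixture_component(self):
        # angle_mix_p=0: angles are uniform on [0, 90]
        cfg = SimulationConfig(angle_mix_p=0.0, seed=6)
        _, angles = simulate.simulate_divisions(cfg, 2000, return_angles=True)
        p = stats.kstest(angles / 90.0, "uniform").pvalue
        assert p > 0.01

    def test_degenerate_oriented_mixture(self):
        # concentrated oriented component: everything within 5 deg of 90
        cfg = SimulationConfig(angle_mix_p=1.0, angle_kappa=4.0, seed=6)
        _, angles = simulate.simulate_divisions(cfg, 500, return_angles=True)
        assert np.all(angles >= 85.0)

    def test_round_trip_through_spindle_angle(self):
        cfg = SimulationConfig(seed=10)
        events, angles = simulate.simulate_divisions(
            cfg, 200, return_angles=True
        )
        measured = np.array([spindle.spindle_angle(ev) for ev in events])
        np.testing.assert_allclose(measured, angles, atol=1e-6)


class TestDoublets:
    def test_noise_free_intensity_arithmetic(self):
        cfg = SimulationConfig(noise_sd=0.0, total_intensity=100.0,
                               background_mean=10.0, seed=1)
        recs = simulate.simulate_doublets(
            cfg, 1, true_category_rates={"Proximal": 1.0})
        r = recs[0]
        p = (r.i_proximal - 10.0) / 100.0
        assert np.isclose(r.i_proximal, 10.0 + p * 100.0)
        assert np.isclose(r.i_distal, 10.0 + (1 - p) * 100.0)
        assert np.isclose(r.i_background, 10.0)

    def test_noise_free_partition_round_trip(self):
        from wntbead import acd
        cfg = SimulationConfig(noise_sd=0.0, seed=13)
        recs = simulate.simulate_doublets(cfg, 50)
        for r in recs:
            p_implied = (r.i_proximal - r.i_background) / cfg.total_intensity
            assert np.isclose(acd.partition_percent(r), 100.0 * p_implied,
                              atol=1e-9)

    def test_symmetric_beta_gives_balanced_partition(self):
        from wntbead import acd
        cfg = SimulationConfig(partition_alpha=3.0, partition_beta=3.0,
                               noise_sd=0.0, seed=14)
        recs = simulate.simulate_doublets(cfg, 5000)
        mean_pct = np.mean([acd.partition_percent(r) for r in recs])
        assert abs(mean_pct - 50.0) <= 1.0
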