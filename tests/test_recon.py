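"""OSEM, penalized MLTR and MLAA-TX: fixed points, monotonicity,
limits and recovery properties."""

from dataclasses import replace

import numpy as np
import pytest

from lutac.constants import ETA_307
from lutac.geometry import LORTable, SinogramSpec, build_scanner, desk_variant
from lutac.grid import Grid
from lutac.phantom import BodySpec, Organ, build_phantom
from lutac.projector import (attenuation_factors, forward_project,
                             place_endpoints, tof_forward_project)
from lutac.recon import (ReconConfig, mlaa_tx_reconstruct, mltr_reconstruct,
                         osem_reconstruct, sqs_curvatures)
from lutac.simulate import SinogramSet, simulate_transmission, LuSourceModel


def toy_table(p1, p2, tof_bins=0, tof_bin_width=1e9):
    """LOR table with explicit endpoints (identical at both energies)."""
    geom = desk_variant(build_scanner("uexplorer"), crystals_per_ring=40,
                        rings_per_unit=3)
    geom = replace(geom, tof_bin_width_ps=tof_bin_width)
    p1 = np.atleast_2d(np.asarray(p1, float))
    p2 = np.atleast_2d(np.asarray(p2, float))
    n = len(p1)
    z = np.zeros(n, dtype=np.int32)
    spec = SinogramSpec(n_radial=1, n_angles=1, axial_mash=1, tof_bins=tof_bins)
    return LORTable(geometry=geom, spec=spec, radial=z, angle=z,
                    plane_a=z, plane_b=z, ring_a=z, ring_b=z,
                    trans_a=z, trans_b=np.ones(n, dtype=np.int32),
                    front_a=p1, front_b=p2,
                    lor_length=np.linalg.norm(p2 - p1, axis=1),
                    geom_weight=np.ones(n),
                    end511_a=p1, end511_b=p2, end307_a=p1, end307_b=p2)


def single_voxel_problem(mu_true=0.0096, chord=200.0):
    grid = Grid((1, 1, 1), chord)
    tab = toy_table([-chord, 0, 0], [chord, 0, 0])
    return grid, tab


class TestOSEM:
    def test_single_lor_fixed_point(self):
        """One voxel, one LOR, no attenuation: one update lands on the
        count-matching solution and stays there."""
        grid = Grid((1, 1, 1), 200.0)
        tab = toy_table([-200, 0, 0], [200, 0, 0], tof_bins=1)
        y = np.array([[50.0]])
        sino = SinogramSet(table=tab, duration_s=1.0, emis_true=y,
                           emission_scale=1.0)
        cfg = ReconConfig(algorithm="osem", n_iterations=1, n_subsets=1)
        res = osem_reconstruct(sino, np.zeros(grid.shape), grid, config=cfg)
        lam = res.activity[0, 0, 0]
        assert lam * 200.0 == pytest.approx(50.0, rel=1e-12)
        res2 = osem_reconstruct(sino, np.zeros(grid.shape), grid,
                                config=replace(cfg, n_iterations=5))
        assert res2.activity[0, 0, 0] == pytest.approx(lam, rel=1e-12)

    def test_loglik_monotone_one_subset(self, tiny_tof_table, tiny_phantom):
        from lutac.simulate import simulate_emission
        em = simulate_emission(tiny_tof_table, tiny_phantom, 600.0, seed=5,
                               target_counts=3e5)
        cfg = ReconConfig(algorithm="osem", n_iterations=6, n_subsets=1,
                          track_objective=True)
        res = osem_reconstruct(em, tiny_phantom.mu511, tiny_phantom.grid,
                               config=cfg)
        obj = np.array(res.objective)
        assert np.all(np.diff(obj) >= -1e-6 * np.abs(obj[:-1]))

    def test_noiseless_uniform_cylinder_recovery(self, small_tof_table):
        """Ground-truth mu, noiseless data: the centre of a uniform
        cylinder is recovered within 1% at 30 equivalent iterations."""
        body = BodySpec(organs=(Organ("water", "cylinder", (0, 0, 0),
                                      (55, 55, 130), "soft_tissue"),),
                        total_activity_mbq=2.0, grid_shape=(20, 20, 40),
                        voxel_size=8.0)
        ph = build_phantom(body)
        tab = small_tof_table
        scale = 1.0
        proj = tof_forward_project(ph.activity, tab.end511_a, tab.end511_b,
                                   ph.grid, tab.geometry, tab.spec.tof_bins)
        a = attenuation_factors(ph.mu511, tab.end511_a, tab.end511_b,
                                ph.grid, 511)
        sino = SinogramSet(table=tab, duration_s=1.0,
                           emis_true=scale * proj * a[:, None],
                           emission_scale=scale)
        res = osem_reconstruct(sino, ph.mu511, ph.grid,
                               config=ReconConfig(algorithm="osem",
                                                  n_iterations=3, n_subsets=10))
        core = np.zeros(ph.grid.shape, dtype=bool)
        core[7:13, 7:13, 12:28] = True
        gt = ph.activity[core].mean()
        assert res.activity[core].mean() == pytest.approx(gt, rel=0.01)

    def test_nonnegative_output(self, tiny_tof_table, tiny_phantom):
        from lutac.simulate import simulate_emission
        em = simulate_emission(tiny_tof_table, tiny_phantom, 600.0, seed=6,
                               target_counts=1e5)
        res = osem_reconstruct(em, tiny_phantom.mu511, tiny_phantom.grid,
                               config=ReconConfig(algorithm="osem",
                                                  n_iterations=2, n_subsets=4))
        assert res.activity.min() >= 0.0


class TestMLTR:
    def test_single_voxel_closed_form(self):
        grid, tab = single_voxel_problem()
        B, mu_t = 1e5, 0.0096
        y = B * np.exp(-ETA_307 * mu_t * 200.0)
        sino = SinogramSet(table=tab, duration_s=1.0, blank=np.array([B]),
                           blank_duration_s=1.0, tran_true=np.array([y]))
        cfg = ReconConfig(algorithm="mltr", n_iterations=150, n_subsets=1,
                          beta=0.0)
        res = mltr_reconstruct(sino, grid, cfg)
        assert res.mu[0, 0, 0] == pytest.approx(mu_t, rel=1e-3)

    def test_vacuum_converges_to_zero(self, tiny_table, tiny_phantom):
        B = np.full(len(tiny_table), 400.0)
        sino = SinogramSet(table=tiny_table, duration_s=1.0, blank=B,
                           blank_duration_s=1.0, tran_true=B.copy())
        res = mltr_reconstruct(sino, tiny_phantom.grid,
                               ReconConfig(algorithm="mltr", n_iterations=20,
                                           n_subsets=1, beta=0.0))
        assert np.abs(res.mu).max() < 1e-5

    def test_penalty_dominated_limit_is_flat(self, tiny_table, tiny_phantom):
        rng = np.random.default_rng(0)
        B = np.full(len(tiny_table), 200.0)
        y = rng.poisson(150.0, len(tiny_table)).astype(float)
        sino = SinogramSet(table=tiny_table, duration_s=1.0, blank=B,
                           blank_duration_s=1.0, tran_true=y)
        res = mltr_reconstruct(sino, tiny_phantom.grid,
                               ReconConfig(algorithm="mltr", n_iterations=30,
                                           n_subsets=1, beta=1e14))
        assert res.mu.max() - res.mu.min() < 1e-6

    def test_penalized_objective_monotone(self, tiny_table, tiny_phantom):
        """Surrogate descent: the penalized negative log-likelihood is
        non-increasing with a single subset (noiseless data)."""
        B = np.full(len(tiny_table), 500.0)
        a = attenuation_factors(tiny_phantom.mu511, tiny_table.end307_a,
                                tiny_table.end307_b, tiny_phantom.grid, 307)
        sino = SinogramSet(table=tiny_table, duration_s=1.0, blank=B,
                           blank_duration_s=1.0, tran_true=B * a)
        cfg = ReconConfig(algorithm="mltr", n_iterations=40, n_subsets=1,
                          beta=500.0, track_objective=True)
        res = mltr_reconstruct(sino, tiny_phantom.grid, cfg)
        obj = np.array(res.objective)
        assert np.all(np.diff(obj) <= 1e-9 * np.abs(obj[:-1]) + 1e-9)

    def test_subset_invariance_noiseless(self, small_geometry):
        """On a well-determined noiseless problem, 1-subset and
        10-subset runs agree within 1% RMS at matched equivalent
        iterations (near convergence)."""
        grid = Grid((12, 12, 8), 8.0)
        body = BodySpec(organs=(Organ("body", "cylinder", (0, 0, 0),
                                      (44, 40, 30), "soft_tissue"),
                                Organ("core", "sphere", (8, 0, 0), (16,),
                                      "bone")),
                        total_activity_mbq=1.0, grid_shape=(12, 12, 8),
                        voxel_size=8.0)
        ph = build_phantom(body)
        from lutac.geometry import SinogramSpec, build_lor_table
        from lutac.projector import chord_lengths, place_endpoints
        spec = SinogramSpec.for_geometry(small_geometry, axial_mash=1)
        tab = place_endpoints(build_lor_table(small_geometry, spec))
        tab = tab.restrict(chord_lengths(tab.front_a, tab.front_b, grid) > 0)
        B = np.full(len(tab), 2000.0)
        a = attenuation_factors(ph.mu511, tab.end307_a, tab.end307_b,
                                ph.grid, 307)
        sino = SinogramSet(table=tab, duration_s=1.0, blank=B,
                           blank_duration_s=1.0, tran_true=B * a)
        full = mltr_reconstruct(sino, ph.grid,
                                ReconConfig(algorithm="mltr", n_iterations=200,
                                            n_subsets=1, beta=500.0))
        sub = mltr_reconstruct(sino, ph.grid,
                               ReconConfig(algorithm="mltr", n_iterations=20,
                                           n_subsets=10, beta=500.0))
        m = ph.labels > 0
        rms = np.sqrt(np.mean((full.mu[m] - sub.mu[m]) ** 2))
        assert rms < 0.01 * ph.mu511[m].mean()

    def test_zero_blank_bins_excluded_with_warning(self, tiny_table,
                                                   tiny_phantom):
        B = np.full(len(tiny_table), 100.0)
        y = np.full(len(tiny_table), 60.0)
        B[0], y[0] = 0.0, 5.0
        sino = SinogramSet(table=tiny_table, duration_s=1.0, blank=B,
                           blank_duration_s=1.0, tran_true=y)
        with pytest.warns(UserWarning, match="zero blank"):
            mltr_reconstruct(sino, tiny_phantom.grid,
                             ReconConfig(algorithm="mltr", n_iterations=1,
                                         n_subsets=1))

    def test_eta_consistent_recovery_water(self, small_geometry, tiny_grid):
        """Data simulated with the eta model reconstruct directly to
        511 keV coefficients (water region within 2%)."""
        from lutac.geometry import build_lor_table
        from lutac.projector import chord_lengths, place_endpoints
        body = BodySpec(organs=(Organ("water", "cylinder", (0, 0, 0),
                                      (55, 55, 130), "water"),),
                        total_activity_mbq=0.0, grid_shape=(20, 20, 40),
                        voxel_size=8.0)
        ph = build_phantom(body)
        spec = SinogramSpec.for_geometry(small_geometry, axial_mash=1)
        tab = place_endpoints(build_lor_table(small_geometry, spec))
        tab = tab.restrict(chord_lengths(tab.front_a, tab.front_b,
                                         tiny_grid) > 0)
        tr = simulate_transmission(tab, ph, LuSourceModel(), 1200.0,
                                   seed=3, exposure_scale=200.0)
        res = mltr_reconstruct(tr, ph.grid,
                               ReconConfig(algorithm="mltr", n_iterations=50,
                                           n_subsets=10, beta=100.0))
        core = np.zeros(ph.grid.shape, dtype=bool)
        core[7:13, 7:13, 10:30] = True
        assert res.mu[core].mean() == pytest.approx(0.0096, rel=0.02)


class TestCurvatures:
    def test_zero_counts_floored_finite(self):
        c = sqs_curvatures(np.zeros(4), np.zeros(4), np.zeros(4),
                           np.array([0.0, 0.1, 1.0, 10.0]))
        assert np.all(c > 0)
        assert np.all(np.isfinite(c))

    def test_positive_for_poisson_data(self):
        rng = np.random.default_rng(1)
        B = rng.uniform(10, 1e4, 100)
        y = rng.poisson(B * 0.3).astype(float)
        Z = rng.uniform(0, 5, 100)
        c = sqs_curvatures(B, np.zeros(100), y, Z)
        assert np.all(c > 0)

    def test_stationary_at_optimum(self):
        """At the exact solution the SQS step vanishes."""
        grid, tab = single_voxel_problem()
        B, mu_t = 1e6, 0.0096
        y = B * np.exp(-ETA_307 * mu_t * 200.0)
        sino = SinogramSet(table=tab, duration_s=1.0, blank=np.array([B]),
                           blank_duration_s=1.0, tran_true=np.array([y]))
        mu0 = np.full(grid.shape, mu_t)
        res = mltr_reconstruct(sino, grid,
                               ReconConfig(algorithm="mltr", n_iterations=1,
                                           n_subsets=1, beta=0.0),
                               init_mu=mu0)
        assert abs(res.mu[0, 0, 0] - mu_t) < 1e-10


class TestMLAATX:
    def test_large_alpha_matches_mltr(self, tiny_tof_table, tiny_table,
                                      tiny_phantom):
        """With an overwhelming transmission weight, MLAA-TX holds an
        (unpenalized) MLTR fixed point: on data exactly consistent
        with the MLTR map, the joint mu update stays put."""
        from lutac.simulate import simulate_emission
        em = simulate_emission(tiny_tof_table, tiny_phantom, 1200.0, seed=9,
                               target_counts=5e5)
        B = np.full(len(tiny_table), 5000.0)
        a = attenuation_factors(tiny_phantom.mu511, tiny_table.end307_a,
                                tiny_table.end307_b, tiny_phantom.grid, 307)
        tr = SinogramSet(table=tiny_table, duration_s=1.0, blank=B,
                         blank_duration_s=1.0, tran_true=B * a)
        mres = mltr_reconstruct(tr, tiny_phantom.grid,
                                ReconConfig(algorithm="mltr", n_iterations=60,
                                            n_subsets=10, beta=0.0))
        # transmission data consistent with the MLTR map: its exact
        # ML fixed point
        a_fix = attenuation_factors(mres.mu, tiny_table.end307_a,
                                    tiny_table.end307_b, tiny_phantom.grid, 307)
        tr_fix = SinogramSet(table=tiny_table, duration_s=1.0, blank=B,
                             blank_duration_s=1.0, tran_true=B * a_fix)
        # single subset: every voxel's update is transmission-dominated
        # (with subsets, a voxel missing from one subset's transmission
        # rows would receive a pure-emission update there)
        jres = mlaa_tx_reconstruct(em, tr_fix, mres.mu, tiny_phantom.grid,
                                   config=ReconConfig(algorithm="mlaa_tx",
                                                      n_iterations=3,
                                                      n_subsets=1, beta=0.0,
                                                      alpha=1e9))
        body = tiny_phantom.labels > 0
        denom = tiny_phantom.mu511[body].mean()
        assert np.abs(jres.mu[body] - mres.mu[body]).max() / denom < 1e-3

    def test_single_voxel_joint_fixed_point(self):
        grid = Grid((1, 1, 1), 200.0)
        tab = toy_table([-200, 0, 0], [200, 0, 0], tof_bins=1)
        mu_t, lam_t, B = 0.0096, 0.3, 1e5
        a511 = np.exp(-mu_t * 200.0)
        y_e = np.array([[lam_t * 200.0 * a511]])
        y_t = np.array([B * np.exp(-ETA_307 * mu_t * 200.0)])
        em = SinogramSet(table=tab, duration_s=1.0, emis_true=y_e,
                         emission_scale=1.0)
        tr = SinogramSet(table=tab, duration_s=1.0, blank=np.array([B]),
                         blank_duration_s=1.0, tran_true=y_t)
        for alpha in (0.1, 1.0, 10.0):
            cfg = ReconConfig(algorithm="mlaa_tx", n_iterations=4, n_subsets=1,
                              beta=0.0, alpha=alpha)
            res = mlaa_tx_reconstruct(em, tr, np.full(grid.shape, mu_t),
                                      grid, config=cfg)
            assert res.mu[0, 0, 0] == pytest.approx(mu_t, rel=1e-6)
            assert res.activity[0, 0, 0] == pytest.approx(lam_t, rel=1e-6)

    def test_crosstalk_direction_with_hot_region(self, small_geometry,
                                                 tiny_grid, tiny_phantom):
        """Early iterations with a weak transmission weight
        underestimate mu inside the hot bladder (crosstalk); a strong
        weight pins mu to the transmission data."""
        from lutac.geometry import SinogramSpec, build_lor_table
        from lutac.projector import chord_lengths, place_endpoints
        from lutac.simulate import simulate_emission

        def mk(tof):
            spec = SinogramSpec.for_geometry(small_geometry, tof=tof,
                                             axial_mash=3)
            t = place_endpoints(build_lor_table(small_geometry, spec))
            return t.restrict(chord_lengths(t.front_a, t.front_b,
                                            tiny_grid) > 0)

        em = simulate_emission(mk(True), tiny_phantom, 1200.0, seed=21,
                               target_counts=3e6)
        tr = simulate_transmission(mk(False), tiny_phantom, LuSourceModel(),
                                   1200.0, seed=22, exposure_scale=3.0)
        mres = mltr_reconstruct(tr, tiny_phantom.grid,
                                ReconConfig(algorithm="mltr", n_iterations=30,
                                            n_subsets=10, beta=1000.0))
        hot = tiny_phantom.organ_mask("bladder")
        mus = {}
        for alpha in (0.1, 10.0):
            cfg = ReconConfig(algorithm="mlaa_tx", n_iterations=3,
                              n_subsets=10, beta=1000.0, alpha=alpha)
            res = mlaa_tx_reconstruct(em, tr, mres.mu, tiny_phantom.grid,
                                      config=cfg)
            mus[alpha] = res.mu[hot].mean()
            assert res.mu.min() >= 0.0
            assert res.activity.min() >= 0.0
        # a weak transmission weight lets the emission term drag the
        # hot-region mu down noticeably
        assert mus[0.1] < 0.95 * mus[10.0]
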