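"""Sinogram-domain simulation: rates, energy model, TOF rule,
scatter categories and normalization."""

import numpy as np
import pytest
from scipy.stats import norm

from lutac.constants import C_MM_PER_PS
from lutac.geometry import (EnergyWindow, GAMMA_WINDOW_250, GAMMA_WINDOW_290)
from lutac.phantom import build_phantom, BodySpec
from lutac.simulate import (LuSourceModel, apply_energy_window,
                            blank_expectation, decay_factor,
                            energy_window_survival, load_sinogram_set,
                            normalization_factors, reject_by_tof,
                            save_sinogram_set, simulate_blank,
                            simulate_emission, simulate_transmission)


class TestDecay:
    def test_20min_f18_factor(self):
        assert decay_factor(1200.0) == pytest.approx(0.93943, abs=1e-4)

    def test_zero_duration(self):
        assert decay_factor(0.0) == 1.0

    def test_monotone_in_duration(self):
        ds = [decay_factor(60.0 * t) for t in (1, 5, 20, 60)]
        assert all(b < a for a, b in zip(ds, ds[1:]))


class TestEnergyModel:
    def test_307_photopeak_survival_in_gamma_window(self):
        s = 0.117 * np.sqrt(511 * 307) / 2.3548200450309493
        expected = norm.cdf((350 - 307) / s) - norm.cdf((250 - 307) / s)
        assert energy_window_survival(307.0, GAMMA_WINDOW_250) == \
            pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.9836, abs=2e-4)

    def test_raising_threshold_removes_fraction(self):
        lost = (energy_window_survival(307.0, GAMMA_WINDOW_250)
                - energy_window_survival(307.0, GAMMA_WINDOW_290))
        assert lost == pytest.approx(0.192, abs=2e-3)

    def test_wide_window_passes_everything(self):
        win = EnergyWindow(1.0, 1e5)
        assert energy_window_survival(307.0, win) == pytest.approx(1.0)

    def test_event_smearing_matches_closed_form(self):
        rng = np.random.default_rng(0)
        e = np.full(200_000, 307.0)
        mask = apply_energy_window(e, GAMMA_WINDOW_250, rng=rng)
        expect = energy_window_survival(307.0, GAMMA_WINDOW_250)
        assert mask.mean() == pytest.approx(expect, abs=3e-3)


class TestBlank:
    def test_linearity_in_duration_and_rate(self, tiny_table):
        lu = LuSourceModel()
        e1 = blank_expectation(tiny_table, lu, 60.0)
        e2 = blank_expectation(tiny_table, lu, 120.0)
        assert np.allclose(e2, 2.0 * e1)
        half = LuSourceModel(rate_per_cc=46.1)
        assert np.allclose(blank_expectation(tiny_table, half, 60.0),
                           0.5 * e1, rtol=1e-12)

    def test_zero_rate_gives_empty_sinogram(self, tiny_table):
        s = simulate_blank(tiny_table, LuSourceModel(rate_per_cc=0.0), 60.0, 1)
        assert s.blank.sum() == 0

    def test_deterministic_given_seed(self, tiny_table):
        lu = LuSourceModel()
        a = simulate_blank(tiny_table, lu, 60.0, seed=9)
        b = simulate_blank(tiny_table, lu, 60.0, seed=9)
        assert np.array_equal(a.blank, b.blank)


class TestTransmission:
    def test_vacuum_equals_blank_in_expectation(self, tiny_table):
        vac = build_phantom(BodySpec(organs=(), grid_shape=(20, 20, 40),
                                     voxel_size=8.0))
        lu = LuSourceModel()
        tr = simulate_transmission(tiny_table, vac, lu, 600.0, seed=2)
        expect = blank_expectation(tiny_table, lu, 600.0)
        tot = expect.sum()
        assert abs(tr.tran_true.sum() - tot) < 4 * np.sqrt(tot)

    def test_attenuation_ratio_matches_closed_form(self, tiny_table,
                                                   tiny_phantom):
        from lutac.projector import attenuation_factors
        lu = LuSourceModel()
        tr = simulate_transmission(tiny_table, tiny_phantom, lu, 600.0, seed=3,
                                   exposure_scale=50.0)
        a = attenuation_factors(tiny_phantom.mu511, tiny_table.end307_a,
                                tiny_table.end307_b, tiny_phantom.grid, 307)
        expect = tr.blank_for_transmission() * a
        # chi-square-like global consistency at high counts
        tot_obs, tot_exp = tr.tran_true.sum(), (blank_expectation(
            tiny_table, lu, 600.0) * 50.0 * a).sum()
        assert abs(tot_obs - tot_exp) < 4 * np.sqrt(tot_exp)
        # per-LOR z-scores approximately standard normal
        lam = blank_expectation(tiny_table, lu, 600.0) * 50.0 * a
        big = lam > 50
        z = (tr.tran_true[big] - lam[big]) / np.sqrt(lam[big])
        assert abs(z.mean()) < 0.05
        assert z.std() == pytest.approx(1.0, abs=0.05)

    def test_no_scatter_mode_has_empty_categories(self, tiny_table,
                                                  tiny_phantom):
        tr = simulate_transmission(tiny_table, tiny_phantom, LuSourceModel(),
                                   600.0, seed=4, scatter_mode="none")
        assert tr.tran_scat307.sum() == 0
        assert tr.tran_contam511.sum() == 0

    def test_single_scatter_categories_are_additive(self, tiny_table,
                                                    tiny_phantom):
        tr = simulate_transmission(tiny_table, tiny_phantom, LuSourceModel(),
                                   600.0, seed=5, scatter_mode="single_scatter",
                                   exposure_scale=2.0)
        assert tr.tran_scat307.sum() > 0
        total = tr.transmission(include_scatter=True)
        assert np.array_equal(total, tr.tran_true + tr.tran_scat307)

    def test_raised_threshold_cuts_scatter_harder_than_trues(
            self, tiny_table, tiny_phantom):
        lu = LuSourceModel()
        kw = dict(seed=6, scatter_mode="single_scatter", exposure_scale=4.0)
        lo = simulate_transmission(tiny_table, tiny_phantom, lu, 600.0,
                                   gamma_window=GAMMA_WINDOW_250, **kw)
        hi = simulate_transmission(tiny_table, tiny_phantom, lu, 600.0,
                                   gamma_window=GAMMA_WINDOW_290, **kw)
        keep_true = hi.tran_true.sum() / lo.tran_true.sum()
        keep_scat = hi.tran_scat307.sum() / lo.tran_scat307.sum()
        assert keep_scat < keep_true  # scattered 307s lost energy


class TestEmission:
    def test_tof_marginal_matches_attenuated_projection(self, tiny_tof_table,
                                                        tiny_phantom):
        from lutac.projector import attenuation_factors, forward_project
        em = simulate_emission(tiny_tof_table, tiny_phantom, 1200.0, seed=7,
                               sensitivity=1e-4)
        proj = forward_project(tiny_phantom.activity, tiny_tof_table.end511_a,
                               tiny_tof_table.end511_b, tiny_phantom.grid)
        a = attenuation_factors(tiny_phantom.mu511, tiny_tof_table.end511_a,
                                tiny_tof_table.end511_b, tiny_phantom.grid, 511)
        lam = em.emission_scale * proj * a
        tot = lam.sum()
        assert abs(em.emis_true.sum() - tot) < 4 * np.sqrt(tot) + 0.002 * tot

    def test_zero_activity(self, tiny_tof_table):
        vac = build_phantom(BodySpec(organs=(), grid_shape=(20, 20, 40),
                                     voxel_size=8.0))
        em = simulate_emission(tiny_tof_table, vac, 1200.0, seed=8,
                               sensitivity=1.0)
        assert em.emis_true.sum() == 0

    def test_decay_factor_in_scale(self, tiny_tof_table, tiny_phantom):
        em = simulate_emission(tiny_tof_table, tiny_phantom, 1200.0, seed=9,
                               sensitivity=2.0)
        assert em.emission_scale == pytest.approx(2.0 * 1200.0 * 0.93943,
                                                  rel=1e-4)


class TestTOFRejection:
    def test_body_origin_rejected_crystal_origin_kept(self, tiny_geometry):
        """Events emitted at the LOR midpoint fail the |TOF| threshold;
        crystal-origin events pass with the 500 ps margin tail."""
        rng = np.random.default_rng(10)
        n = 100_000
        L = 786.0
        thr = L / C_MM_PER_PS - 500.0
        sigma = tiny_geometry.ctr_ps / 2.3548200450309493
        # midpoint emission: true TOF 0
        tof_mid = rng.standard_normal(n) * sigma
        frac_mid = reject_by_tof(tof_mid, thr).mean()
        assert frac_mid < 1e-4
        # crystal origin: |TOF| centred 500 ps above the threshold
        tof_cry = L / C_MM_PER_PS + rng.standard_normal(n) * sigma
        frac_cry = reject_by_tof(tof_cry, thr).mean()
        assert frac_cry == pytest.approx(norm.cdf(500.0 / sigma), abs=5e-3)

    def test_short_lor_accepts_everything(self):
        thr = 100.0 / C_MM_PER_PS - 500.0  # negative threshold
        assert thr < 0
        tof = np.array([0.0, -10.0, 5.0])
        assert reject_by_tof(tof, thr).all()


class TestNormalization:
    def test_ideal_is_unity(self, tiny_table):
        n = normalization_factors(tiny_table, "ideal")
        assert np.all(n.n_i == 1.0)

    def test_annulus_converges_to_unity(self, tiny_table):
        n = normalization_factors(tiny_table, "annulus", seed=1,
                                  counts_per_lor=2000.0)
        spec = tiny_table.spec
        width = tiny_table.geometry.transaxial_fov / spec.n_radial
        s = (tiny_table.radial - spec.n_radial // 2) * width
        covered = np.abs(s) < tiny_table.geometry.transaxial_fov / 2.0 - 20.0
        assert np.abs(n.n_i[covered] - 1.0).max() < 0.05
        assert np.abs(np.median(n.n_i[covered]) - 1.0) < 0.01

    def test_injected_efficiency_recovered(self, tiny_table):
        ring = int(tiny_table.ring_a[0])
        trans = int(tiny_table.trans_a[0])
        n = normalization_factors(tiny_table, "annulus", seed=2,
                                  counts_per_lor=2000.0,
                                  crystal_efficiency={(ring, trans): 2.0})
        touched = ((tiny_table.ring_a == ring) & (tiny_table.trans_a == trans))
        others = ~touched & ((tiny_table.ring_b != ring) | (tiny_table.trans_b != trans))
        ratio = np.median(n.n_i[touched]) / np.median(n.n_i[others])
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestSerialization:
    def test_hdf5_roundtrip(self, tiny_table, tiny_phantom, tmp_path):
        tr = simulate_transmission(tiny_table, tiny_phantom, LuSourceModel(),
                                   600.0, seed=11)
        path = tmp_path / "sino.h5"
        save_sinogram_set(tr, path)
        back = load_sinogram_set(path, tiny_table)
        assert np.array_equal(back.tran_true, tr.tran_true)
        assert np.array_equal(back.blank, tr.blank)
        assert back.duration_s == tr.duration_s
        assert back.windows == tr.windows
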