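"""Ray tracing, DOI model, attenuation and TOF projection."""

import numpy as np
import pytest

from lutac.constants import C_MM_PER_PS, ETA_307
from lutac.grid import Grid
from lutac.projector import (DOIModel, attenuation_factors, back_project,
                             chord_lengths, doi_depth, eta_transform,
                             forward_project, siddon_path, tof_back_project,
                             tof_forward_project)


class TestDOI:
    def test_mean_depth_at_511(self):
        # the fixed quantile reproduces the ~7 mm interaction depth
        assert doi_depth(DOIModel()) == pytest.approx(7.623, abs=1e-3)

    def test_depth_at_307_scaling(self):
        assert doi_depth(DOIModel(eta=ETA_307)) == pytest.approx(6.966, abs=1e-3)

    def test_limits(self):
        m = DOIModel()
        assert doi_depth(m, 0.0) == 0.0
        assert doi_depth(m, 1.0) == pytest.approx(m.crystal_length)

    def test_monotone_in_quantile_and_energy(self):
        ys = np.linspace(0.01, 0.99, 25)
        d511 = doi_depth(DOIModel(), ys)
        d307 = doi_depth(DOIModel(eta=ETA_307), ys)
        assert np.all(np.diff(d511) > 0)
        assert np.all(d307 < d511)  # higher effective mu -> shallower

    def test_invalid_quantile(self):
        with pytest.raises(ValueError):
            DOIModel(Y=1.5)


def _clip_length(p1, p2, lo, hi):
    """Independent Liang-Barsky box clip used as the chord oracle."""
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    d = p2 - p1
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if d[ax] == 0:
            if p1[ax] <= lo[ax] or p1[ax] >= hi[ax]:
                return 0.0
        else:
            a = (lo[ax] - p1[ax]) / d[ax]
            b = (hi[ax] - p1[ax]) / d[ax]
            a, b = min(a, b), max(a, b)
            t0, t1 = max(t0, a), min(t1, b)
    return max(t1 - t0, 0.0) * np.linalg.norm(d)


class TestSiddon:
    def test_axis_aligned_ray(self):
        g = Grid((5, 3, 3), 4.0)
        idx, ln = siddon_path((-100, 2, 2), (100, 2, 2), g)
        assert len(ln) == 5
        assert np.allclose(ln, 4.0)
        assert list(idx[:, 0]) == [0, 1, 2, 3, 4]

    def test_ray_missing_grid(self):
        g = Grid((5, 5, 5), 4.0)
        idx, ln = siddon_path((-100, 100, 0), (100, 100, 0), g)
        assert len(ln) == 0

    def test_degenerate_ray(self):
        with pytest.raises(ValueError, match="zero-length"):
            siddon_path((1, 1, 1), (1, 1, 1), Grid((5, 5, 5), 4.0))

    def test_chord_conservation_random_rays(self):
        rng = np.random.default_rng(3)
        g = Grid((9, 11, 13), 3.0)
        lo, hi = g.origin, g.origin + g.extent
        p1 = rng.normal(0, 40, (200, 3))
        p2 = rng.normal(0, 40, (200, 3))
        lens = chord_lengths(p1, p2, g)
        for i in range(200):
            _, ln = siddon_path(p1[i], p2[i], g)
            oracle = _clip_length(p1[i], p2[i], lo, hi)
            assert ln.sum() == pytest.approx(oracle, rel=1e-9, abs=1e-9)
            assert lens[i] == pytest.approx(oracle, rel=1e-9, abs=1e-9)
            assert np.all(ln >= 0)


class TestAdjointness:
    def test_nontof_exact(self):
        rng = np.random.default_rng(11)
        g = Grid((10, 11, 12), 4.0)
        p1 = rng.normal(0, 30, (150, 3))
        p2 = rng.normal(0, 30, (150, 3)) + [60, 0, 0]
        x = rng.random(g.shape)
        y = rng.random(150)
        lhs = float(np.dot(forward_project(x, p1, p2, g), y))
        rhs = float(np.sum(x * back_project(y, p1, p2, g)))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_tof_exact(self, tiny_geometry):
        rng = np.random.default_rng(12)
        g = Grid((8, 9, 10), 4.0)
        p1 = rng.normal(0, 25, (100, 3))
        p2 = rng.normal(0, 25, (100, 3)) + [50, 0, 0]
        x = rng.random(g.shape)
        y = rng.random((100, 9))
        f = tof_forward_project(x, p1, p2, g, tiny_geometry, 9)
        lhs = float(np.sum(f * y))
        rhs = float(np.sum(x * tof_back_project(y, p1, p2, g, tiny_geometry)))
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestAttenuation:
    def test_examples(self):
        g = Grid((1, 1, 1), 200.0)
        mu = np.full(g.shape, 0.0096)
        p1, p2 = np.array([[-150, 0, 0.0]]), np.array([[150, 0, 0.0]])
        a511 = attenuation_factors(mu, p1, p2, g, 511)
        a307 = attenuation_factors(mu, p1, p2, g, 307)
        assert a511[0] == pytest.approx(np.exp(-1.92), rel=1e-12)
        assert a307[0] == pytest.approx(np.exp(-ETA_307 * 1.92), rel=1e-12)

    def test_empty_path(self):
        g = Grid((4, 4, 4), 4.0)
        a = attenuation_factors(np.zeros(g.shape), [(100, 100, 0)],
                                [(200, 100, 0)], g, 511)
        assert a[0] == 1.0

    def test_multiplicative_under_path_split(self):
        rng = np.random.default_rng(5)
        g = Grid((10, 10, 10), 5.0)
        mu = rng.random(g.shape) * 0.01
        p1 = np.array([-80.0, 3.0, 7.0])
        p2 = np.array([80.0, -11.0, -3.0])
        mid = 0.5 * (p1 + p2)
        whole = attenuation_factors(mu, [p1], [p2], g, 511)[0]
        half1 = attenuation_factors(mu, [p1], [mid], g, 511)[0]
        half2 = attenuation_factors(mu, [mid], [p2], g, 511)[0]
        assert whole == pytest.approx(half1 * half2, rel=1e-9)

    def test_negative_mu_rejected(self):
        g = Grid((2, 2, 2), 4.0)
        with pytest.raises(ValueError, match="negative"):
            attenuation_factors(np.full(g.shape, -1e-3), [(0, 0, -50)],
                                [(0, 0, 50)], g, 511)


class TestTOFProjection:
    def test_marginalization_matches_nontof(self, tiny_geometry, tiny_grid,
                                            tiny_tof_table):
        tab = tiny_tof_table
        vol = np.full(tiny_grid.shape, 0.01)
        n_tof = tab.spec.tof_bins
        sel = slice(0, 400)
        f = tof_forward_project(vol, tab.end511_a[sel], tab.end511_b[sel],
                                tiny_grid, tiny_geometry, n_tof)
        nf = forward_project(vol, tab.end511_a[sel], tab.end511_b[sel], tiny_grid)
        good = nf > 1e-9
        assert np.max(np.abs(f.sum(1)[good] - nf[good]) / nf[good]) < 1e-3

    def test_point_source_peak_and_shift(self, tiny_geometry):
        g = Grid((61, 1, 1), 4.0)  # 244 mm long strip along x
        p1 = np.array([[-400.0, 0.0, 0.0]])
        p2 = np.array([[400.0, 0.0, 0.0]])
        n_tof = 21
        mid = np.zeros(g.shape)
        mid[30, 0, 0] = 1.0  # at the LOR midpoint
        prof = tof_forward_project(mid, p1, p2, g, tiny_geometry, n_tof)[0]
        assert np.argmax(prof) == n_tof // 2
        # one-bin displacement: dx = c * 273 ps / 2 = 40.92 mm ~ 10 voxels
        shift_vox = int(round(0.5 * C_MM_PER_PS * 273.0 / 4.0))
        shifted = np.zeros(g.shape)
        shifted[30 + shift_vox, 0, 0] = 1.0
        prof2 = tof_forward_project(shifted, p1, p2, g, tiny_geometry, n_tof)[0]
        assert np.argmax(prof2) == n_tof // 2 + 1

    def test_single_wide_bin_equals_nontof(self, tiny_geometry):
        g = Grid((10, 10, 10), 5.0)
        rng = np.random.default_rng(8)
        vol = rng.random(g.shape)
        p1 = np.array([[-100.0, 5.0, 5.0]])
        p2 = np.array([[100.0, -5.0, -5.0]])
        from dataclasses import replace
        wide = replace(tiny_geometry, tof_bin_width_ps=1e6)
        f = tof_forward_project(vol, p1, p2, g, wide, 1)
        nf = forward_project(vol, p1, p2, g)
        assert f[0, 0] == pytest.approx(nf[0], rel=1e-6)


class TestEtaTransform:
    def test_scaling_and_roundtrip(self):
        mu = np.array([0.0096, 0.0, 0.016])
        out = eta_transform(mu)
        assert out[0] == pytest.approx(0.01178496, rel=1e-12)
        assert out[1] == 0.0
        back = eta_transform(out, inverse=True)
        assert np.allclose(back, mu, rtol=1e-15)
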