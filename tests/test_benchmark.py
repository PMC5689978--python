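"""Difference maps, TG43 extraction, DVHs and skin morphology."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brachydeck import benchmark, phantoms, tg43
from brachydeck.grids import DoseGrid
from brachydeck.plan import Structure


def uniform_grid(values):
    return DoseGrid(origin=np.zeros(3), spacing=np.ones(3),
                    values=np.asarray(values, dtype=float))


class TestDiffMap:
    def test_self_comparison_is_zero(self):
        g = uniform_grid(np.full((5, 5, 5), 2.0))
        cmap = benchmark.diff_map(g, g)
        assert np.allclose(cmap.diff[cmap.mask], 0.0)
        assert cmap.summary["fraction_within_2pct"] == 1.0

    def test_two_percent_scaling(self):
        rng = np.random.default_rng(1)
        ref = uniform_grid(rng.uniform(1, 5, (6, 6, 6)))
        test = uniform_grid(1.02 * ref.values)
        cmap = benchmark.diff_map(test, ref)
        assert np.allclose(cmap.diff[cmap.mask], 2.0)

    def test_reference_zero_voxels_excluded(self):
        ref = np.ones((4, 4, 4))
        ref[0] = 0.0
        cmap = benchmark.diff_map(uniform_grid(np.ones((4, 4, 4))),
                                  uniform_grid(ref))
        assert not cmap.mask[0].any()
        assert cmap.mask[1:].all()

    def test_air_and_body_masking(self, small_ct):
        density = np.where(np.asarray(small_ct.hu) == 0, 1.0, 0.0012)
        ref = uniform_grid(np.ones(small_ct.hu.shape))
        ref.origin, ref.spacing = small_ct.origin, small_ct.spacing
        cmap = benchmark.diff_map(ref, ref, density=density)
        assert cmap.mask.sum() == (density >= 0.05).sum()
        # masked fraction equals the in-sphere voxel fraction
        assert cmap.mask.mean() == pytest.approx(
            (np.asarray(small_ct.hu) == 0).mean())

    @given(st.floats(min_value=-40.0, max_value=80.0))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_identity(self, pct):
        ref = uniform_grid(np.full((3, 3, 3), 10.0))
        test = uniform_grid(np.full((3, 3, 3), 10.0 * (1 + pct / 100.0)))
        fwd = benchmark.diff_map(test, ref).diff[1, 1, 1]
        rev = benchmark.diff_map(ref, test).diff[1, 1, 1]
        assert rev == pytest.approx(-100.0 * fwd / (100.0 + fwd), rel=1e-9)

    def test_resampling_congruent_extents(self):
        # same physical extent, double spacing: trilinear resample applies
        fine = DoseGrid(origin=np.zeros(3), spacing=np.ones(3),
                        values=np.ones((9, 9, 9)) * 3.0)
        coarse = DoseGrid(origin=np.zeros(3), spacing=np.full(3, 2.0),
                          values=np.ones((5, 5, 5)) * 3.0)
        cmap = benchmark.diff_map(fine, coarse)
        assert np.allclose(cmap.diff[cmap.mask], 0.0)


class TestDiffHistogram:
    def test_constant_map_occupies_single_bin(self):
        g = uniform_grid(np.ones((4, 4, 4)))
        cmap = benchmark.diff_map(uniform_grid(1.02 * g.values), g)
        edges, counts = benchmark.diff_histogram(cmap, bin_width=0.5)
        assert (counts > 0).sum() == 1

    def test_total_count_equals_mask_size(self):
        rng = np.random.default_rng(2)
        ref = uniform_grid(rng.uniform(1, 2, (7, 7, 7)))
        test = uniform_grid(ref.values * rng.uniform(0.9, 1.1, (7, 7, 7)))
        cmap = benchmark.diff_map(test, ref)
        _, counts = benchmark.diff_histogram(cmap, 0.5)
        assert counts.sum() == cmap.mask.sum()

    def test_mirrored_field_gives_symmetric_histogram(self):
        ref = uniform_grid(np.ones((8, 8, 8)))
        delta = np.linspace(-0.05, 0.05, 8 ** 3).reshape(8, 8, 8)
        test = uniform_grid(1.0 + delta)
        cmap = benchmark.diff_map(test, ref)
        edges, counts = benchmark.diff_histogram(cmap, 1.0)
        assert np.array_equal(counts, counts[::-1])


class TestExtraction:
    def test_point_source_recovers_flat_g(self):
        flat = tg43.TG43SourceData(
            Lambda=1.109, L=0.0, Sk=40000.0,
            g_r=[0.05, 1.0, 20.0], g_values=[1.0, 1.0, 1.0],
            F_r=[0.05, 1.0, 20.0], F_theta=[0.0, 90.0, 180.0],
            F_values=np.ones((3, 3)))
        plan = phantoms.make_single_dwell_plan(center=(0, 0, 0), time=300.0)
        n = 81
        dose = tg43.render_rtdose(plan, flat, origin=-np.ones(3) * 40,
                                  spacing=np.ones(3), shape=(n, n, n))
        from brachydeck.sources import dwell_transform
        pose = dwell_transform(plan.dwells[0], plan.catheters[0])
        g = benchmark.extract_g(dose, pose, 0.0, [0.5, 1.0, 2.0, 3.0])
        assert np.abs(g - 1.0).max() < 0.005

    def test_known_g_recovered_within_half_percent(self, fine_dose,
                                                   source_data):
        dose, pose = fine_dose
        r = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0])
        g = benchmark.extract_g(dose, pose, source_data.L, r)
        assert np.abs(g / source_data.g(r) - 1.0).max() <= 0.005

    def test_g_at_reference_radius_is_one(self, fine_dose, source_data):
        dose, pose = fine_dose
        g = benchmark.extract_g(dose, pose, source_data.L, [1.0])
        assert g[0] == pytest.approx(1.0, abs=1e-12)

    def test_known_F_recovered_within_one_percent(self, fine_dose,
                                                  source_data):
        dose, pose = fine_dose
        theta = np.arange(10.0, 170.1, 5.0)
        for r_cm in (1.0, 2.0):
            F = benchmark.extract_F(dose, pose, source_data.L, r_cm, theta)
            want = source_data.F(r_cm, theta)
            assert np.abs(F / want - 1.0).max() <= 0.01

    def test_F_at_transverse_axis_is_one(self, fine_dose, source_data):
        dose, pose = fine_dose
        F = benchmark.extract_F(dose, pose, source_data.L, 2.0, [90.0])
        assert F[0] == pytest.approx(1.0, abs=1e-12)


class TestDVH:
    def square_structure(self, z, half=10.0):
        return Structure("SQ", [np.array(
            [[-half, -half, z], [half, -half, z], [half, half, z],
             [-half, half, z]])])

    def test_uniform_dose_step_curve(self):
        dose = DoseGrid(origin=np.array([-12.0, -12.0, 0.0]),
                        spacing=np.ones(3),
                        values=np.full((3, 25, 25), 4.0))
        curve = benchmark.compute_dvh(dose, self.square_structure(1.0),
                                      bin_width=0.5)
        v = curve.cumulative_volume
        assert v[0] == 100.0
        assert v[curve.dose_bins <= 4.0][-1] == 100.0
        assert v[curve.dose_bins > 4.0][0] == 0.0

    def test_curve_non_increasing(self, fine_dose, small_ct, single_plan):
        dose, _ = fine_dose
        s = self.square_structure(0.0, half=20.0)
        curve = benchmark.compute_dvh(dose, s, bin_width=0.05)
        assert (np.diff(curve.cumulative_volume) <= 1e-12).all()

    def test_voxel_count_matches_brute_force_rasterization(self):
        # oracle: explicit even-odd point-in-polygon per voxel center
        z = 0.5
        poly = np.array([[-7.3, -5.1, z], [7.9, -5.1, z], [7.9, 6.2, z],
                         [-7.3, 6.2, z]])
        dose = DoseGrid(origin=np.array([-10.0, -10.0, 0.0]),
                        spacing=np.array([1.0, 1.0, 0.5]),
                        values=np.ones((3, 21, 21)))
        curve = benchmark.compute_dvh(dose, Structure("S", [poly]), 0.5)
        x = -10.0 + np.arange(21)
        inside = 0
        for yy in x:
            for xx in x:
                crossings = 0
                n = len(poly)
                for a in range(n):
                    x1, y1 = poly[a][:2]
                    x2, y2 = poly[(a + 1) % n][:2]
                    if (y1 > yy) != (y2 > yy):
                        xi = x1 + (yy - y1) * (x2 - x1) / (y2 - y1)
                        if xi > xx:
                            crossings += 1
                inside += crossings % 2
        assert curve.voxel_count == inside

    def test_sphere_volume_within_one_percent(self, small_ct, single_plan,
                                              small_spec):
        ss = phantoms.make_structures(small_ct, single_plan)
        dose = DoseGrid(origin=small_ct.origin, spacing=small_ct.spacing,
                        values=np.ones(small_ct.hu.shape))
        curve = benchmark.compute_dvh(dose, ss["BODY"], 0.5)
        oracle = int((np.asarray(small_ct.hu) == 0).sum())
        assert curve.voxel_count == pytest.approx(oracle, rel=0.01)

    def test_whole_grid_dvh_reproduces_histogram_integral(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 10, (4, 16, 16))
        dose = DoseGrid(origin=np.array([-8.0, -8.0, 0.0]),
                        spacing=np.ones(3), values=vals)
        big = Structure("ALL", [np.array(
            [[-8.5, -8.5, k], [8.5, -8.5, k], [8.5, 8.5, k], [-8.5, 8.5, k]])
            for k in range(4)])
        curve = benchmark.compute_dvh(dose, big, bin_width=0.01)
        assert curve.voxel_count == vals.size
        # cumulative curve at bin edges equals the survival function
        frac = 100.0 * (vals.ravel()[None, :]
                        >= curve.dose_bins[:, None]).mean(axis=1)
        assert np.allclose(curve.cumulative_volume, frac)


class TestSkin:
    def test_solid_square_gives_two_pixel_ring(self):
        body = np.zeros((1, 14, 14), dtype=bool)
        body[0, 2:12, 2:12] = True
        skin = benchmark.derive_skin(body)
        # oracle: enumerate pixels by city-block distance to the boundary
        expected = np.zeros_like(body)
        for j in range(14):
            for i in range(14):
                in_dil = any(
                    0 <= j + dj < 14 and 0 <= i + di < 14
                    and body[0, j + dj, i + di]
                    for dj, di in [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)])
                in_ero = body[0, j, i] and all(
                    0 <= j + dj < 14 and 0 <= i + di < 14
                    and body[0, j + dj, i + di]
                    for dj, di in [(1, 0), (-1, 0), (0, 1), (0, -1)])
                expected[0, j, i] = in_dil and not in_ero
        assert np.array_equal(skin, expected)
        # ring is two pixels wide along the edge mid-sections
        assert skin[0, :, 7].sum() == 4

    def test_empty_mask_gives_empty_skin(self):
        assert not benchmark.derive_skin(np.zeros((2, 5, 5), bool)).any()

    def test_skin_misses_deep_interior(self, small_ct):
        body = np.asarray(small_ct.hu) == 0
        skin = benchmark.derive_skin(body)
        nz, ny, nx = body.shape
        assert not skin[nz // 2, ny // 2, nx // 2]
        # per-slice morphology: skin forms a shell on every populated slice
        assert skin[nz // 2].any()
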