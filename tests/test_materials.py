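"""Density calibration, truncation, binning and tissue assignment."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brachydeck import materials
from brachydeck.materials import (
    BinningScheme, HUCalibration, TissueTable, assign_tissue, bin_density,
    build_material_model, downsample_inplane, hu_to_density,
    truncate_density,
)

SWEEP = np.arange(0.001, 3.0001, 0.001)


class TestCalibration:
    def test_water_and_air_anchors(self, calibration):
        assert hu_to_density(0, calibration) == pytest.approx(1.00)
        assert hu_to_density(-1000, calibration) == pytest.approx(
            calibration.air_density)

    def test_midway_between_anchors_is_mean(self, calibration):
        # anchors at -1000 and -700
        mid = hu_to_density(-850, calibration)
        assert mid == pytest.approx((calibration.air_density + 0.30) / 2)

    def test_clamps_outside_anchor_range(self, calibration):
        assert hu_to_density(-2000, calibration) == pytest.approx(
            calibration.air_density)
        assert hu_to_density(3071, calibration) == pytest.approx(
            hu_to_density(3000, calibration))


class TestTruncation:
    @pytest.mark.parametrize("value,expected", [
        (1.789, 1.7), (0.0012345, 0.0012), (1.0, 1.0), (0.999, 0.99),
        (2.699, 2.6), (0.05, 0.05),
    ])
    def test_examples(self, value, expected):
        assert truncate_density(value) == pytest.approx(expected)

    @given(st.floats(min_value=1e-4, max_value=3.0))
    @settings(max_examples=200, deadline=None)
    def test_truncation_never_increases_and_is_idempotent(self, d):
        t = truncate_density(d)
        assert t <= d + 1e-12
        assert (d - t) / d < 0.1   # drops < one unit in the second digit
        assert truncate_density(t) == pytest.approx(t, rel=1e-9)


class TestBinning:
    def test_default_scheme_has_54_bins(self, scheme):
        assert scheme.n_bins == 54

    def test_sweep_hits_every_bin(self, scheme):
        out = bin_density(SWEEP, scheme)
        assert len(np.unique(out)) == 54

    def test_representative_maps_to_itself(self, scheme):
        out = bin_density(scheme.representatives, scheme)
        assert np.array_equal(out, scheme.representatives)

    def test_binned_value_within_bin_width(self, scheme):
        out = bin_density(SWEEP, scheme)
        widths = np.diff(scheme.edges)
        idx = np.searchsorted(scheme.edges[1:-1], SWEEP, side="right")
        inside = (SWEEP >= scheme.edges[0]) & (SWEEP <= scheme.edges[-1])
        assert (np.abs(out - SWEEP)[inside] <= widths[idx][inside]).all()

    def test_truncate_then_bin_is_idempotent(self, scheme):
        f = lambda d: bin_density(truncate_density(d), scheme)
        once = f(SWEEP)
        assert np.allclose(f(once), once, rtol=1e-9)

    def test_water_density_binned_to_exactly_one(self, scheme):
        assert bin_density(truncate_density(1.0), scheme) == 1.0


class TestTissueTable:
    def test_default_has_23_rows_and_sweep_hits_all(self, tissue_table):
        assert tissue_table.n_rows == 23
        idx = assign_tissue(SWEEP, tissue_table)
        assert len(np.unique(idx)) == 23

    def test_water_maps_to_soft_tissue(self, tissue_table):
        row = assign_tissue(1.00, tissue_table)
        assert "soft" in tissue_table.names[row]

    def test_boundary_goes_to_range_starting_there(self, tissue_table):
        # half-open [low, high): a boundary density belongs to the row
        # whose range starts at it
        b = tissue_table.lows[5]
        assert assign_tissue(b, tissue_table) == 5
        assert assign_tissue(b - 1e-9, tissue_table) == 4

    def test_fractions_sum_to_one(self, tissue_table):
        assert np.abs(tissue_table.fractions.sum(axis=1) - 1).max() <= 1e-6

    def test_assigned_density_in_row_range(self, scheme, tissue_table):
        d = bin_density(truncate_density(SWEEP), scheme)
        idx = assign_tissue(d, tissue_table)
        lows = tissue_table.lows[idx]
        highs = tissue_table.highs[idx]
        ok = (d >= lows) & ((d < highs) | (idx == tissue_table.n_rows - 1))
        assert ok.all()


class TestDownsample:
    def test_uniform_volume_unchanged(self, calibration):
        from brachydeck.grids import CTVolume
        ct = CTVolume(origin=np.zeros(3), spacing=np.ones(3),
                      hu=np.full((4, 16, 16), 100, dtype=np.int16))
        out = downsample_inplane(ct, 4)
        assert out.hu.shape == (4, 4, 4)
        assert np.allclose(out.hu, 100.0)

    def test_shape_and_spacing_scaling(self, small_ct):
        out = downsample_inplane(small_ct, 4)
        assert out.hu.shape == (32, 8, 8)
        assert np.allclose(out.spacing, small_ct.spacing * [4, 4, 1])

    def test_mean_hu_conserved_under_exact_divisibility(self, small_ct):
        for f in (2, 4, 8):
            out = downsample_inplane(small_ct, f)
            assert out.hu.mean() == pytest.approx(
                np.asarray(small_ct.hu, dtype=float).mean(), abs=1e-9)

    def test_block_sum_bookkeeping(self, small_ct):
        # independent oracle: explicit block summation on one slice
        out = downsample_inplane(small_ct, 2)
        hu = np.asarray(small_ct.hu, dtype=float)
        k, j, i = 16, 3, 5
        block = hu[k, 2 * j:2 * j + 2, 2 * i:2 * i + 2]
        assert out.hu[k, j, i] == pytest.approx(block.mean())

    def test_pad_with_air_when_not_divisible(self):
        from brachydeck.grids import CTVolume
        ct = CTVolume(origin=np.zeros(3), spacing=np.ones(3),
                      hu=np.zeros((2, 6, 6), dtype=np.int16))
        out = downsample_inplane(ct, 4)
        assert out.hu.shape == (2, 2, 2)
        # padded blocks mix water (0) and air (-1000)
        assert out.hu[0, 1, 1] < 0

    def test_invalid_factor_rejected(self, small_ct):
        from brachydeck.errors import InputError
        with pytest.raises(InputError):
            downsample_inplane(small_ct, 3)


class TestMaterialModel:
    def test_binary_phantom_has_two_pairs(self, small_ct, scheme):
        model = build_material_model(small_ct, scheme=scheme)
        assert len(model.pairs()) == 2

    def test_element_count_equals_voxel_count(self, small_ct):
        model = build_material_model(small_ct)
        assert model.n_voxels == int(np.prod(small_ct.hu.shape))

    def test_against_per_voxel_oracle(self, small_ct, calibration, scheme,
                                      tissue_table):
        model = build_material_model(small_ct, calibration, scheme,
                                     tissue_table)
        # brute-force recomputation, voxel by voxel, on a thinned subset
        hu = np.asarray(small_ct.hu)
        for k in range(0, hu.shape[0], 6):
            for j in range(0, hu.shape[1], 5):
                for i in range(0, hu.shape[2], 4):
                    d = float(np.interp(hu[k, j, i], calibration.anchors_hu,
                                        calibration.anchors_density))
                    d = truncate_density(d)
                    b = int(np.clip(np.searchsorted(
                        scheme.edges[1:-1], d, side="right"), 0, 53))
                    d = scheme.representatives[b]
                    row = int(np.searchsorted(tissue_table.highs[:-1], d,
                                              side="right"))
                    assert model.density[k, j, i] == pytest.approx(d)
                    assert model.material_index[k, j, i] == row

    def test_binning_only_moves_density_within_material_range(
            self, small_ct, tissue_table):
        unbinned = build_material_model(small_ct, scheme=None)
        binned = build_material_model(small_ct,
                                      scheme=BinningScheme.default())
        lows = tissue_table.lows[binned.material_index.ravel()]
        highs = tissue_table.highs[binned.material_index.ravel()]
        d = binned.density.ravel()
        last = tissue_table.n_rows - 1
        ok = (d >= lows) & ((d < highs)
                            | (binned.material_index.ravel() == last))
        assert ok.all()
        assert unbinned.density.shape == binned.density.shape

    def test_downsample_then_build_uses_pooled_hu(self, small_ct):
        pooled = downsample_inplane(small_ct, 2)
        model = build_material_model(pooled)
        assert model.shape == pooled.hu.shape
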