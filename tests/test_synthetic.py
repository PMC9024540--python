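import numpy as np
import pytest

from ensemblesdm.raster import RasterStack, GridGeoreference
from ensemblesdm.synthetic import (ClimateSpec, ScenarioShift, VirtualSpecies,
                                   apply_scenario, generate_climate,
                                   sample_occurrences, true_suitability)


def _corr(stack, i, j):
    a, b = stack.data[i].ravel(), stack.data[j].ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


class TestGenerateClimate:
    def test_same_seed_bit_identical(self):
        spec = ClimateSpec(n_layers=3, grid_shape=(40, 40), seed=9,
                           nodata_fraction=0.1)
        a, b = generate_climate(spec), generate_climate(spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_independent_layers_nearly_uncorrelated(self):
        spec = ClimateSpec(n_layers=2, grid_shape=(100, 100), seed=3)
        assert abs(_corr(generate_climate(spec), 0, 1)) < 0.1

    def test_target_pair_correlation_recovered(self):
        C = np.array([[1.0, 0.9], [0.9, 1.0]])
        spec = ClimateSpec(n_layers=2, grid_shape=(200, 200),
                           cross_correlation=C, seed=5)
        assert 0.8 <= _corr(generate_climate(spec), 0, 1) <= 1.0

    def test_non_psd_target_rejected(self):
        C = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        spec = ClimateSpec(n_layers=3, grid_shape=(30, 30), cross_correlation=C)
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_climate(spec)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ClimateSpec(n_layers=2, grid_shape=(5, 50))
        with pytest.raises(ValueError):
            ClimateSpec(n_layers=2, nodata_fraction=1.0)


def _tiny_stack(values):
    """One-row stack from a (n_layers, n_cells) array."""
    data = np.asarray(values, dtype=float)[:, None, :]
    res = 0.1  # keeps even 1000-cell rows inside the lon range
    georef = GridGeoreference(0.0, res, res, -res)
    names = [f"bio{i + 1:02d}" for i in range(data.shape[0])]
    return RasterStack(names, data, georef)


class TestTrueSuitability:
    sp = VirtualSpecies(response_means=(0.0, 1.0), response_widths=(1.0, 2.0),
                        driving_layers=(0, 1))

    def test_cell_at_all_optima_is_one(self):
        stack = _tiny_stack([[0.0, 5.0], [1.0, 1.0], [9.0, 9.0]])
        suit = true_suitability(stack, self.sp)
        assert suit[0, 0] == pytest.approx(1.0)

    def test_three_widths_off_gives_gaussian_kernel_value(self):
        # second cell is 3 widths off on layer 0, at optimum elsewhere;
        # first cell sits at all optima so rescaling is by 1
        stack = _tiny_stack([[0.0, 3.0], [1.0, 1.0], [0.0, 0.0]])
        suit = true_suitability(stack, self.sp)
        assert suit[0, 1] == pytest.approx(np.exp(-4.5))

    def test_non_driving_layer_has_no_effect(self):
        base = _tiny_stack([[0.0, 1.0], [1.0, 2.0], [0.0, 0.0]])
        pert = _tiny_stack([[0.0, 1.0], [1.0, 2.0], [100.0, -7.0]])
        np.testing.assert_allclose(true_suitability(base, self.sp),
                                   true_suitability(pert, self.sp))

    def test_all_nodata_stack_errors(self):
        stack = _tiny_stack([[np.nan, np.nan], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="no valid cells"):
            true_suitability(stack, VirtualSpecies((0.0,), (1.0,), (0,)))

    def test_nodata_propagates(self):
        stack = _tiny_stack([[0.0, np.nan], [1.0, 1.0]])
        suit = true_suitability(stack, self.sp)
        assert np.isnan(suit[0, 1]) and np.isfinite(suit[0, 0])


class TestSampleOccurrences:
    def test_uniform_suitability_distinct_cells(self):
        stack = _tiny_stack([np.ones(20)])
        occ = sample_occurrences(np.ones((1, 20)), stack, 10, seed=0)
        assert len(occ) == 10
        assert len({(lo, la) for lo, la in zip(occ.lons, occ.lats)}) == 10

    def test_single_positive_cell_is_chosen(self):
        suit = np.zeros((1, 5))
        suit[0, 3] = 1.0
        stack = _tiny_stack([np.ones(5)])
        occ = sample_occurrences(suit, stack, 1, seed=0)
        assert occ.lons[0] == pytest.approx(0.35)

    def test_samples_avoid_zero_suitability_half(self):
        suit = np.concatenate([np.ones(500), np.zeros(500)]).reshape(1, 1000)
        stack = _tiny_stack([np.ones(1000)])
        occ = sample_occurrences(suit, stack, 400, seed=1)
        assert np.all(occ.lons < 50.0)  # first 500 cells span lon [0, 50)

    def test_oversampling_errors(self):
        stack = _tiny_stack([np.ones(4)])
        with pytest.raises(ValueError, match="only 4 cells"):
            sample_occurrences(np.ones((1, 4)), stack, 5, seed=0)

    def test_recovery_peaked_species_concentrates_in_top_quantile(self):
        """With a peaked species, sampled presences over-represent the top-p
        suitability quantile by at least a factor of two."""
        spec = ClimateSpec(n_layers=2, grid_shape=(80, 80), seed=11)
        stack = generate_climate(spec)
        sp = VirtualSpecies((0.0,), (0.4,), (0,), prevalence_target=0.1)
        suit = true_suitability(stack, sp)
        occ = sample_occurrences(suit, stack, 300, seed=12)
        p = sp.prevalence_target
        cutoff = np.nanquantile(suit, 1 - p)
        vals = suit[stack.georef.cell_index(occ.lons, occ.lats)]
        assert np.mean(vals >= cutoff) >= 2 * p


class TestApplyScenario:
    def test_identity_shift(self):
        stack = generate_climate(ClimateSpec(n_layers=2, grid_shape=(20, 20), seed=0))
        out = apply_scenario(stack, ScenarioShift((0.0, 0.0)))
        np.testing.assert_array_equal(out.data, stack.data)

    def test_offset_moves_mean_exactly(self):
        stack = generate_climate(ClimateSpec(n_layers=2, grid_shape=(20, 20),
                                             seed=0, nodata_fraction=0.1))
        out = apply_scenario(stack, ScenarioShift((2.0, 0.0)))
        assert np.nanmean(out.data[0]) - np.nanmean(stack.data[0]) == pytest.approx(2.0)
        np.testing.assert_array_equal(out.valid_mask, stack.valid_mask)

    def test_length_mismatch_errors(self):
        stack = generate_climate(ClimateSpec(n_layers=2, grid_shape=(20, 20), seed=0))
        with pytest.raises(ValueError, match="deltas"):
            apply_scenario(stack, ScenarioShift((1.0,)))

    def test_shift_off_optimum_shrinks_true_suitable_area(self):
        stack = generate_climate(ClimateSpec(n_layers=2, grid_shape=(60, 60), seed=2))
        sp = VirtualSpecies((0.0,), (0.5,), (0,))
        before = true_suitability(stack, sp)
        shifted = apply_scenario(stack, ScenarioShift((1.5, 0.0)))
        after = true_suitability(shifted, sp)
        assert np.nansum(after > 0.5) < np.nansum(before > 0.5)

    def test_valid_cell_count_conserved(self, study):
        for scen in study.scenarios.values():
            assert scen.valid_mask.sum() == study.stack.valid_mask.sum()
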