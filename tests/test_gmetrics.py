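"""Geographic-space metrics: thresholding, omission, CBP, partial ROC, ensemble."""

import numpy as np
import pytest
from scipy import stats

import nicheval as nv
from nicheval.gmetrics import DegeneratePredictionError, _partial_auc_ratio


def occ_at_cells(geom, cells, population="other"):
    lons, lats = zip(*[geom.cell_center(r, c) for r, c in cells])
    return nv.OccurrenceSet.from_arrays(lons, lats, [population] * len(cells))


def raster_with(geom, fill, at=()):
    values = np.full(geom.shape, float(fill))
    for (r, c), v in at:
        values[r, c] = v
    return nv.Raster(geom, values)


class TestThresholding:
    def test_zero_tolerance_uses_minimum_training_presence(self, small_grid):
        pred = raster_with(small_grid, 0.05, [((0, 0), 0.2), ((0, 1), 0.4), ((0, 2), 0.6)])
        calib = occ_at_cells(small_grid, [(0, 0), (0, 1), (0, 2)])
        bm = nv.threshold_by_omission(pred, calib, 0.0)
        assert bm.threshold_value == 0.2
        assert all(bm.suitable[c] for c in [(0, 0), (0, 1), (0, 2)])
        assert not bm.suitable[5, 5]  # background below threshold

    def test_five_percent_rule_on_100_values(self):
        """With n=100 sorted calibration values the 5% threshold is the 6th
        smallest, and at most 5 calibration points are omitted (brute force)."""
        geom = nv.GridGeometry(10, 10, 0.5, -75.0, -45.0)
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.linspace(0.01, 1.0, 100)).reshape(10, 10)
        pred = nv.Raster(geom, vals)
        cells = [(r, c) for r in range(10) for c in range(10)]
        calib = occ_at_cells(geom, cells)
        bm = nv.threshold_by_omission(pred, calib, 0.05)
        assert bm.threshold_value == np.sort(vals.ravel())[5]  # 6th smallest
        omitted = sum(1 for c in cells if not bm.suitable[c])
        assert omitted <= 5

    def test_zero_tolerance_gives_exactly_zero_calibration_omission(self, small_grid):
        rng = np.random.default_rng(1)
        pred = nv.Raster(small_grid, rng.random((10, 10)))
        cells = [(r, c) for r in range(0, 10, 2) for c in range(0, 10, 3)]
        calib = occ_at_cells(small_grid, cells)
        bm = nv.threshold_by_omission(pred, calib, 0.0)
        assert nv.omission_rate(bm, calib).omission_rate == 0.0

    def test_threshold_monotonicity_in_tolerance(self, small_grid):
        rng = np.random.default_rng(2)
        pred = nv.Raster(small_grid, rng.random((10, 10)))
        calib = occ_at_cells(small_grid, [(r, r) for r in range(10)])
        counts = [
            nv.threshold_by_omission(pred, calib, tol).suitable.sum()
            for tol in (0.0, 0.1, 0.2, 0.35, 0.5)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_no_usable_calibration_raises(self, small_grid):
        pred = nv.Raster(small_grid, np.ones((10, 10)))
        far = nv.OccurrenceSet.from_arrays([0.0], [0.0])
        with pytest.raises(ValueError):
            nv.threshold_by_omission(pred, far, 0.0)


class TestOmissionRate:
    def _binary(self, geom, suitable_cells):
        suitable = np.zeros(geom.shape, dtype=bool)
        for c in suitable_cells:
            suitable[c] = True
        return nv.BinaryMap(geom, suitable, np.zeros(geom.shape, bool), 0.5, 0.0)

    def test_four_of_seven_missed_rounds_to_057(self, small_grid):
        cells = [(0, i) for i in range(7)]
        bm = self._binary(small_grid, cells[:3])  # 3 hit, 4 missed
        res = nv.omission_rate(bm, occ_at_cells(small_grid, cells))
        assert res.n_omitted == 4 and res.n_test == 7
        assert round(res.omission_rate, 2) == 0.57

    def test_all_suitable_and_all_unsuitable(self, small_grid):
        cells = [(1, 1), (2, 2)]
        assert nv.omission_rate(self._binary(small_grid, cells), occ_at_cells(small_grid, cells)).omission_rate == 0.0
        assert nv.omission_rate(self._binary(small_grid, []), occ_at_cells(small_grid, cells)).omission_rate == 1.0

    def test_counts_partition_exactly(self, small_grid):
        cells = [(r, c) for r in range(5) for c in range(5)]
        bm = self._binary(small_grid, cells[::2])
        res = nv.omission_rate(bm, occ_at_cells(small_grid, cells))
        assert res.n_omitted + round((1 - res.omission_rate) * res.n_test) == res.n_test


class TestProportionSuitable:
    def test_extremes_and_simple_fraction(self, small_grid):
        ones = nv.BinaryMap(small_grid, np.ones((10, 10), bool), np.zeros((10, 10), bool), 0, 0)
        zeros = nv.BinaryMap(small_grid, np.zeros((10, 10), bool), np.zeros((10, 10), bool), 0, 0)
        assert nv.proportion_suitable(ones) == 1.0
        assert nv.proportion_suitable(zeros) == 0.0
        thirty = np.zeros((10, 10), bool)
        thirty.ravel()[:30] = True
        bm = nv.BinaryMap(small_grid, thirty, np.zeros((10, 10), bool), 0, 0)
        assert nv.proportion_suitable(bm) == pytest.approx(0.30)

    def test_region_mask_restricts_counting(self, small_grid):
        suitable = np.zeros((10, 10), bool)
        suitable[:5] = True
        bm = nv.BinaryMap(small_grid, suitable, np.zeros((10, 10), bool), 0, 0)
        region = np.zeros((10, 10), bool)
        region[:5] = True
        assert nv.proportion_suitable(bm, region) == 1.0

    def test_empty_region_raises(self, small_grid):
        bm = nv.BinaryMap(small_grid, np.ones((10, 10), bool), np.zeros((10, 10), bool), 0, 0)
        with pytest.raises(ValueError):
            nv.proportion_suitable(bm, np.zeros((10, 10), bool))


class TestCumulativeBinomial:
    def test_worked_examples(self):
        assert nv.cumulative_binomial(7, 7, 0.5) == pytest.approx(0.0078125, abs=1e-12)
        assert nv.cumulative_binomial(0, 13, 0.2) == 1.0
        assert nv.cumulative_binomial(7, 7, 0.96) == pytest.approx(0.96**7, rel=1e-12)

    @pytest.mark.parametrize(
        "n,k,p", [(10, 3, 0.2), (100, 55, 0.5), (1000, 400, 0.41), (1000, 999, 0.995)]
    )
    def test_matches_brute_force_pmf_sum(self, n, k, p):
        brute = float(sum(stats.binom.pmf(i, n, p) for i in range(k, n + 1)))
        assert nv.cumulative_binomial(k, n, p) == pytest.approx(brute, abs=1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            nv.cumulative_binomial(8, 7, 0.5)
        with pytest.raises(ValueError):
            nv.cumulative_binomial(3, 7, 1.5)


class TestPartialROC:
    def _uniform_setup(self, seed=7, n_points=50):
        geom = nv.GridGeometry(100, 100, 0.05, -75.0, -45.0)
        rng = np.random.default_rng(seed)
        pred = nv.Raster(geom, rng.random((100, 100)))
        rows = rng.integers(0, 100, n_points)
        cols = rng.integers(0, 100, n_points)
        occ = occ_at_cells(geom, list(zip(rows, cols)))
        return pred, occ

    def test_monotone_transform_leaves_ratios_unchanged(self):
        pred, occ = self._uniform_setup()
        r1 = nv.partial_roc(pred, occ, n_replicates=50, seed=3)
        transformed = nv.Raster(pred.geometry, np.exp(3.0 * pred.values))
        r2 = nv.partial_roc(transformed, occ, n_replicates=50, seed=3)
        assert np.allclose(r1.ratios, r2.ratios)  # rank statistic

    def test_ratios_bounded_zero_two(self):
        pred, occ = self._uniform_setup(seed=1)
        res = nv.partial_roc(pred, occ, n_replicates=100, seed=9)
        assert res.ratios.min() >= 0.0 and res.ratios.max() <= 2.0

    def test_perfect_model_ratio_exceeds_1_5(self):
        geom = nv.GridGeometry(100, 100, 0.05, -75.0, -45.0)
        rng = np.random.default_rng(2)
        values = rng.random((100, 100)) * 0.5
        top_cells = [(0, c) for c in range(10)]
        for cell in top_cells:
            values[cell] = 0.9 + 0.01 * cell[1]  # highest values, small area
        pred = nv.Raster(geom, values)
        res = nv.partial_roc(pred, occ_at_cells(geom, top_cells), n_replicates=100, seed=4)
        assert res.mean_ratio > 1.5
        assert res.p_value == 0.0

    def test_constant_prediction_raises(self, small_grid):
        pred = nv.Raster(small_grid, np.ones((10, 10)))
        occ = occ_at_cells(small_grid, [(0, 0), (1, 1)])
        with pytest.raises(DegeneratePredictionError):
            nv.partial_roc(pred, occ)

    def test_invalid_E_raises(self):
        pred, occ = self._uniform_setup()
        with pytest.raises(ValueError):
            nv.partial_roc(pred, occ, E=0.7)

    def test_partial_auc_ratio_closed_form(self):
        # y = 1 everywhere, x on [0, 1]: ratio = (1 - x0) / ((1 - x0^2)/2)
        x = np.linspace(0.0, 1.0, 101)
        y = np.ones_like(x)
        assert _partial_auc_ratio(x, y, 0.05) == pytest.approx(2.0, rel=1e-9)
        # diagonal curve: ratio exactly 1 within the band
        assert _partial_auc_ratio(x, x.copy(), 0.05) == pytest.approx(1.0, rel=1e-9)


class TestEnsemble:
    def _bm(self, geom, suitable):
        return nv.BinaryMap(geom, suitable, np.zeros(geom.shape, bool), 0, 0)

    def test_identical_maps_give_zero_or_k(self, small_grid):
        s = np.zeros((10, 10), bool)
        s[3:6, 3:6] = True
        ens = nv.ensemble_sum([self._bm(small_grid, s)] * 3)
        assert set(np.unique(ens.values)) == {0.0, 3.0}

    def test_complementary_pair_sums_to_one(self, small_grid):
        s = np.zeros((10, 10), bool)
        s[:5] = True
        ens = nv.ensemble_sum([self._bm(small_grid, s), self._bm(small_grid, ~s)])
        assert np.all(ens.values == 1.0)

    def test_bounded_by_number_of_maps(self, small_grid):
        rng = np.random.default_rng(3)
        maps = [self._bm(small_grid, rng.random((10, 10)) > 0.5) for _ in range(5)]
        ens = nv.ensemble_sum(maps)
        assert ens.values.max() <= 5 and ens.values.min() >= 0

    def test_misaligned_maps_raise(self, small_grid):
        other = nv.GridGeometry(10, 10, 0.5, -70.0, -45.0)
        with pytest.raises(nv.AlignmentError):
            nv.ensemble_sum(
                [self._bm(small_grid, np.ones((10, 10), bool)),
                 self._bm(other, np.ones((10, 10), bool))]
            )
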