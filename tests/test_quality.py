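"""Habitat-quality model: decay kernels, degradation, half-saturation score."""

import numpy as np
import pytest

from hqscape import (CLASS_CODES, LandUseRaster, ThreatSpec, decay_factor,
                     default_sensitivity, degradation, grade_hq,
                     habitat_quality, hq_summary, threat_raster)
from hqscape.quality import (DEFAULT_THREATS, HabitatQualityRaster,
                             degradation_bruteforce)

from conftest import random_landuse

CROP = CLASS_CODES["cropland"]
FOREST = CLASS_CODES["forest"]
IMP = CLASS_CODES["impervious"]

CROP_THREAT = ThreatSpec("cropland", frozenset({CROP}), 6.0, 0.7, "linear")
CONSTR_THREAT = ThreatSpec("construction", frozenset({IMP}), 5.0, 1.0,
                           "exponential")


class TestDecay:
    def test_unity_at_source(self):
        assert decay_factor(0.0, CROP_THREAT) == 1.0
        assert decay_factor(0.0, CONSTR_THREAT) == 1.0

    def test_linear_zero_at_max_distance(self):
        assert decay_factor(CROP_THREAT.d_rmax_m, CROP_THREAT) == 0.0

    def test_exponential_value_before_cutoff_and_hard_cutoff(self):
        d = CONSTR_THREAT.d_rmax_m
        assert decay_factor(d - 1e-6, CONSTR_THREAT) == pytest.approx(
            np.exp(-2.99), rel=1e-6)
        assert decay_factor(d, CONSTR_THREAT) == 0.0
        assert decay_factor(2 * d, CONSTR_THREAT) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            decay_factor(-1.0, CROP_THREAT)


class TestThreatRaster:
    def test_absent_class_gives_all_zero(self):
        lu = LandUseRaster(values=np.full((8, 8), FOREST), cell_size=30.0)
        assert threat_raster(lu, CONSTR_THREAT).sum() == 0

    def test_single_source_cell(self):
        vals = np.full((8, 8), FOREST)
        vals[2, 3] = CROP
        lu = LandUseRaster(values=vals, cell_size=30.0)
        r = threat_raster(lu, CROP_THREAT)
        assert r.sum() == 1 and r[2, 3] == 1

    def test_count_matches_class_histogram(self):
        lu = random_landuse(21)
        assert threat_raster(lu, CROP_THREAT).sum() == (lu.values == CROP).sum()


class TestDegradation:
    def test_hand_worked_adjacent_forest_cell(self, sens):
        """Forest cell 30 m from the only cropland cell, sole linear threat:
        D = (1 - 30/6000) * 0.7 = 0.6965."""
        vals = np.full((9, 9), FOREST)
        vals[4, 4] = CROP
        lu = LandUseRaster(values=vals, cell_size=30.0)
        D = degradation(lu, [CROP_THREAT], sens).values
        assert D[4, 5] == pytest.approx(0.6965, abs=1e-12)

    def test_far_cell_has_zero_degradation(self, sens):
        spec = ThreatSpec("cropland", frozenset({CROP}), 0.06, 0.7, "linear")
        vals = np.full((16, 16), FOREST)
        vals[0, 0] = CROP
        lu = LandUseRaster(values=vals, cell_size=30.0)
        D = degradation(lu, [spec], sens).values
        assert D[10, 10] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_kernel_equals_allpairs_oracle(self, seed, sens):
        threats = [
            ThreatSpec("cropland", frozenset({CROP}), 0.3, 0.7, "linear"),
            ThreatSpec("construction", frozenset({IMP}), 0.24, 1.0,
                       "exponential"),
        ]
        lu = random_landuse(seed, shape=(32, 32))
        D = degradation(lu, threats, sens).values
        oracle = degradation_bruteforce(lu, threats, sens)
        assert np.abs(D - oracle).max() < 1e-9

    def test_adding_a_threat_cell_never_decreases_D(self, sens):
        lu = random_landuse(33)
        D0 = degradation(lu, list(DEFAULT_THREATS), sens).values
        vals = lu.values.copy()
        forest_cells = np.argwhere(vals == FOREST)
        vals[tuple(forest_cells[0])] = CROP
        lu2 = LandUseRaster(values=vals, cell_size=30.0)
        D1 = degradation(lu2, list(DEFAULT_THREATS), sens).values
        changed = tuple(forest_cells[0])
        same_class = lu.values == lu2.values
        assert (D1[same_class] >= D0[same_class] - 1e-12).all()
        Q0 = habitat_quality(lu, degradation(lu, list(DEFAULT_THREATS), sens),
                             sens, k=1.0)
        Q1 = habitat_quality(lu2, degradation(lu2, list(DEFAULT_THREATS), sens),
                             sens, k=1.0)
        assert (Q1.values[same_class] <= Q0.values[same_class] + 1e-12).all()

    def test_scale_consistency_under_grid_refinement(self, sens):
        """With area-weighted sources, halving the cell size on the same
        physical landscape changes interior D by < 2%."""
        rng = np.random.default_rng(3)
        coarse = rng.integers(1, 8, (32, 32))
        fine = np.kron(coarse, np.ones((2, 2), int))
        luc = LandUseRaster(values=coarse, cell_size=60.0)
        luf = LandUseRaster(values=fine, cell_size=30.0)
        threats = [
            ThreatSpec("cropland", frozenset({CROP}), 0.72, 0.7, "linear"),
            ThreatSpec("construction", frozenset({IMP}), 0.61, 1.0,
                       "exponential"),
        ]
        Dc = degradation(luc, threats, sens, area_weight=True).values
        Df = degradation(luf, threats, sens, area_weight=True).values
        Df_agg = Df.reshape(32, 2, 32, 2).mean(axis=(1, 3))
        inner = (slice(12, 20), slice(12, 20))
        nonzero = Df_agg[inner] > 0  # insensitive classes have D = 0 at both scales
        rel = (np.abs(Dc[inner] - Df_agg[inner])[nonzero]
               / Df_agg[inner][nonzero])
        assert rel.max() < 0.02


class TestHabitatQuality:
    def test_zero_degradation_forest_scores_one(self, sens):
        lu = LandUseRaster(values=np.full((8, 8), FOREST), cell_size=30.0)
        D = degradation(lu, list(DEFAULT_THREATS), sens)
        Q = habitat_quality(lu, D, sens)
        assert (Q.values == 1.0).all()
        assert Q.k_half_saturation == 0.0

    def test_half_saturation_identity(self, sens):
        """Cells with D = k score exactly H_j / 2."""
        lu = random_landuse(40)
        D = degradation(lu, list(DEFAULT_THREATS), sens)
        k = 0.5 * D.values[D.mask].max()
        D.values[3, 3] = k          # force one cell exactly to k
        lu.values[3, 3] = FOREST
        Q = habitat_quality(lu, D, sens, k=k)
        assert Q.values[3, 3] == pytest.approx(0.5, abs=1e-12)

    def test_construction_cells_score_zero(self, sens):
        lu = random_landuse(41)
        D = degradation(lu, list(DEFAULT_THREATS), sens)
        Q = habitat_quality(lu, D, sens)
        assert (Q.values[lu.values == IMP] == 0.0).all()

    def test_Q_bounded_by_suitability(self, sens):
        lu = random_landuse(42)
        D = degradation(lu, list(DEFAULT_THREATS), sens)
        Q = habitat_quality(lu, D, sens)
        H = np.vectorize(sens.H)(lu.values)
        assert (Q.values >= 0).all() and (Q.values <= H + 1e-12).all()

    def test_z_must_be_positive(self, sens):
        lu = random_landuse(43)
        D = degradation(lu, list(DEFAULT_THREATS), sens)
        with pytest.raises(ValueError, match="z"):
            habitat_quality(lu, D, sens, z=0.0)


class TestGradingAndSummary:
    def _hq(self, values):
        return HabitatQualityRaster(values=np.asarray(values, float),
                                    cell_size=30.0, nodata=-9999.0,
                                    mask=np.ones(np.shape(values), bool))

    def test_constant_one_is_all_high(self):
        g = grade_hq(self._hq(np.ones((5, 5))))
        assert g.set_index("grade").loc["high", "proportion"] == 1.0

    def test_boundary_quarter_counts_as_medium(self):
        g = grade_hq(self._hq([[0.25]]))
        assert g.set_index("grade").loc["medium", "proportion"] == 1.0

    def test_proportions_sum_to_one_and_match_histogram(self):
        rng = np.random.default_rng(5)
        q = rng.random((30, 30))
        g = grade_hq(self._hq(q))
        assert g["proportion"].sum() == pytest.approx(1.0, abs=1e-9)
        hist = np.histogram(q, bins=[0, 0.25, 0.5, 0.75, 1.0 + 1e-12])[0]
        np.testing.assert_array_equal(
            (g["proportion"] * q.size).round().astype(int), hist)

    def test_summary_closed_forms(self):
        assert hq_summary(self._hq(np.full((4, 4), 0.3))) == (
            pytest.approx(0.3), pytest.approx(0.0))
        mean, sd = hq_summary(self._hq([[0.0, 1.0]]))
        assert (mean, sd) == (pytest.approx(0.5), pytest.approx(0.5))

    def test_summary_matches_independent_recomputation(self):
        rng = np.random.default_rng(6)
        q = rng.random((12, 12))
        mean, sd = hq_summary(self._hq(q))
        assert mean == pytest.approx(float(np.mean(q)))
        assert sd == pytest.approx(float(np.std(q)))
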