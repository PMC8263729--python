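"""Degradation / quality model: closed forms, oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from habscape.habitat import (
    DegradationSurface,
    compute_degradation,
    compute_quality,
    decay_factor,
    grade_quality,
    threat_density,
    threat_presence,
)
from habscape.landuse import CLASS_CODES
from habscape.params import ThreatSpec
from habscape.raster import Raster

from conftest import dense_degradation_oracle, quadruple_loop_degradation

CROP = CLASS_CODES["cropland"]
FOREST = CLASS_CODES["forestland"]
CITY = CLASS_CODES["city_town"]


class TestDecayFactor:
    @pytest.mark.parametrize(
        "d, dmax, kind, expected",
        [
            (0.0, 9.0, "exponential", 1.0),
            (5.0, 5.0, "linear", 0.0),
            (9.0, 9.0, "exponential", math.exp(-2.99)),
            (9.0001, 9.0, "exponential", 0.0),
            (6.0, 5.0, "linear", 0.0),
            (2.5, 5.0, "linear", 0.5),
        ],
    )
    def test_closed_forms(self, d, dmax, kind, expected):
        assert decay_factor(d, dmax, kind) == pytest.approx(expected, abs=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            decay_factor(-1.0, 5.0, "linear")

    @given(
        d=st.floats(0, 20),
        d2=st.floats(0, 20),
        dmax=st.floats(0.1, 15),
        kind=st.sampled_from(["linear", "exponential"]),
    )
    def test_bounded_and_monotone(self, d, d2, dmax, kind):
        lo, hi = sorted([d, d2])
        f_lo, f_hi = decay_factor(lo, dmax, kind), decay_factor(hi, dmax, kind)
        assert 0.0 <= f_hi <= f_lo <= 1.0


class TestThreatPresence:
    def make_spec(self, codes=(CROP,), d=5.0, decay="exponential"):
        return ThreatSpec("cropland", tuple(codes), d, 0.5, decay)

    def test_all_and_none(self):
        spec = self.make_spec()
        all_crop = Raster(np.full((4, 4), CROP, np.int16), 500.0)
        no_crop = Raster(np.full((4, 4), FOREST, np.int16), 500.0)
        assert threat_presence(all_crop, spec).sum() == 16
        assert threat_presence(no_crop, spec).sum() == 0

    def test_checkerboard_half(self):
        data = np.where(np.indices((8, 8)).sum(0) % 2 == 0, CROP, FOREST)
        grid = Raster(data.astype(np.int16), 500.0)
        assert threat_presence(grid, self.make_spec()).sum() == 32

    def test_unknown_code_warns(self):
        grid = Raster(np.full((2, 2), 99, np.int16), 500.0)
        with pytest.warns(UserWarning, match="unknown codes"):
            pres = threat_presence(grid, self.make_spec())
        assert pres.sum() == 0


class TestThreatDensity:
    spec = ThreatSpec("cropland", (CROP,), 5.0, 0.5, "linear")

    def test_all_sources_density_one_including_edges(self):
        pres = np.ones((16, 16))
        dens = threat_density(pres, self.spec, 500.0)
        np.testing.assert_allclose(dens, 1.0, atol=1e-9)

    def test_no_sources_density_zero(self):
        dens = threat_density(np.zeros((16, 16)), self.spec, 500.0)
        np.testing.assert_allclose(dens, 0.0, atol=1e-9)

    def test_single_source_matches_brute_force(self):
        """One source cell: density at any x is decay(d)/sum over kernel."""
        pres = np.zeros((21, 21))
        pres[10, 10] = 1.0
        cell = 500.0
        dens = threat_density(pres, self.spec, cell)
        # brute force at a probe half the max distance away (5 cells = 2.5 km)
        probe = (10, 15)
        num = den = 0.0
        for i in range(21):
            for j in range(21):
                d = math.hypot(probe[0] - i, probe[1] - j) * cell / 1000.0
                if d > self.spec.d_rmax_km:
                    continue
                f = decay_factor(d, self.spec.d_rmax_km, self.spec.decay)
                den += f
                if pres[i, j]:
                    num += f
        assert dens[probe] == pytest.approx(num / den, abs=1e-10)
        assert num / den == pytest.approx(0.5 / den, abs=1e-12)


class TestComputeDegradation:
    def test_no_threat_cells_zero(self, sens):
        grid = Raster(np.full((8, 8), FOREST, np.int16), 500.0)
        spec = ThreatSpec("cropland", (CROP,), 5.0, 0.5, "exponential")
        deg = compute_degradation(grid, [spec], sens)
        np.testing.assert_allclose(deg.raster.data, 0.0, atol=1e-12)

    def test_single_threat_full_density(self, sens):
        """Forest sensitivity 0.9 to city/town, density 1 => D = 0.9."""
        data = np.full((20, 20), CITY, np.int16)
        data[10, 10] = FOREST
        grid = Raster(data, 100.0)
        spec = ThreatSpec("city_town", (CITY,), 9.0, 1.0, "exponential")
        deg = compute_degradation(grid, [spec], sens)
        # density at the forest cell is (sum - self)/sum, very close to 1
        d_forest = deg.raster.data[10, 10]
        assert d_forest == pytest.approx(0.9, abs=0.01)

    def test_equal_weight_split(self, sens):
        """Two threats of equal weight, one at density ~1 and one at 0:
        D = 0.5 * S_threat1."""
        data = np.full((20, 20), CITY, np.int16)
        data[10, 10] = FOREST
        grid = Raster(data, 100.0)
        present = ThreatSpec("city_town", (CITY,), 9.0, 0.7, "exponential")
        absent = ThreatSpec("unused_land", (CLASS_CODES["unused_land"],), 9.0, 0.7, "linear")
        deg = compute_degradation(grid, [present, absent], sens)
        assert deg.raster.data[10, 10] == pytest.approx(0.5 * 0.9, abs=0.01)

    def test_weight_scale_invariance(self, sens, threats, make_landscape):
        grid = make_landscape((12, 12), seed=3)
        d1 = compute_degradation(grid, threats, sens).raster.data
        # scale all weights by 0.5 (stays within [0, 1])
        halved = [
            ThreatSpec(t.name, t.source_codes, t.d_rmax_km, t.weight * 0.5, t.decay)
            for t in threats
        ]
        d2 = compute_degradation(grid, halved, sens).raster.data
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_matches_dense_distance_oracle(self, sens, threats, make_landscape):
        grid = make_landscape((16, 16), cell_size=500.0, seed=8)
        ours = compute_degradation(grid, threats, sens).raster.data
        oracle = dense_degradation_oracle(grid, threats, sens)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_matches_quadruple_loop_on_tiny_grid(self, sens, threats, make_landscape):
        grid = make_landscape((6, 6), cell_size=500.0, seed=4)
        ours = compute_degradation(grid, threats, sens).raster.data
        oracle = quadruple_loop_degradation(grid, threats, sens)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_bounded_in_unit_interval(self, sens, threats, make_landscape):
        for seed in range(5):
            grid = make_landscape((16, 16), seed=seed)
            D = compute_degradation(grid, threats, sens).raster.data
            assert D.min() >= 0.0 and D.max() <= 1.0

    def test_accessibility_scales_exposure(self, sens, threats, make_landscape):
        grid = make_landscape((10, 10), seed=2)
        beta = grid.with_data(np.full(grid.shape, 0.5))
        d_full = compute_degradation(grid, threats, sens).raster.data
        d_half = compute_degradation(grid, threats, sens, accessibility=beta).raster.data
        np.testing.assert_allclose(d_half, 0.5 * d_full, atol=1e-12)

    def test_all_zero_weights_rejected(self, sens):
        grid = Raster(np.full((4, 4), CROP, np.int16), 500.0)
        spec = ThreatSpec("cropland", (CROP,), 5.0, 0.0, "linear")
        with pytest.raises(ValueError, match="weights"):
            compute_degradation(grid, [spec], sens)


class TestComputeQuality:
    def test_zero_degradation_gives_suitability(self, sens):
        grid = Raster(np.full((4, 4), FOREST, np.int16), 500.0)
        deg = grid.with_data(np.zeros(grid.shape))
        q = compute_quality(deg, sens, grid, k=0.5)
        np.testing.assert_allclose(q.raster.data, 1.0)  # forest H = 1.0

    def test_half_saturation_point(self, sens):
        grid = Raster(np.full((4, 4), FOREST, np.int16), 500.0)
        k = 0.37
        deg = grid.with_data(np.full(grid.shape, k))
        q = compute_quality(deg, sens, grid, k=k)
        np.testing.assert_allclose(q.raster.data, 0.5, atol=1e-12)

    def test_closed_form_h1_d1_k_half(self, sens):
        grid = Raster(np.full((2, 2), FOREST, np.int16), 500.0)
        deg = grid.with_data(np.ones(grid.shape))
        q = compute_quality(deg, sens, grid, k=0.5)
        np.testing.assert_allclose(q.raster.data, 0.2, atol=1e-12)

    def test_limits_in_k(self, sens, threats, make_landscape):
        grid = make_landscape((12, 12), seed=1)
        deg = compute_degradation(grid, threats, sens)
        h = np.array(
            [[sens.suitability(int(c)) for c in row] for row in grid.data]
        )
        q_big = compute_quality(deg, sens, grid, k=1e9).raster.data
        np.testing.assert_allclose(q_big, h, atol=1e-12)
        q_small = compute_quality(deg, sens, grid, k=1e-12).raster.data
        degraded = deg.raster.data > 1e-6
        np.testing.assert_allclose(q_small[degraded], 0.0, atol=1e-9)

    def test_invalid_k_rejected(self, sens, make_landscape):
        grid = make_landscape((4, 4))
        deg = grid.with_data(np.zeros(grid.shape))
        with pytest.raises(ValueError, match="k must be positive"):
            compute_quality(deg, sens, grid, k=0.0)


class TestMonotonicity:
    def test_adding_threat_never_decreases_d_never_increases_q(self, sens, threats):
        rng = np.random.default_rng(0)
        for trial in range(20):
            data = rng.choice([CROP, FOREST, CLASS_CODES["water"]], size=(12, 12))
            grid = Raster(data.astype(np.int16), 500.0)
            deg0 = compute_degradation(grid, threats, sens)
            q0 = compute_quality(deg0, sens, grid).raster.data
            non_threat = ~np.isin(grid.data, [CROP, CITY])
            cells = np.argwhere(non_threat)
            r, c = cells[rng.integers(len(cells))]
            data2 = grid.data.copy()
            data2[r, c] = CITY
            grid2 = grid.with_data(data2)
            deg1 = compute_degradation(grid2, threats, sens)
            # compare on cells whose own class did not change
            same = grid.data == grid2.data
            q1 = compute_quality(deg1, sens, grid2).raster.data
            assert (deg1.raster.data[same] >= deg0.raster.data[same] - 1e-12).all()
            assert (q1[same] <= q0[same] + 1e-12).all()


class TestGradeQuality:
    @pytest.mark.parametrize(
        "q, grade",
        [(0.1, 1), (0.2, 2), (0.5, 3), (0.85, 5), (1.0, 5), (0.0, 1), (0.6, 4)],
    )
    def test_thresholds(self, q, grade):
        r = Raster(np.full((2, 2), q), 500.0)
        assert (grade_quality(r).data == grade).all()

    def test_out_of_range_rejected(self):
        r = Raster(np.full((2, 2), 1.5), 500.0)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            grade_quality(r)

    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4))
    def test_partition_every_q_in_exactly_one_grade(self, vals):
        r = Raster(np.array(vals).reshape(2, 2), 500.0)
        g = grade_quality(r).data
        assert ((g >= 1) & (g <= 5)).all()
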