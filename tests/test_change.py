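"""Transition matrices, expansion sources, HQCI/CI and grade bookkeeping."""

import math

import numpy as np
import pandas as pd
import pytest

from habscape import reference_values as ref
from habscape.change import (
    expansion_sources,
    grade_change_table,
    hqci_ci,
    mean_quality,
    transition_matrix,
    transition_report,
)
from habscape.landuse import CLASS_CODES, CONSTRUCTION_CODES
from habscape.raster import Raster
from habscape.synthetic import LandscapeConfig, generate_landscape, grow_urban

CROP = CLASS_CODES["cropland"]
FOREST = CLASS_CODES["forestland"]
CITY = CLASS_CODES["city_town"]


def _r(data, cell=1000.0, nodata=None):
    return Raster(np.asarray(data), cell_size=cell, nodata=nodata)


class TestTransitionMatrix:
    def test_identical_grids_diagonal_only(self):
        g = _r(np.array([[CROP, FOREST], [CITY, CROP]], np.int16))
        m = transition_matrix(g, g)
        off = m.counts.to_numpy().sum() - np.diag(
            m.counts.reindex(index=m.counts.columns).fillna(0).to_numpy()
        ).sum()
        assert off == 0

    def test_single_cell_conversion_area(self):
        a = np.full((10, 10), CROP, np.int16)
        b = a.copy()
        b[0, 0] = CITY
        m = transition_matrix(_r(a, cell=30.0), _r(b, cell=30.0))
        assert m.areas.loc[CROP, CITY] == pytest.approx(9e-4)
        assert m.counts.loc[CROP, CITY] == 1

    def test_total_area_conserved(self):
        cfg = LandscapeConfig(grid_height=64, grid_width=64, seed=1, cell_size=250.0)
        l1 = generate_landscape(cfg)
        l2 = grow_urban(l1, 0.15, seed=2)
        m = transition_matrix(l1, l2)
        assert m.total_area_km2 == pytest.approx(64 * 64 * 0.0625)

    def test_growth_moves_mass_only_into_construction(self):
        cfg = LandscapeConfig(grid_height=64, grid_width=64, seed=3, cell_size=250.0)
        l1 = generate_landscape(cfg)
        l2 = grow_urban(l1, 0.1, seed=4)
        m = transition_matrix(l1, l2)
        for to_code in m.counts.columns:
            if to_code in CONSTRUCTION_CODES:
                continue
            col = m.counts[to_code]
            off_diag = col.sum() - col.get(to_code, 0)
            assert off_diag == 0

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            transition_matrix(_r(np.zeros((2, 2))), _r(np.zeros((3, 3))))


class TestExpansionSources:
    def test_no_new_construction_all_nodata(self):
        g = _r(np.full((4, 4), FOREST, np.int16))
        out = expansion_sources(g, g)
        assert (out.data == 0).all()

    def test_single_conversion_labelled_by_source(self):
        a = np.full((4, 4), CROP, np.int16)
        b = a.copy()
        b[2, 2] = CITY
        out = expansion_sources(_r(a), _r(b))
        assert out.data[2, 2] == CROP
        assert (out.data != 0).sum() == 1

    def test_counts_match_transition_matrix(self):
        cfg = LandscapeConfig(grid_height=48, grid_width=48, seed=5, cell_size=250.0)
        l1 = generate_landscape(cfg)
        l2 = grow_urban(l1, 0.2, seed=6)
        out = expansion_sources(l1, l2)
        m = transition_matrix(l1, l2)
        con_cols = [c for c in m.counts.columns if c in CONSTRUCTION_CODES]
        for code in m.counts.index:
            if code in CONSTRUCTION_CODES:
                continue
            expected = m.counts.loc[code, con_cols].sum()
            assert (out.data == code).sum() == expected


class TestHqciCi:
    def test_unchanged_quality_zero(self):
        l1 = _r(np.full((3, 3), CROP, np.int16))
        l2 = _r(np.full((3, 3), CITY, np.int16))
        q = _r(np.full((3, 3), 0.4))
        imp = hqci_ci(q, q, l1, l2, CROP, CITY)
        assert imp.hqci == 0.0 and imp.ci == 0.0
        assert imp.n == 9

    def test_hand_computed_example(self):
        """3 transition cells with dQ = (-0.3, -0.2, -0.1) on 1 km^2 cells."""
        l1 = np.full((2, 2), FOREST, np.int16)
        l2 = l1.copy()
        l2[0, 0] = l2[0, 1] = l2[1, 0] = CITY
        q1 = np.array([[0.9, 0.8], [0.7, 0.9]])
        q2 = np.array([[0.6, 0.6], [0.6, 0.9]])
        imp = hqci_ci(_r(q1), _r(q2), _r(l1), _r(l2), FOREST, CITY)
        assert imp.n == 3
        assert imp.hqci == pytest.approx(-0.2, abs=1e-12)
        assert imp.s_km2 == pytest.approx(3.0)
        assert imp.ci == pytest.approx(-0.6, abs=1e-12)

    def test_empty_transition_reported_as_nan(self):
        g = _r(np.full((2, 2), FOREST, np.int16))
        q = _r(np.full((2, 2), 0.9))
        imp = hqci_ci(q, q, g, g, CROP, CITY)
        assert imp.n == 0 and imp.s_km2 == 0.0
        assert math.isnan(imp.hqci) and math.isnan(imp.ci)

    def test_ci_equals_hqci_times_area(self):
        cfg = LandscapeConfig(grid_height=32, grid_width=32, seed=9, cell_size=500.0)
        l1 = generate_landscape(cfg)
        l2 = grow_urban(l1, 0.3, seed=1)
        rng = np.random.default_rng(0)
        q1 = l1.with_data(rng.uniform(0, 1, l1.shape))
        q2 = l1.with_data(rng.uniform(0, 1, l1.shape))
        imp = hqci_ci(q1, q2, l1, l2, CROP, CONSTRUCTION_CODES)
        assert imp.ci == pytest.approx(imp.hqci * imp.s_km2, rel=1e-9)


class TestReferenceConsistency:
    def test_all_published_impact_rows_consistent(self):
        out = ref.check_impact_consistency()
        assert len(out) == 6
        assert out["consistent"].all()

    def test_grade_area_changes_telescope_within_rounding(self):
        t = ref.grade_area_change_table()
        subs = t.loc[["1990-2000", "2000-2010", "2010-2018"]].sum()
        full = t.loc["1990-2018"]
        assert (subs - full).abs().max() <= 0.02


class TestGradeChangeTable:
    def _q(self, vals, cell=1000.0):
        return _r(np.asarray(vals, dtype=float), cell=cell)

    def test_identical_surfaces_zero_deltas(self):
        q = self._q(np.linspace(0, 1, 16).reshape(4, 4))
        shares, deltas = grade_change_table({0: q, 1: q})
        assert np.allclose(deltas.to_numpy(), 0.0)

    def test_shares_sum_to_100(self):
        rng = np.random.default_rng(1)
        surfaces = {e: self._q(rng.uniform(0, 1, (8, 8))) for e in range(3)}
        shares, _ = grade_change_table(surfaces)
        np.testing.assert_allclose(shares.sum(axis=1), 100.0, atol=0.1)

    def test_subperiod_deltas_telescope_exactly(self):
        rng = np.random.default_rng(2)
        surfaces = {e: self._q(rng.uniform(0, 1, (10, 10))) for e in range(4)}
        _, deltas = grade_change_table(surfaces)
        subs = deltas.iloc[:-1].sum()
        full = deltas.iloc[-1]
        np.testing.assert_allclose(subs.to_numpy(), full.to_numpy(), atol=1e-12)

    def test_needs_two_epochs(self):
        with pytest.raises(ValueError, match="two epochs"):
            grade_change_table({0: self._q(np.zeros((2, 2)))})


class TestMeanQuality:
    def test_constant_surface(self):
        assert mean_quality(_r(np.full((5, 5), 0.37))) == pytest.approx(0.37)

    def test_half_zero_half_one(self):
        data = np.zeros((4, 4))
        data[:2] = 1.0
        assert mean_quality(_r(data)) == pytest.approx(0.5)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(0, 1, (32, 32))
        r = _r(data)
        # streaming two-pass mean
        total = 0.0
        for v in data.ravel():
            total += v
        assert mean_quality(r) == pytest.approx(total / data.size, abs=1e-12)

    def test_nodata_excluded_and_empty_rejected(self):
        data = np.array([[0.5, -9999.0], [0.5, 0.5]])
        r = _r(data, nodata=-9999.0)
        assert mean_quality(r) == pytest.approx(0.5)
        empty = _r(np.full((2, 2), -9999.0), nodata=-9999.0)
        with pytest.raises(ValueError, match="no valid cells"):
            mean_quality(empty)


def test_transition_report_rounding_consistency():
    """The reporting path reproduces printed-table arithmetic: CI/S rounds to
    HQCI at two decimals for every row it emits."""
    cfg = LandscapeConfig(grid_height=64, grid_width=64, seed=13, cell_size=500.0)
    l1 = generate_landscape(cfg)
    l2 = grow_urban(l1, 0.25, seed=14)
    rng = np.random.default_rng(5)
    q1 = l1.with_data(rng.uniform(0.3, 1.0, l1.shape))
    q2 = l1.with_data(q1.data * rng.uniform(0.4, 1.0, l1.shape))
    report = transition_report(q1, q2, l1, l2, CONSTRUCTION_CODES, round_decimals=None)
    assert not report.empty
    np.testing.assert_allclose(
        report["CI"], report["HQCI"] * report["S_km2"], rtol=1e-9
    )
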