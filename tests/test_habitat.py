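import itertools

import numpy as np
import pytest

from scenariosdm.habitat import (
    Centroid,
    ClassifiedMap,
    area_report,
    centroid_displacement,
    change_analysis,
    jenks_breaks,
    jenks_classify,
    lucc_profile,
    mean_center,
    report_from_areas,
)
from scenariosdm.stack import GridGeometry, OccurrenceSet

from . import reference_tables as ref
from .conftest import make_stack


def _brute_force_ssd(values, k):
    v = np.sort(np.asarray(values, dtype=float))
    best = np.inf
    for cuts in itertools.combinations(range(1, len(v)), k - 1):
        parts = np.split(v, cuts)
        ssd = sum(((p - p.mean()) ** 2).sum() for p in parts)
        best = min(best, ssd)
    return best


def _ssd_of_breaks(values, breaks):
    v = np.sort(np.asarray(values, dtype=float))
    cls = np.digitize(v, breaks, right=True)
    return sum(((v[cls == c] - v[cls == c].mean()) ** 2).sum() for c in np.unique(cls))


class TestJenks:
    def test_two_obvious_clusters(self):
        (b,) = jenks_breaks([1, 2, 3, 10, 11, 12], 2)
        assert 3 <= b < 10

    def test_k_equals_distinct_values(self):
        breaks = jenks_breaks([1.0, 2.0, 3.0, 4.0], 4)
        assert breaks == (1.0, 2.0, 3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random(30) * 10
        breaks = jenks_breaks(values, 4)
        assert _ssd_of_breaks(values, breaks) == pytest.approx(
            _brute_force_ssd(values, 4), abs=1e-9
        )

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            jenks_breaks([1.0, 1.0, 2.0], 4)

    def test_classification_order_preserving(self, tiny_geometry):
        rng = np.random.default_rng(1)
        grid = rng.random((5, 5))
        cmap = jenks_classify(grid, tiny_geometry)
        flat_s = grid.ravel()
        flat_c = cmap.classes.ravel()
        order = np.argsort(flat_s)
        assert np.all(np.diff(flat_c[order]) >= 0)


class TestAreaReport:
    def test_all_unsuitable_grid(self):
        geom = GridGeometry(10, 10, 1.0, (100.0, 30.0))
        cmap = ClassifiedMap(np.zeros((10, 10), dtype=int), (0.2, 0.5, 0.8), geom)
        rep = area_report(cmap)
        assert rep.class_areas["unsuitable"] == pytest.approx(0.01)
        assert rep.proportions["unsuitable"] == pytest.approx(100.0)

    def test_four_equal_classes(self):
        geom = GridGeometry(10, 10, 1.0, (100.0, 30.0))
        classes = np.repeat(np.arange(4), 25).reshape(10, 10)
        rep = area_report(ClassifiedMap(classes, (0.2, 0.5, 0.8), geom))
        assert all(p == pytest.approx(25.0) for p in rep.proportions.values())

    def test_area_conservation(self, tiny_geometry):
        rng = np.random.default_rng(0)
        cmap = jenks_classify(rng.random((5, 5)), tiny_geometry)
        rep = area_report(cmap)
        assert sum(rep.class_areas.values()) == pytest.approx(rep.study_area)
        assert sum(rep.proportions.values()) == pytest.approx(100.0)

    def test_published_scenario1_total(self):
        rep = report_from_areas(ref.AREAS_SCENARIO1)
        assert rep.total_suitable == pytest.approx(184.24)


class TestChangeAnalysis:
    def test_identical_reports_zero_delta(self):
        rep = report_from_areas(ref.AREAS_SCENARIO1)
        ch = change_analysis(rep, rep)
        assert ch.total_delta == 0.0
        assert ch.pct_change == 0.0

    def test_disturbance_reduction(self):
        ch = change_analysis(
            report_from_areas(ref.AREAS_SCENARIO1), report_from_areas(ref.AREAS_SCENARIO2)
        )
        assert ch.total_delta == pytest.approx(-44.13, abs=5e-3)
        assert ch.pct_change == pytest.approx(-23.95, abs=5e-3)

    def test_future_expansion(self):
        ch = change_analysis(
            report_from_areas(ref.AREAS_SCENARIO2), report_from_areas(ref.AREAS_SSP585_2090)
        )
        assert ch.total_delta == pytest.approx(27.04, abs=5e-3)
        assert ch.pct_change == pytest.approx(19.30, abs=5e-3)

    def test_mismatched_study_areas_rejected(self):
        a = report_from_areas({"unsuitable": 50.0, "highly": 50.0})
        b = report_from_areas({"unsuitable": 10.0, "highly": 50.0})
        with pytest.raises(ValueError, match="differ"):
            change_analysis(a, b)


class TestCentroid:
    def test_single_cell(self, tiny_geometry):
        classes = np.zeros((5, 5), dtype=int)
        classes[2, 3] = 3
        c = mean_center(ClassifiedMap(classes, (0.2, 0.5, 0.8), tiny_geometry))
        lon, lat = tiny_geometry.cell_center(2, 3)
        assert (c.lon, c.lat) == pytest.approx((lon, lat))

    def test_symmetric_block(self, tiny_geometry):
        classes = np.zeros((5, 5), dtype=int)
        classes[1:4, 1:4] = 2
        c = mean_center(ClassifiedMap(classes, (0.2, 0.5, 0.8), tiny_geometry))
        lon, lat = tiny_geometry.cell_center(2, 2)
        assert (c.lon, c.lat) == pytest.approx((lon, lat))

    def test_l_shape_matches_enumeration(self, tiny_geometry):
        cells = [(0, 0), (1, 0), (2, 0), (2, 1), (2, 2)]
        classes = np.zeros((5, 5), dtype=int)
        for r, c in cells:
            classes[r, c] = 1
        got = mean_center(ClassifiedMap(classes, (0.2, 0.5, 0.8), tiny_geometry))
        lons, lats = zip(*(tiny_geometry.cell_center(r, c) for r, c in cells))
        assert got.lon == pytest.approx(np.mean(lons))
        assert got.lat == pytest.approx(np.mean(lats))

    def test_no_member_cells_raises(self, tiny_geometry):
        with pytest.raises(ValueError):
            mean_center(ClassifiedMap(np.zeros((5, 5), dtype=int), (0.2, 0.5, 0.8), tiny_geometry))

    def test_zero_displacement(self):
        assert centroid_displacement(Centroid(100.0, 30.0), Centroid(100.0, 30.0)) == (0.0, 0.0)

    def test_one_degree_latitude(self):
        d, b = centroid_displacement(Centroid(100.0, 30.0), Centroid(100.0, 31.0))
        assert d == pytest.approx(111.195, abs=0.05)
        assert b == pytest.approx(0.0)

    def test_due_east_at_equator(self):
        _, b = centroid_displacement(Centroid(10.0, 0.0), Centroid(11.0, 0.0))
        assert b == pytest.approx(90.0)


class TestLuccProfile:
    @staticmethod
    def _stack_with_lucc(lucc):
        stack = make_stack({"x": np.zeros(lucc.shape, dtype=float)})
        stack.add_layer("lucc", lucc, meta="human", categorical=True)
        stack.class_table = {1: "woodland", 2: "urban"}
        return stack

    def test_all_points_one_class(self):
        stack = self._stack_with_lucc(np.ones((4, 4), dtype=int))
        pts = [stack.geometry.cell_center(r, c) for r, c in [(0, 0), (1, 2), (3, 3)]]
        occ = OccurrenceSet(*map(np.array, zip(*pts)))
        prof = lucc_profile(occ, stack)
        assert prof.iloc[0]["class"] == "woodland"
        assert prof.iloc[0]["percentage"] == pytest.approx(100.0)

    def test_three_one_split(self):
        lucc = np.ones((4, 4), dtype=int)
        lucc[0, 0] = 2
        stack = self._stack_with_lucc(lucc)
        pts = [stack.geometry.cell_center(r, c) for r, c in [(0, 0), (1, 1), (2, 2), (3, 3)]]
        occ = OccurrenceSet(*map(np.array, zip(*pts)))
        prof = lucc_profile(occ, stack).set_index("class")
        assert prof.loc["woodland", "percentage"] == pytest.approx(75.0)
        assert prof.loc["urban", "percentage"] == pytest.approx(25.0)

    def test_outside_point_flagged(self):
        stack = self._stack_with_lucc(np.ones((4, 4), dtype=int))
        occ = OccurrenceSet(np.array([0.0]), np.array([0.0]))
        prof = lucc_profile(occ, stack)
        assert prof.iloc[0]["class"] == "outside"
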