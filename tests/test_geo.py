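import numpy as np
import pytest

from nicheshift import GridSpec, cell_area_km2, classify
from nicheshift.geo import (
    CLASS_NAMES,
    AreaReport,
    ClassifiedRaster,
    area_ratio,
    bearing_direction,
    centroid,
    centroid_shift,
    class_areas,
    displacement,
)


def grid_of(values: np.ndarray, cell=0.1, lon0=80.0, lat0=45.0) -> GridSpec:
    return GridSpec(n_rows=values.shape[0], n_cols=values.shape[1],
                    cell_size=cell, origin_lon=lon0, origin_lat=lat0)


class TestClassify:
    @pytest.mark.parametrize(
        "value, name",
        [
            (0.0, "unsuitable"),
            (0.04, "unsuitable"),
            (0.05, "poorly"),
            (0.32, "poorly"),
            (0.33, "moderately"),
            (0.65, "moderately"),
            (0.66, "highly"),
            (1.0, "highly"),
        ],
    )
    def test_threshold_boundaries(self, value, name):
        arr = np.array([[value]])
        cls = classify(arr, grid_of(arr))
        assert CLASS_NAMES[cls.classes[0, 0]] == name

    def test_partition_tiles_unit_interval(self):
        """Every probability lands in exactly one class: no gaps, no overlaps."""
        sweep = np.linspace(0, 1, 10_001)[None, :]
        cls = classify(sweep, grid_of(np.zeros((1, 10_001)), cell=0.001, lat0=5.0))
        assert cls.classes.min() == 0 and cls.classes.max() == 3
        # class codes are non-decreasing along the sweep: intervals are contiguous
        assert (np.diff(cls.classes[0]) >= 0).all()

    def test_nan_becomes_nodata(self):
        arr = np.array([[0.5, np.nan]])
        cls = classify(arr, grid_of(arr))
        assert cls.classes[0, 1] == -1

    def test_out_of_range_rejected(self):
        arr = np.array([[1.5]])
        with pytest.raises(ValueError):
            classify(arr, grid_of(arr))


class TestCellArea:
    def test_global_sum_is_earth_surface(self):
        lats = np.arange(-89.5, 90, 1.0)
        total = cell_area_km2(lats, 1.0).sum() * 360
        assert total == pytest.approx(5.1006e8, rel=1e-3)

    def test_cosine_latitude_scaling(self):
        ratio = cell_area_km2(60.0, 0.01) / cell_area_km2(0.0, 0.01)
        assert ratio == pytest.approx(np.cos(np.radians(60)), rel=1e-2)

    def test_zero_cell_size(self):
        assert cell_area_km2(45.0, 0.0) == 0.0

    def test_pole_overflow_rejected(self):
        with pytest.raises(ValueError):
            cell_area_km2(89.9, 0.5)


class TestClassAreas:
    def test_single_class_takes_all(self):
        arr = np.full((4, 4), 0.9)
        rep = class_areas(classify(arr, grid_of(arr)))
        assert rep.highly_suitable_km2 == pytest.approx(rep.total_km2)
        assert rep.area_km2["poorly"] == 0.0

    def test_conservation(self):
        rng = np.random.default_rng(0)
        arr = rng.random((30, 30))
        rep = class_areas(classify(arr, grid_of(arr)))
        total = cell_area_km2(
            grid_of(arr).lat_centers, 0.1
        ).sum() * 30
        assert rep.total_km2 == pytest.approx(total, rel=1e-9)

    def test_checkerboard_symmetric_about_equator(self):
        # equator-symmetric grid: the two interleaved classes cover equal area
        n = 10
        arr = np.indices((n, n)).sum(axis=0) % 2 * 0.9 + 0.01
        grid = GridSpec(n_rows=n, n_cols=n, cell_size=1.0, origin_lon=0.0, origin_lat=5.0)
        rep = class_areas(classify(arr, grid))
        assert rep.area_km2["unsuitable"] == pytest.approx(rep.area_km2["highly"], rel=1e-9)


class TestAreaRatio:
    def test_forecast_to_current_ratios(self):
        current = AreaReport("current", {"unsuitable": 0.0, "poorly": 0.0,
                                         "moderately": 0.0, "highly": 1_091_466.0})
        up = AreaReport("2050s", {"unsuitable": 0.0, "poorly": 0.0,
                                  "moderately": 0.0, "highly": 1_457_640.0})
        down = AreaReport("2070s", {"unsuitable": 0.0, "poorly": 0.0,
                                    "moderately": 0.0, "highly": 1_216_426.0})
        assert round(area_ratio(up, current, "highly"), 2) == 1.34
        assert round(area_ratio(down, current, "highly"), 2) == 1.11

    def test_equal_areas_ratio_one(self):
        rep = AreaReport("x", {"unsuitable": 0, "poorly": 0, "moderately": 0, "highly": 5.0})
        assert round(area_ratio(rep, rep, "highly"), 2) == 1.00

    def test_zero_current_rejected(self):
        empty = AreaReport("x", {c: 0.0 for c in CLASS_NAMES})
        with pytest.raises(ZeroDivisionError):
            area_ratio(empty, empty, "highly")


class TestCentroid:
    def _raster(self, codes, cell=1.0, lat0=2.0):
        codes = np.asarray(codes)
        grid = GridSpec(n_rows=codes.shape[0], n_cols=codes.shape[1],
                        cell_size=cell, origin_lon=0.0, origin_lat=lat0)
        return ClassifiedRaster(grid=grid, classes=codes)

    def test_single_cell(self):
        cr = self._raster([[3]])
        assert centroid(cr, "highly") == pytest.approx((0.5, 1.5))

    def test_two_equal_cells_midpoint(self):
        cr = self._raster([[3, 0, 3]], lat0=0.5)  # centers at lon 0.5 and 2.5, lat 0
        x, y = centroid(cr, "highly")
        assert x == pytest.approx(1.5) and y == pytest.approx(0.0)

    def test_area_weighted_latitude(self):
        # two cells at lat 0.5 and 59.5: weighted mean uses spherical areas
        grid = GridSpec(n_rows=60, n_cols=1, cell_size=1.0, origin_lon=0.0, origin_lat=60.0)
        codes = np.zeros((60, 1), dtype=int)
        codes[0, 0] = 3   # lat 59.5
        codes[59, 0] = 3  # lat 0.5
        cr = ClassifiedRaster(grid=grid, classes=codes)
        a_hi = cell_area_km2(59.5, 1.0)
        a_lo = cell_area_km2(0.5, 1.0)
        expected = (59.5 * a_hi + 0.5 * a_lo) / (a_hi + a_lo)
        assert centroid(cr, "highly")[1] == pytest.approx(expected)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            centroid(self._raster([[0]]), "highly")


class TestDisplacementAndBearing:
    def test_identical_centroids(self):
        assert displacement((10.0, 20.0), (10.0, 20.0)) == 0.0

    def test_three_four_five(self):
        # at the equator: 3 km east, 4 km north
        c1 = (0.0, 0.0)
        c2 = (3.0 / 111.320, 4.0 / 110.574)
        assert displacement(c1, c2) == pytest.approx(5.0, rel=1e-6)

    def test_one_degree_north(self):
        assert displacement((100.0, 40.0), (100.0, 41.0)) == pytest.approx(110.574)

    @pytest.mark.parametrize(
        "theta, label",
        [
            (7.20, "Northeast"),
            (42.84, "Northeast"),
            (156.31, "Northwest"),
            (204.74, "Southwest"),
            (300.0, "Southeast"),
        ],
    )
    def test_quadrant_labels(self, theta, label):
        c1 = (50.0, 0.0)
        c2 = (50.0 + np.cos(np.radians(theta)) / 111.320,
              np.sin(np.radians(theta)) / 110.574)
        got_theta, got_label = bearing_direction(c1, c2)
        assert got_theta == pytest.approx(theta, abs=1e-6)
        assert got_label == label

    @pytest.mark.parametrize(
        "theta, label", [(0.0, "East"), (90.0, "North"), (180.0, "West"), (270.0, "South")]
    )
    def test_cardinal_boundaries(self, theta, label):
        dx, dy = np.cos(np.radians(theta)), np.sin(np.radians(theta))
        c2 = (50.0 + round(dx) / 111.320, round(dy) / 110.574)
        assert bearing_direction((50.0, 0.0), c2)[1] == label

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError):
            bearing_direction((10.0, 20.0), (10.0, 20.0))

    def test_label_sign_consistency(self, rng):
        for _ in range(50):
            dx, dy = rng.normal(size=2)
            c2 = (50.0 + dx, 10.0 + dy)
            theta, label = bearing_direction((50.0, 10.0), c2)
            northward = label in {"Northeast", "Northwest", "North"}
            assert northward == (dy > 0 and label not in {"East", "West"})

    def test_centroid_shift_summary(self):
        grid = GridSpec(n_rows=10, n_cols=10, cell_size=0.5, origin_lon=0.0, origin_lat=45.0)
        a = np.zeros((10, 10), dtype=int)
        b = np.zeros((10, 10), dtype=int)
        a[6, 4] = 3
        b[2, 4] = 3  # 4 cells = 2 degrees due north
        s = centroid_shift(ClassifiedRaster(grid, a), ClassifiedRaster(grid, b), "highly")
        assert s.direction == "North"
        assert s.distance_km == pytest.approx(2 * 110.574, rel=1e-6)
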