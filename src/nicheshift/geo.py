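"""Suitability classification, latitude-corrected areas and range-shift metrics.

Suitability maps are cut into four classes at occurrence-probability
thresholds 0.05 / 0.33 / 0.66 (unsuitable, poorly, moderately, highly
suitable). Class areas are true spherical areas per cell, so high-latitude
cells count less. Range shifts between periods are summarized by the
area-weighted centroid of a class set, the displacement distance D (km) and
the displacement bearing theta measured counter-clockwise from due east,
mapped to a compass quadrant: theta in (0, 90) northeast, (90, 180)
northwest, (180, 270) southwest, (270, 360) southeast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridSpec

__all__ = [
    "CLASS_NAMES",
    "CLASS_THRESHOLDS",
    "ClassifiedRaster",
    "AreaReport",
    "CentroidShift",
    "classify",
    "cell_area_km2",
    "class_areas",
    "area_ratio",
    "centroid",
    "displacement",
    "bearing_direction",
    "centroid_shift",
]

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320

CLASS_NAMES = ("unsuitable", "poorly", "moderately", "highly")
CLASS_THRESHOLDS = (0.05, 0.33, 0.66)
NODATA_CLASS = -1
#: classes counted as the "total suitable" region (probability >= 0.05)
SUITABLE_CLASSES = frozenset({"poorly", "moderately", "highly"})


@dataclass
class ClassifiedRaster:
    """Per-cell suitability class codes: 0..3 valid, -1 nodata."""

    grid: GridSpec
    classes: np.ndarray  # int array (n_rows, n_cols)

    def class_mask(self, class_set) -> np.ndarray:
        if isinstance(class_set, str):
            class_set = {class_set}
        codes = [CLASS_NAMES.index(c) for c in class_set]
        return np.isin(self.classes, codes)


def classify(suitability: np.ndarray, grid: GridSpec) -> ClassifiedRaster:
    """Cut a probability raster into the four suitability classes.

    Intervals are left-closed: [0, 0.05) unsuitable, [0.05, 0.33) poorly,
    [0.33, 0.66) moderately, [0.66, 1] highly. NaN cells become nodata.
    """
    s = np.asarray(suitability, dtype=float)
    valid = np.isfinite(s)
    if ((s[valid] < 0) | (s[valid] > 1)).any():
        raise ValueError("suitability values outside [0, 1]")
    out = np.full(s.shape, NODATA_CLASS, dtype=int)
    out[valid] = np.digitize(s[valid], CLASS_THRESHOLDS, right=False)
    return ClassifiedRaster(grid=grid, classes=out)


def cell_area_km2(lat_center, cell_size: float):
    """Spherical area of a grid cell centered at ``lat_center`` degrees.

    R^2 * d_lambda * (sin(phi_top) - sin(phi_bottom)), R = 6371.0088 km.
    """
    lat = np.asarray(lat_center, dtype=float)
    half = cell_size / 2.0
    if np.any(np.abs(lat) + half > 90.0 + 1e-12):
        raise ValueError("cell extends beyond the poles")
    top = np.radians(lat + half)
    bot = np.radians(lat - half)
    return EARTH_RADIUS_KM**2 * np.radians(cell_size) * (np.sin(top) - np.sin(bot))


def _area_raster(grid: GridSpec) -> np.ndarray:
    col = cell_area_km2(grid.lat_centers, grid.cell_size)
    return np.repeat(col[:, None], grid.n_cols, axis=1)


@dataclass
class AreaReport:
    """Per-class spherical areas (km^2) for one scenario."""

    scenario: str
    area_km2: dict[str, float]

    @property
    def total_suitable_km2(self) -> float:
        return sum(self.area_km2[c] for c in SUITABLE_CLASSES)

    @property
    def highly_suitable_km2(self) -> float:
        return self.area_km2["highly"]

    @property
    def total_km2(self) -> float:
        return sum(self.area_km2.values())

    def rounded(self) -> dict[str, int]:
        """Integer-km^2 rendering used in summary tables."""
        return {c: int(round(a)) for c, a in self.area_km2.items()}


def class_areas(classified: ClassifiedRaster, scenario: str = "") -> AreaReport:
    """Sum spherical cell areas per suitability class."""
    areas = _area_raster(classified.grid)
    if not (classified.classes >= 0).any():
        raise ValueError("classified raster has no valid cells")
    report = {}
    for code, name in enumerate(CLASS_NAMES):
        report[name] = float(areas[classified.classes == code].sum())
    return AreaReport(scenario=scenario, area_km2=report)


def area_ratio(future: AreaReport, current: AreaReport, class_name: str = "highly") -> float:
    """Future / current area for one class (summaries print it at 2 dp)."""
    if class_name == "total_suitable":
        cur, fut = current.total_suitable_km2, future.total_suitable_km2
    else:
        cur, fut = current.area_km2[class_name], future.area_km2[class_name]
    if cur <= 0:
        raise ZeroDivisionError(f"current {class_name} area is zero")
    return fut / cur


def centroid(classified: ClassifiedRaster, class_set) -> tuple[float, float]:
    """Area-weighted mean (lon, lat) of all cells in ``class_set``.

    x = sum(S_i X_i) / S, y = sum(S_i Y_i) / S with S_i the spherical cell
    area and (X_i, Y_i) the cell-center coordinates.
    """
    mask = classified.class_mask(class_set)
    if not mask.any():
        raise ValueError(f"no cells in class set {class_set!r}")
    areas = _area_raster(classified.grid)[mask]
    r, c = np.nonzero(mask)
    lon, lat = classified.grid.cell_center(r, c)
    s = areas.sum()
    return float((areas * lon).sum() / s), float((areas * lat).sum() / s)


def displacement(c1: tuple[float, float], c2: tuple[float, float]) -> float:
    """Distance in km between two centroids, equirectangular about the mean latitude."""
    dx, dy = _dxdy_km(c1, c2)
    return float(np.hypot(dx, dy))


def _dxdy_km(c1, c2) -> tuple[float, float]:
    lon1, lat1 = c1
    lon2, lat2 = c2
    mean_lat = np.radians((lat1 + lat2) / 2.0)
    dx = (lon2 - lon1) * np.cos(mean_lat) * KM_PER_DEG_LON_EQ
    dy = (lat2 - lat1) * KM_PER_DEG_LAT
    return float(dx), float(dy)


def bearing_direction(c1: tuple[float, float], c2: tuple[float, float]) -> tuple[float, str]:
    """Displacement angle in [0, 360) from due east (counter-clockwise) and its quadrant label.

    Exact multiples of 90 degrees get cardinal labels (East/North/West/South).
    Raises on zero displacement, where the direction is undefined.
    """
    dx, dy = _dxdy_km(c1, c2)
    if dx == 0.0 and dy == 0.0:
        raise ValueError("zero displacement: direction undefined")
    theta = float(np.degrees(np.arctan2(dy, dx)) % 360.0)
    if theta == 0.0:
        return theta, "East"
    if theta == 90.0:
        return theta, "North"
    if theta == 180.0:
        return theta, "West"
    if theta == 270.0:
        return theta, "South"
    label = ("Northeast", "Northwest", "Southwest", "Southeast")[int(theta // 90)]
    return theta, label


@dataclass
class CentroidShift:
    """Centroid movement of a class set between two periods or scenarios."""

    from_scenario: str
    to_scenario: str
    class_set: str
    x_t: float
    y_t: float
    x_t1: float
    y_t1: float
    distance_km: float
    theta_deg: float | None
    direction: str | None


def centroid_shift(
    classified_from: ClassifiedRaster,
    classified_to: ClassifiedRaster,
    class_set,
    from_scenario: str = "current",
    to_scenario: str = "future",
) -> CentroidShift:
    """Full shift summary (centroids, D, theta, compass label) for one class set."""
    c1 = centroid(classified_from, class_set)
    c2 = centroid(classified_to, class_set)
    d = displacement(c1, c2)
    if d == 0.0:
        theta, label = None, None
    else:
        theta, label = bearing_direction(c1, c2)
    name = class_set if isinstance(class_set, str) else "+".join(sorted(class_set))
    return CentroidShift(
        from_scenario=from_scenario,
        to_scenario=to_scenario,
        class_set=name,
        x_t=c1[0], y_t=c1[1], x_t1=c2[0], y_t1=c2[1],
        distance_km=d, theta_deg=theta, direction=label,
    )
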