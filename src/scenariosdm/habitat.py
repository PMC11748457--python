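"""Habitat grading, area accounting, centroids and land-use profiles.

Suitability surfaces are cut into four grades (unsuitable, poorly,
moderately, highly) with Jenks natural breaks — the exact Fisher dynamic
program minimizing total within-class sum of squared deviations on the
sorted value sample. Areas are reported in units of 10^4 km^2; centroids
are unweighted mean centers of suitable-cell coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import haversine_km, initial_bearing_deg
from .stack import EnvStack, GridGeometry, OccurrenceSet

CLASS_NAMES = {0: "unsuitable", 1: "poorly", 2: "moderately", 3: "highly"}
NAME_CODES = {v: k for k, v in CLASS_NAMES.items()}
NODATA_CLASS = -1

#: exact-DP size cap; larger samples are thinned to every k-th sorted value
JENKS_MAX_EXACT = 10_000


def jenks_breaks(values, n_classes: int) -> tuple[float, ...]:
    """Exact Fisher-Jenks break values (upper class bounds, ascending).

    Minimizes the total within-class sum of squared deviations over all
    partitions of the sorted sample into ``n_classes`` contiguous runs.
    Returns ``n_classes - 1`` break values; a value classifies into class c
    iff it is <= break c and > break c-1.
    """
    v = np.sort(np.asarray(values, dtype=float))
    v = v[np.isfinite(v)]
    n = len(v)
    if len(np.unique(v)) < n_classes:
        raise ValueError(f"need at least {n_classes} distinct values")
    if n > JENKS_MAX_EXACT:
        step = int(np.ceil(n / JENKS_MAX_EXACT))
        v = v[::step]
        n = len(v)
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def seg_cost(i, j):
        # SSD of v[i..j] inclusive; i may be an array
        cnt = j - i + 1
        tot = s1[j + 1] - s1[i]
        return (s2[j + 1] - s2[i]) - tot * tot / cnt

    idx = np.arange(n)
    dp = seg_cost(0, idx)  # one class covering v[0..j]
    back = np.zeros((n_classes, n), dtype=int)
    for c in range(1, n_classes):
        new = np.empty(n)
        new[:c] = np.inf
        for j in range(c, n):
            m = np.arange(c - 1, j)  # last index of previous class
            costs = dp[m] + seg_cost(m + 1, j)
            best = int(np.argmin(costs))
            new[j] = costs[best]
            back[c, j] = m[best]
        dp = new
    # recover class boundaries
    bounds = []
    j = n - 1
    for c in range(n_classes - 1, 0, -1):
        j = back[c, j]
        bounds.append(v[j])
    return tuple(sorted(bounds))


@dataclass
class ClassifiedMap:
    """Four-grade habitat map with the break values that produced it."""

    classes: np.ndarray  # int grid; NODATA_CLASS outside the valid area
    breaks: tuple[float, ...]
    geometry: GridGeometry
    scenario: str = ""
    period: str = ""

    def __post_init__(self):
        if list(self.breaks) != sorted(set(self.breaks)):
            raise ValueError("breaks must be strictly ascending")

    def suitable_mask(self, classes=(1, 2, 3)) -> np.ndarray:
        return np.isin(self.classes, list(classes))

    def class_counts(self) -> dict[int, int]:
        return {
            c: int(np.sum(self.classes == c)) for c in range(len(self.breaks) + 1)
        }


def jenks_classify(
    suitability: np.ndarray,
    geometry: GridGeometry,
    n_classes: int = 4,
    breaks: tuple[float, ...] | None = None,
    scenario: str = "",
    period: str = "",
) -> ClassifiedMap:
    """Classify a suitability grid into ``n_classes`` Jenks grades.

    Pass ``breaks`` to reuse break values computed on another map (shared
    breaks across periods); by default breaks are computed per map.
    """
    suitability = np.asarray(suitability, dtype=float)
    valid = np.isfinite(suitability)
    if breaks is None:
        breaks = jenks_breaks(suitability[valid], n_classes)
    classes = np.digitize(suitability, breaks, right=True)
    classes = np.where(valid, classes, NODATA_CLASS).astype(int)
    return ClassifiedMap(classes, tuple(breaks), geometry, scenario=scenario, period=period)


@dataclass
class AreaReport:
    """Per-grade habitat areas in 10^4 km^2 and shares of the study area."""

    class_areas: dict[str, float]  # name -> 1e4 km^2
    proportions: dict[str, float] = field(default_factory=dict)  # name -> %
    scenario: str = ""
    period: str = ""

    @property
    def total_suitable(self) -> float:
        return sum(v for k, v in self.class_areas.items() if k != "unsuitable")

    @property
    def study_area(self) -> float | None:
        if "unsuitable" not in self.class_areas:
            return None
        return sum(self.class_areas.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"suitable_areas": k, "area_1e4_km2": v, "proportion_pct": self.proportions.get(k)}
            for k, v in self.class_areas.items()
        ]
        return pd.DataFrame(rows)


def area_report(
    cmap: ClassifiedMap, cell_area_km2: float | None = None, scenario: str = "", period: str = ""
) -> AreaReport:
    """Account per-grade areas of a classified map.

    ``cell_area_km2`` defaults to the grid's constant cell area (no
    latitude-dependent correction).
    """
    if cell_area_km2 is None:
        cell_area_km2 = cmap.geometry.cell_area_km2
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    counts = cmap.class_counts()
    n_valid = sum(counts.values())
    areas = {CLASS_NAMES.get(c, str(c)): cnt * cell_area_km2 / 1e4 for c, cnt in counts.items()}
    props = {
        CLASS_NAMES.get(c, str(c)): (100.0 * cnt / n_valid if n_valid else 0.0)
        for c, cnt in counts.items()
    }
    return AreaReport(class_areas=areas, proportions=props, scenario=scenario, period=period)


def report_from_areas(class_areas: dict[str, float], scenario: str = "", period: str = "") -> AreaReport:
    """Build an AreaReport directly from per-grade areas (10^4 km^2),
    e.g. when re-analyzing published area tables."""
    total = sum(class_areas.values())
    props = {k: 100.0 * v / total for k, v in class_areas.items()} if total else {}
    return AreaReport(class_areas=dict(class_areas), proportions=props, scenario=scenario, period=period)


@dataclass
class ChangeReport:
    """Signed differences b - a between two area reports.

    ``pct_change`` is the percentage change of total suitable area relative
    to report ``a`` (negative = reduction).
    """

    per_class_delta: dict[str, float]
    total_delta: float
    pct_change: float
    label: str = ""


def change_analysis(a: AreaReport, b: AreaReport, label: str = "") -> ChangeReport:
    """Per-grade and total suitable-area change from report a to report b."""
    if a.study_area is not None and b.study_area is not None:
        if abs(a.study_area - b.study_area) > 1e-6 * max(a.study_area, 1.0):
            raise ValueError(
                f"study areas differ: {a.study_area:.4f} vs {b.study_area:.4f} (x1e4 km^2)"
            )
    keys = sorted(set(a.class_areas) | set(b.class_areas))
    deltas = {k: b.class_areas.get(k, 0.0) - a.class_areas.get(k, 0.0) for k in keys}
    total_delta = b.total_suitable - a.total_suitable
    pct = 100.0 * total_delta / a.total_suitable if a.total_suitable else float("nan")
    return ChangeReport(per_class_delta=deltas, total_delta=total_delta, pct_change=pct, label=label)


@dataclass(frozen=True)
class Centroid:
    """Mean center of suitable habitat."""

    lon: float
    lat: float


def mean_center(cmap: ClassifiedMap, classes=(1, 2, 3), weights: np.ndarray | None = None) -> Centroid:
    """Unweighted arithmetic mean of suitable cell-center coordinates.

    ``weights`` (e.g. a suitability surface) switches to a weighted mean.
    """
    member = cmap.suitable_mask(classes)
    if not member.any():
        raise ValueError("no cell belongs to the requested classes")
    lons, lats = cmap.geometry.lonlat_grids()
    if weights is None:
        return Centroid(float(lons[member].mean()), float(lats[member].mean()))
    w = np.asarray(weights, dtype=float)[member]
    if w.sum() <= 0:
        raise ValueError("weights sum to zero over member cells")
    return Centroid(
        float(np.average(lons[member], weights=w)), float(np.average(lats[member], weights=w))
    )


def centroid_displacement(c1: Centroid, c2: Centroid) -> tuple[float, float]:
    """(distance km, initial bearing deg clockwise from north) from c1 to c2."""
    d = float(haversine_km(c1.lon, c1.lat, c2.lon, c2.lat))
    if d == 0.0:
        return 0.0, 0.0
    return d, float(initial_bearing_deg(c1.lon, c1.lat, c2.lon, c2.lat))


def lucc_profile(occ: OccurrenceSet, stack: EnvStack, lucc_var: str = "lucc") -> pd.DataFrame:
    """Tabulate the land-use class of the cell containing each occurrence.

    Points outside the grid extent are counted under an ``outside`` bucket.
    Returns a DataFrame with columns class, count, percentage (of all points).
    """
    grid = stack.categorical_layers[lucc_var]
    counts: dict[str, int] = {}
    for lon, lat in zip(occ.lons, occ.lats):
        cell = stack.geometry.cell_of(lon, lat)
        if cell is None:
            key = "outside"
        else:
            code = int(grid[cell])
            key = stack.class_table.get(code, str(code))
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    rows = [
        {"class": k, "count": c, "percentage": 100.0 * c / total}
        for k, c in sorted(counts.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(rows)
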