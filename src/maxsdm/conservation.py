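"""Priority-area delineation, protected-area gap analysis, and
range-centroid tracking.

Priority conservation areas are cells where at least ``min_species``
species are moderately or highly suitable (class >= 2).  Gap analysis
overlays them with the protected-area mask and reports the unprotected
percentage.  Range centroids are area-weighted means of suitable cell
centers; shifts between consecutive periods are haversine distances on
the R = 6371 km sphere with initial bearings clockwise from north.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import EARTH_RADIUS_KM, GridSpec, cell_area_vector
from .habitat import ClassMap
from .maxent import SuitabilityMap
from .synth import PAMask

__all__ = [
    "GapReport",
    "priority_areas",
    "gap_analysis",
    "suitable_centroid",
    "centroid_shift",
    "haversine_km",
    "centroid_track",
    "pa_mask_from_geojson",
]


def priority_areas(
    classmaps: dict[str, ClassMap] | list[ClassMap], min_species: int = 2
) -> np.ndarray:
    """Boolean priority mask: >= ``min_species`` species at class >= 2.

    Monotone in ``min_species``: raising it never grows the mask.
    """
    cmaps = list(classmaps.values()) if isinstance(classmaps, dict) else list(classmaps)
    if not cmaps:
        raise ValueError("need at least one class map")
    grid = cmaps[0].grid
    for c in cmaps[1:]:
        if c.grid != grid:
            raise ValueError("class maps are on different grids")
    counts = np.zeros(grid.shape, dtype=int)
    for c in cmaps:
        counts += ((c.classes >= 2) & c.mask).astype(int)
    return counts >= min_species


@dataclass
class GapReport:
    """Protected-area coverage of the priority area (1e4 km^2, %)."""

    priority_area: float
    protected_overlap: float
    percent_unprotected: float

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "priority_area_1e4_km2": round(self.priority_area, 2),
                "protected_overlap_1e4_km2": round(self.protected_overlap, 2),
                "percent_unprotected": round(self.percent_unprotected, 2),
            },
            indent=1,
        )
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def gap_analysis(priority: np.ndarray, pa: PAMask, grid: GridSpec) -> GapReport:
    """Overlay the priority mask with the PA mask.

    percent_unprotected = 100 * (1 - overlap / priority).
    """
    priority = np.asarray(priority, dtype=bool)
    if priority.shape != grid.shape or pa.member.shape != grid.shape:
        raise ValueError("masks must be on the working grid")
    if not priority.any():
        raise ValueError("empty priority mask")
    row_areas = cell_area_vector(grid)
    prio = float((priority.sum(axis=1) * row_areas).sum()) / 1e4
    over = float(((priority & pa.member).sum(axis=1) * row_areas).sum()) / 1e4
    return GapReport(
        priority_area=prio,
        protected_overlap=over,
        percent_unprotected=100.0 * (1.0 - over / prio),
    )


def suitable_centroid(
    smap: SuitabilityMap, mask_threshold: float = 0.2
) -> tuple[float, float]:
    """Area-weighted centroid (lon, lat) of cells with HSI >= threshold."""
    hit = (smap.values >= mask_threshold) & smap.mask
    if not hit.any():
        raise ValueError(f"no cell reaches suitability {mask_threshold}")
    grid = smap.grid
    row_areas = cell_area_vector(grid)
    rows, cols = np.nonzero(hit)
    w = row_areas[rows]
    lon = grid.x_min + (cols + 0.5) * grid.cell_size
    lat = grid.y_max - (rows + 0.5) * grid.cell_size
    return (float((w * lon).sum() / w.sum()), float((w * lat).sum() / w.sum()))


def haversine_km(c_from: tuple[float, float], c_to: tuple[float, float]) -> float:
    """Great-circle distance (km) on the R = 6371 km sphere."""
    lon1, lat1 = map(math.radians, c_from)
    lon2, lat2 = map(math.radians, c_to)
    a = (
        math.sin((lat2 - lat1) / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def centroid_shift(
    c_from: tuple[float, float], c_to: tuple[float, float]
) -> tuple[float, float]:
    """(distance_km, initial bearing in degrees clockwise from north)."""
    dist = haversine_km(c_from, c_to)
    lon1, lat1 = map(math.radians, c_from)
    lon2, lat2 = map(math.radians, c_to)
    dlon = lon2 - lon1
    y = math.sin(dlon) * math.cos(lat2)
    x = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlon)
    bearing = math.degrees(math.atan2(y, x)) % 360.0
    return dist, bearing


def centroid_track(
    scenario: str,
    periods: list[str],
    centroids: list[tuple[float, float]],
) -> pd.DataFrame:
    """Chained centroid shifts between consecutive periods.

    Row 0 (the starting period) has no step distance; each later row
    records the step from its predecessor.
    """
    if len(periods) != len(centroids) or len(periods) < 1:
        raise ValueError("periods and centroids must align (>= 1 entry)")
    rows = []
    for i, (period, (lon, lat)) in enumerate(zip(periods, centroids)):
        if i == 0:
            dist, bearing = float("nan"), float("nan")
        else:
            dist, bearing = centroid_shift(centroids[i - 1], (lon, lat))
        rows.append(
            {"scenario": scenario, "period": period,
             "lon": round(lon, 2), "lat": round(lat, 2),
             "distance_km": round(dist, 2) if i else float("nan"),
             "bearing_deg": round(bearing, 1) if i else float("nan")}
        )
    return pd.DataFrame(rows)


def pa_mask_from_geojson(path, grid: GridSpec) -> PAMask:
    """Rasterize GeoJSON polygons to a PA mask (cell-center-in-polygon)."""
    from shapely.geometry import shape
    from shapely.prepared import prep

    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    geoms = [shape(f["geometry"] if "geometry" in f else f) for f in feats]
    lon = grid.lon_centers()
    lat = grid.lat_centers()
    member = np.zeros(grid.shape, dtype=bool)
    from shapely.geometry import Point

    prepared = [prep(g) for g in geoms]
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            pt = Point(lon[c], lat[r])
            if any(p.contains(pt) for p in prepared):
                member[r, c] = True
    return PAMask(grid=grid, member=member)
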