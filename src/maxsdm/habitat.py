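"""Habitat-suitability classification and area dynamics.

The continuous habitat suitability index (HSI, cloglog scale) is cut
into four levels — not (0-0.2), minimally (0.2-0.4), moderately
(0.4-0.6) and highly (0.6-1) suitable — with lower-closed, upper-open
intervals and the top class closed at 1.  Class areas use the
spherical per-row cell areas and are reported in units of 1e4 km^2;
change and rate-of-change chains run current -> 2050 -> 2070 -> 2090
within each scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import EnvStack, GridSpec, cell_area_vector
from .maxent import MaxentModel, SuitabilityMap, predict

__all__ = [
    "DEFAULT_CLASS_CUTS",
    "CLASS_NAMES",
    "ClassMap",
    "classify",
    "class_areas",
    "area_change",
    "project_future",
    "area_table",
]

DEFAULT_CLASS_CUTS = (0.2, 0.4, 0.6)
CLASS_NAMES = ("not", "minimal", "moderate", "high")


@dataclass
class ClassMap:
    """4-level suitability classes per valid cell (0=not .. 3=high)."""

    grid: GridSpec
    classes: np.ndarray  # int, full grid; only mask cells meaningful
    mask: np.ndarray
    cuts: tuple[float, float, float] = DEFAULT_CLASS_CUTS
    label: str = ""

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if not np.issubdtype(self.classes.dtype, np.integer):
            raise TypeError("ClassMap.classes must be integer-coded")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.classes.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise ValueError("class map shape must match grid")
        v = self.classes[self.mask]
        if v.size and (v.min() < 0 or v.max() > 3):
            raise ValueError("classes must be in {0, 1, 2, 3}")


def classify(
    smap: SuitabilityMap, cuts: tuple[float, float, float] = DEFAULT_CLASS_CUTS
) -> ClassMap:
    """Discretize an HSI map into the 4-level codebook.

    Intervals are lower-closed, upper-open; class 3 is [0.6, 1].
    Rejects non-HSI input (raw maps, or anything outside [0, 1]).
    """
    if isinstance(smap, ClassMap):
        raise TypeError("classify expects a continuous SuitabilityMap, not a ClassMap")
    if tuple(sorted(cuts)) != tuple(cuts) or len(cuts) != 3:
        raise ValueError("cuts must be three increasing thresholds")
    v = smap.values[smap.mask]
    if v.size and (v.min() < 0.0 or v.max() > 1.0):
        raise ValueError("suitability values must lie in [0, 1] to classify")
    classes = np.digitize(smap.values, bins=np.asarray(cuts), right=False)
    classes = classes.astype(np.int8)
    classes[~smap.mask] = 0
    return ClassMap(
        grid=smap.grid, classes=classes, mask=smap.mask.copy(),
        cuts=tuple(cuts), label=smap.label,
    )


def class_areas(cmap: ClassMap) -> pd.Series:
    """Per-class and total-suitable areas in 1e4 km^2 (unrounded).

    ``total_suitable`` = minimal + moderate + high; the four classes
    partition the valid land area exactly.
    """
    row_areas = cell_area_vector(cmap.grid)  # km^2 per row
    areas = {}
    for code, name in enumerate(CLASS_NAMES):
        hit = (cmap.classes == code) & cmap.mask
        areas[name] = float((hit.sum(axis=1) * row_areas).sum()) / 1e4
    areas["total_suitable"] = areas["minimal"] + areas["moderate"] + areas["high"]
    areas["total_land"] = float((cmap.mask.sum(axis=1) * row_areas).sum()) / 1e4
    return pd.Series(areas, name=cmap.label or "areas")


def area_change(previous_total: float, current_total: float) -> tuple[float, float]:
    """(change, rate %) between consecutive periods, rounded to 2 decimals.

    Rate is undefined (NaN) when the previous total is zero.
    """
    change = current_total - previous_total
    if previous_total == 0:
        return round(change, 2), float("nan")
    return round(change, 2), round(100.0 * change / previous_total, 2)


def project_future(
    model: MaxentModel, future: EnvStack, transform: str = "cloglog"
) -> SuitabilityMap:
    """Project a fitted model onto a scenario stack (features clamp to
    the training range); the scenario label rides on the map."""
    smap = predict(model, future, transform=transform)
    smap.label = future.label
    return smap


def area_table(
    current: ClassMap, scenario_maps: dict[str, list[ClassMap]]
) -> pd.DataFrame:
    """Assemble the per-scenario area/change/rate table.

    ``scenario_maps`` maps scenario name -> chronologically ordered
    class maps; the change chain starts at the current map within each
    scenario.  Areas in 1e4 km^2 rounded to 2 decimals at report time.
    """
    rows = []
    cur = class_areas(current)
    rows.append(
        {"scenario": "current", "period": "current",
         **{k: round(cur[k], 2) for k in ("minimal", "moderate", "high", "total_suitable")},
         "change": np.nan, "rate_percent": np.nan}
    )
    for scenario, cmaps in scenario_maps.items():
        prev_total = cur["total_suitable"]
        for cmap in cmaps:
            a = class_areas(cmap)
            change, rate = area_change(prev_total, a["total_suitable"])
            rows.append(
                {"scenario": scenario, "period": cmap.label or "?",
                 **{k: round(a[k], 2) for k in ("minimal", "moderate", "high", "total_suitable")},
                 "change": change, "rate_percent": rate}
            )
            prev_total = a["total_suitable"]
    return pd.DataFrame(rows)
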