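"""Occurrence records: CSV ingest and one-record-per-grid-cell thinning.

Spatial rarefaction to a single record per raster cell removes
duplicate herbarium/GBIF-style records that would otherwise overweight
well-collected localities and overfit the model.  Thinning always uses
the working (modelling) grid, so the rarefaction resolution equals the
environmental resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .grids import GridSpec

logger = logging.getLogger(__name__)

__all__ = ["OccurrenceSet", "read_occurrences", "thin_to_grid"]


@dataclass
class OccurrenceSet:
    """Ordered presence coordinates for one species."""

    species: str
    records: list[tuple[float, float]] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        for lon, lat in self.records:
            if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                raise ValueError(
                    f"{self.species}: coordinate ({lon}, {lat}) out of range"
                )

    def __len__(self) -> int:
        return len(self.records)

    def lonlat(self):
        import numpy as np

        if not self.records:
            return np.empty((0, 2))
        return np.asarray(self.records, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "lon": [r[0] for r in self.records],
                "lat": [r[1] for r in self.records],
            }
        )


def read_occurrences(path, species: str | None = None) -> OccurrenceSet:
    """Read an occurrence CSV with columns species, lon, lat.

    Rows with unparseable or out-of-range coordinates are dropped and
    counted in a log line.  With multiple species in the file,
    ``species`` selects one; otherwise the file must contain a single
    species name.
    """
    df = pd.read_csv(path)
    missing = {"species", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if species is not None:
        df = df[df["species"] == species]
    else:
        names = df["species"].dropna().unique()
        if len(names) > 1:
            raise ValueError(
                f"{path}: multiple species {list(names)}; pass species= to select one"
            )
        species = str(names[0]) if len(names) else "unknown"
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    ok = lon.notna() & lat.notna() & lon.between(-180, 180) & lat.between(-90, 90)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d row(s) with invalid coordinates", species, n_dropped
        )
    records = list(zip(lon[ok].astype(float), lat[ok].astype(float)))
    return OccurrenceSet(species=species, records=records, provenance=str(path))


def thin_to_grid(
    occ: OccurrenceSet, grid: GridSpec, valid_mask=None
) -> OccurrenceSet:
    """Keep at most one record per grid cell (first in input order).

    Records outside the grid extent — or on cells that are nodata under
    ``valid_mask`` — are dropped and logged.  Idempotent.
    """
    seen: set[tuple[int, int]] = set()
    kept: list[tuple[float, float]] = []
    n_outside = 0
    for lon, lat in occ.records:
        cell = grid.cell_of(lon, lat)
        if cell is None or (valid_mask is not None and not valid_mask[cell]):
            n_outside += 1
            continue
        if cell in seen:
            continue
        seen.add(cell)
        kept.append((lon, lat))
    logger.info(
        "%s: thinned %d -> %d record(s) (%d outside grid or on nodata cells)",
        occ.species, len(occ.records), len(kept), n_outside,
    )
    return OccurrenceSet(
        species=occ.species, records=kept, provenance=f"{occ.provenance} [thinned]"
    )
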