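"""Raster grid data model and I/O.

Every spatial object in the package lives on a regular north-up
lon/lat grid of square cells (WGS84 degrees).  Rasters are exchanged as
ESRI ASCII grids (plain text, 6-line header) or single-band float32
GeoTIFFs.  Cell areas are computed on a sphere of radius 6371 km, which
is what all area tables (reported in units of 1e4 km^2) rest on.

Conventions
-----------
* ``values[0, :]`` is the northernmost row (ESRI ASCII row order).
* Cell centers sit at ``(x_min + (c + 0.5) s,  y_max - (r + 0.5) s)``.
* Point-in-cell tests use half-open intervals ``[edge, edge + s)``.
* Grid equality is exact, field by field — no epsilon.  Two rasters
  either share a grid bit-for-bit or they do not align.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GridSpec",
    "EnvLayer",
    "EnvStack",
    "RasterFormatError",
    "GridAlignmentError",
    "read_raster",
    "write_raster",
    "assemble_stack",
    "cell_area_km2",
    "cell_area_vector",
]


class RasterFormatError(ValueError):
    """Malformed raster file or unsupported grid geometry."""


class GridAlignmentError(ValueError):
    """Two rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Header of a regular north-up lon/lat grid with square cells."""

    n_rows: int
    n_cols: int
    x_min: float
    y_min: float
    cell_size: float
    nodata: float = -9999.0
    crs_label: str = "WGS84 lon/lat"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.y_max > 90.0 + 1e-12 or self.y_min < -90.0 - 1e-12:
            raise ValueError(
                f"grid latitude extent [{self.y_min}, {self.y_max}] leaves [-90, 90]"
            )

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row center, row 0 northernmost."""
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Return (row, col) containing the point, or None if outside.

        Half-open convention: a point exactly on the east/south outer
        edge is outside; on an interior edge it belongs to the
        east/south-ward cell of that edge's west/north neighbour.
        """
        s = self.cell_size
        col = math.floor((lon - self.x_min) / s)
        row = math.floor((self.y_max - lat) / s)
        # top edge (lat == y_max) belongs to row 0
        if lat == self.y_max:
            row = 0
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return (row, col)
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        s = self.cell_size
        return (self.x_min + (col + 0.5) * s, self.y_max - (row + 0.5) * s)


def cell_area_km2(grid: GridSpec, row: int) -> float:
    """Area in km^2 of one cell in the given row (spherical zone formula).

    A = R^2 * dlam * (sin(phi_top) - sin(phi_bot)); decreases toward the
    poles, mirror-symmetric about the equator.
    """
    if not 0 <= row < grid.n_rows:
        raise IndexError(f"row {row} out of range [0, {grid.n_rows})")
    s = grid.cell_size
    phi_top = math.radians(grid.y_max - row * s)
    phi_bot = math.radians(grid.y_max - (row + 1) * s)
    dlam = math.radians(s)
    return EARTH_RADIUS_KM**2 * dlam * (math.sin(phi_top) - math.sin(phi_bot))


def cell_area_vector(grid: GridSpec) -> np.ndarray:
    """Per-row cell areas (km^2), shape (n_rows,)."""
    s = grid.cell_size
    rows = np.arange(grid.n_rows)
    phi_top = np.radians(grid.y_max - rows * s)
    phi_bot = np.radians(grid.y_max - (rows + 1) * s)
    return EARTH_RADIUS_KM**2 * math.radians(s) * (np.sin(phi_top) - np.sin(phi_bot))


@dataclass
class EnvLayer:
    """One named environmental variable on a grid.

    ``values`` is float64 (n_rows, n_cols), row 0 north; ``mask`` is True
    on valid (data) cells.
    """

    name: str
    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"!= grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError(f"layer {self.name!r}: mask shape mismatch")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError(f"layer {self.name!r}: non-finite values on valid cells")

    def copy(self, name: str | None = None) -> "EnvLayer":
        return EnvLayer(
            name=self.name if name is None else name,
            grid=self.grid,
            values=self.values.copy(),
            mask=self.mask.copy(),
        )


class EnvStack:
    """Ordered collection of co-registered :class:`EnvLayer`.

    All layers must share a bitwise-identical :class:`GridSpec`; the
    joint validity mask is the intersection of the layer masks.
    """

    def __init__(self, layers: Sequence[EnvLayer], label: str = ""):
        layers = list(layers)
        if not layers:
            raise ValueError("EnvStack needs at least one layer")
        ref = layers[0]
        for lyr in layers[1:]:
            _check_same_grid(ref, lyr)
        names = [l.name for l in layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        self.layers = layers
        self.label = label
        self.grid: GridSpec = ref.grid
        self.joint_mask: np.ndarray = np.logical_and.reduce(
            [l.mask for l in layers]
        )
        if not self.joint_mask.any():
            raise ValueError("no jointly valid cell across layers")

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> EnvLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(f"no layer named {name!r}; have {self.names}")

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def subset(self, names: Iterable[str]) -> "EnvStack":
        return EnvStack([self[n] for n in names], label=self.label)

    def valid_values(self, names: Iterable[str] | None = None) -> np.ndarray:
        """Matrix (n_valid_cells, n_vars) of values on jointly valid cells."""
        names = self.names if names is None else list(names)
        return np.column_stack([self[n].values[self.joint_mask] for n in names])

    def valid_rowcol(self) -> tuple[np.ndarray, np.ndarray]:
        """Row and column indices of jointly valid cells (C order)."""
        return np.nonzero(self.joint_mask)


def _check_same_grid(a: EnvLayer, b: EnvLayer) -> None:
    ga, gb = a.grid, b.grid
    for f in ("n_rows", "n_cols", "x_min", "y_min", "cell_size", "nodata"):
        va, vb = getattr(ga, f), getattr(gb, f)
        if va != vb:
            raise GridAlignmentError(
                f"layers {a.name!r} and {b.name!r} disagree on {f}: {va} != {vb}"
            )


def assemble_stack(layers: Sequence[EnvLayer], label: str = "") -> EnvStack:
    """Stack co-registered layers, verifying exact grid equality."""
    return EnvStack(layers, label=label)


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

_ASCII_HEADER_FIELDS = {
    "ncols": int,
    "nrows": int,
    "xllcorner": float,
    "yllcorner": float,
    "cellsize": float,
    "nodata_value": float,
}


def _read_esri_ascii(path: Path, name: str) -> EnvLayer:
    with open(path) as fh:
        text = fh.read().split("\n")
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_FIELDS:
            key = parts[0].lower()
            try:
                header[key] = _ASCII_HEADER_FIELDS[key](parts[1])
            except ValueError as exc:
                raise RasterFormatError(
                    f"{path}: cannot parse header field {key!r}: {parts[1]!r}"
                ) from exc
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"{path}: missing header field {key!r}")
    nodata = header.get("nodata_value", -9999.0)
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=nodata,
    )
    body = " ".join(text[i:]).split()
    try:
        flat = np.array(body, dtype=float)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: non-numeric cell value in body") from exc
    if flat.size != grid.n_rows * grid.n_cols:
        raise RasterFormatError(
            f"{path}: expected {grid.n_rows * grid.n_cols} values, got {flat.size}"
        )
    values = flat.reshape(grid.n_rows, grid.n_cols)
    mask = values != nodata
    values = np.where(mask, values, np.nan)
    return EnvLayer(name=name, grid=grid, values=np.where(mask, values, 0.0), mask=mask)


def _write_esri_ascii(layer: EnvLayer, path: Path) -> None:
    g = layer.grid
    out = np.where(layer.mask, layer.values, g.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.x_min!r}\n")
        fh.write(f"yllcorner {g.y_min!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {g.nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# GeoTIFF (single band, float32, EPSG:4326) via tifffile tags
# ---------------------------------------------------------------------------

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKeys: geographic model, pixel-is-area, EPSG:4326
_GEO_KEYS = (
    1, 1, 0, 3,
    1024, 0, 1, 2,   # GTModelTypeGeoKey = geographic
    1025, 0, 1, 1,   # GTRasterTypeGeoKey = PixelIsArea
    2048, 0, 1, 4326,  # GeographicTypeGeoKey
)


def _write_geotiff(layer: EnvLayer, path: Path) -> None:
    import tifffile

    g = layer.grid
    data = np.where(layer.mask, layer.values, g.nodata).astype(np.float32)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x_min, g.y_max, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_GEO_KEYS), _GEO_KEYS),
        (_TAG_GDAL_NODATA, "s", 0, repr(g.nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def _read_geotiff(path: Path, name: str) -> EnvLayer:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}
    if data.ndim != 2:
        raise RasterFormatError(f"{path}: expected a single-band raster")
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise RasterFormatError(f"{path}: missing GeoTIFF georeferencing tags")
    sx, sy = tags[_TAG_MODEL_PIXEL_SCALE][:2]
    if not math.isclose(sx, sy, rel_tol=0, abs_tol=0):
        raise RasterFormatError(
            f"{path}: non-square cells ({sx} x {sy}) are not supported"
        )
    tie = tags[_TAG_MODEL_TIEPOINT]
    x_min = tie[3] - tie[0] * sx
    y_max = tie[4] + tie[1] * sy
    nodata = -9999.0
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(tags[_TAG_GDAL_NODATA])
        except (TypeError, ValueError) as exc:
            raise RasterFormatError(f"{path}: unparseable nodata tag") from exc
    n_rows, n_cols = data.shape
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_min=float(x_min),
        y_min=float(y_max - n_rows * sx),
        cell_size=float(sx),
        nodata=nodata,
    )
    values = data.astype(float)
    mask = values != nodata
    return EnvLayer(
        name=name, grid=grid, values=np.where(mask, values, 0.0), mask=mask
    )


def read_raster(path, format: str | None = None, name: str | None = None) -> EnvLayer:
    """Read a single-band raster (ESRI ASCII or GeoTIFF).

    ``format`` may be ``"esri_ascii"`` or ``"geotiff"``; when omitted it
    is inferred from the file suffix.  The layer name defaults to the
    file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "esri_ascii"
    name = path.stem if name is None else name
    if format == "esri_ascii":
        return _read_esri_ascii(path, name)
    if format == "geotiff":
        return _read_geotiff(path, name)
    raise ValueError(f"unknown raster format {format!r}")


def write_raster(layer: EnvLayer, path, format: str | None = None) -> Path:
    """Write a layer as ESRI ASCII (full repr precision) or float32 GeoTIFF."""
    path = Path(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "esri_ascii"
    if format == "esri_ascii":
        _write_esri_ascii(layer, path)
    elif format == "geotiff":
        _write_geotiff(layer, path)
    else:
        raise ValueError(f"unknown raster format {format!r}")
    return path
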