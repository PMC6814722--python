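"""Georeferenced raster data model, GeoTIFF I/O, and resampling.

Conventions
-----------
Row 0 is the northernmost row and the origin is the raster's northwest
corner. Cell ``(r, c)`` covers the half-open box
``[x0 + c*s, x0 + (c+1)*s) x (y0 - (r+1)*s, y0 - r*s]`` where ``s`` is the
cell size in meters. Only projected (meter-unit) coordinate reference
systems are supported; buffer distances and cell sizes throughout the
package assume metric grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = [
    "GridSpec",
    "RasterLayer",
    "LayerStack",
    "NODATA_FLOAT",
    "NODATA_BYTE",
    "read_raster",
    "write_raster",
    "resample_nearest",
    "resample_bilinear",
]

#: default nodata for continuous layers
NODATA_FLOAT = -9999.0
#: default nodata for byte-coded layers
NODATA_BYTE = 255

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_PROJECTED_CS = 3072

_MODEL_TYPE_PROJECTED = 1
_MODEL_TYPE_GEOGRAPHIC = 2

VALID_SEMANTICS = frozenset(
    {"cover_pct", "height_m", "loss_year_code", "hfp", "sci", "fsii",
     "fhd", "density", "class_label"}
)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid with square cells.

    Parameters
    ----------
    origin_x, origin_y : float
        Map coordinates (meters) of the northwest corner.
    cell_size : float
        Edge length of the square cells in meters.
    n_rows, n_cols : int
        Grid dimensions.
    crs_id : int
        Opaque projected-CRS identifier (an EPSG code in practice).
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_id: int = 32722

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates as 1-D arrays (cols, rows)."""
        s = self.cell_size
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * s
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * s
        return xs, ys

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (may fall off-grid)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        # top edge belongs to row 0 (the y-box is closed at its north edge)
        row = np.where(np.asarray(y) == self.origin_y, 0, row)
        return row, col

    def contains(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass
class RasterLayer:
    """A georeferenced grid of values with a nodata sentinel.

    ``semantics`` tags what the numbers mean (``cover_pct``, ``height_m``,
    ``loss_year_code``, ``hfp``, ``sci``, ``fsii``, ``fhd``, ``density``,
    ``class_label``) and travels with the file as the band description.
    """

    spec: GridSpec
    values: np.ndarray
    nodata: float
    semantics: str = "class_label"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"spec shape {self.spec.shape}"
            )
        if self.semantics not in VALID_SEMANTICS:
            raise ValueError(f"unknown semantics {self.semantics!r}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        if np.issubdtype(self.values.dtype, np.floating):
            return ~(np.isclose(self.values, self.nodata) | np.isnan(self.values))
        return self.values != self.nodata

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def with_values(self, values: np.ndarray, semantics: str | None = None) -> "RasterLayer":
        return RasterLayer(self.spec, values, self.nodata,
                           semantics if semantics is not None else self.semantics)


@dataclass
class LayerStack:
    """The aligned SCI inputs plus a (possibly coarser) human-footprint layer."""

    cover: RasterLayer
    height: RasterLayer
    loss: RasterLayer
    hfp: RasterLayer | None = None

    def __post_init__(self) -> None:
        if not (self.cover.spec == self.height.spec == self.loss.spec):
            raise ValueError("cover, height, and loss layers must share a GridSpec")
        if self.hfp is not None and self.hfp.spec.crs_id != self.cover.spec.crs_id:
            raise ValueError("hfp layer must share the stack's CRS")


def _geokeys(crs_id: int) -> tuple[int, ...]:
    return (
        1, 1, 0, 3,
        _KEY_MODEL_TYPE, 0, 1, _MODEL_TYPE_PROJECTED,
        _KEY_RASTER_TYPE, 0, 1, 1,  # pixel-is-area
        _KEY_PROJECTED_CS, 0, 1, crs_id,
    )


def write_raster(layer: RasterLayer, path) -> None:
    """Write a single-band GeoTIFF with georeferencing and nodata metadata.

    Integer layers round-trip bit-exactly through :func:`read_raster`.
    """
    spec = layer.spec
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0), True),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, spec.origin_x, spec.origin_y, 0.0), True),
        (_TAG_GEO_KEY_DIRECTORY, "H", 16, _geokeys(spec.crs_id), True),
        (_TAG_GDAL_NODATA, "s", None, repr(layer.nodata)
         if isinstance(layer.nodata, float) else str(layer.nodata), True),
    ]
    tifffile.imwrite(
        str(path),
        layer.values,
        extratags=extratags,
        metadata=None,
        description=f"semantics={layer.semantics}",
    )


def read_raster(path, nodata: float | None = None) -> RasterLayer:
    """Read a single-band projected GeoTIFF into a :class:`RasterLayer`.

    Raises ``ValueError`` for multi-band files and for geographic
    (degree-unit) CRSs, which must be projected before use.
    """
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        if page.samplesperpixel != 1 or len(tf.pages) > 1:
            raise ValueError(f"{path}: expected a single-band GeoTIFF")
        values = page.asarray()
        tags = page.tags

        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF geotransform tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        if not math.isclose(sx, sy):
            raise ValueError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
        tie = tags[_TAG_MODEL_TIEPOINT].value
        origin_x = tie[3] - tie[0] * sx
        origin_y = tie[4] + tie[1] * sy

        crs_id = 0
        if _TAG_GEO_KEY_DIRECTORY in tags:
            gkd = tags[_TAG_GEO_KEY_DIRECTORY].value
            keys = {gkd[i]: gkd[i + 3] for i in range(4, len(gkd), 4)}
            if keys.get(_KEY_MODEL_TYPE) == _MODEL_TYPE_GEOGRAPHIC:
                raise ValueError(
                    f"{path}: geographic (degree-unit) CRS; project the raster "
                    "to a metric CRS first"
                )
            crs_id = int(keys.get(_KEY_PROJECTED_CS, 0))

        file_nodata = None
        if _TAG_GDAL_NODATA in tags:
            try:
                file_nodata = float(tags[_TAG_GDAL_NODATA].value)
            except ValueError:
                file_nodata = None
        if file_nodata is not None and np.issubdtype(values.dtype, np.integer):
            file_nodata = int(file_nodata)

        semantics = "class_label"
        desc = page.description or ""
        if desc.startswith("semantics="):
            semantics = desc.split("=", 1)[1].strip()

    if nodata is None:
        if file_nodata is not None:
            nodata = file_nodata
        else:
            nodata = (NODATA_FLOAT if np.issubdtype(values.dtype, np.floating)
                      else NODATA_BYTE)

    spec = GridSpec(origin_x, origin_y, float(sx),
                    values.shape[0], values.shape[1], crs_id)
    return RasterLayer(spec, values, nodata, semantics)


def resample_nearest(layer: RasterLayer, target: GridSpec) -> RasterLayer:
    """Nearest-neighbor resampling: each target cell takes the value of the
    source cell containing the target cell's center. Off-grid centers and
    nodata propagate as nodata."""
    if layer.spec.crs_id != target.crs_id:
        raise ValueError("CRS mismatch between source layer and target spec")
    xs, ys = target.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    row, col = layer.spec.cell_of(xx, yy)
    inside = layer.spec.contains(row, col)
    out = np.full(target.shape, layer.nodata, dtype=layer.values.dtype)
    out[inside] = layer.values[row[inside], col[inside]]
    return RasterLayer(target, out, layer.nodata, layer.semantics)


def resample_bilinear(layer: RasterLayer, target: GridSpec) -> RasterLayer:
    """Bilinear resampling between cell centers for continuous layers.

    Each target center is interpolated from the four surrounding source
    cell centers; any target cell whose support touches a nodata source
    cell, or that falls outside the source center lattice, becomes nodata.
    """
    if layer.spec.crs_id != target.crs_id:
        raise ValueError("CRS mismatch between source layer and target spec")
    src = layer.spec
    s = src.cell_size
    xs, ys = target.cell_centers()
    xx, yy = np.meshgrid(xs, ys)

    # fractional position in source cell-center coordinates
    fx = (xx - (src.origin_x + 0.5 * s)) / s
    fy = ((src.origin_y - 0.5 * s) - yy) / s
    c0 = np.floor(fx).astype(int)
    r0 = np.floor(fy).astype(int)
    tx = fx - c0
    ty = fy - r0

    inside = (r0 >= 0) & (r0 + 1 < src.n_rows) & (c0 >= 0) & (c0 + 1 < src.n_cols)
    # allow exact landing on the last center row/col
    on_last_col = (c0 + 1 == src.n_cols) & (tx == 0)
    on_last_row = (r0 + 1 == src.n_rows) & (ty == 0)
    c0 = np.where(on_last_col, c0 - 1, c0)
    tx = np.where(on_last_col, 1.0, tx)
    r0 = np.where(on_last_row, r0 - 1, r0)
    ty = np.where(on_last_row, 1.0, ty)
    inside |= ((r0 >= 0) & (r0 + 1 < src.n_rows) &
               (c0 >= 0) & (c0 + 1 < src.n_cols))

    r0c = np.clip(r0, 0, src.n_rows - 2)
    c0c = np.clip(c0, 0, src.n_cols - 2)
    v00 = layer.values[r0c, c0c].astype(float)
    v01 = layer.values[r0c, c0c + 1].astype(float)
    v10 = layer.values[r0c + 1, c0c].astype(float)
    v11 = layer.values[r0c + 1, c0c + 1].astype(float)

    m = layer.mask
    ok = (inside & m[r0c, c0c] & m[r0c, c0c + 1]
          & m[r0c + 1, c0c] & m[r0c + 1, c0c + 1])

    interp = ((1 - ty) * ((1 - tx) * v00 + tx * v01)
              + ty * ((1 - tx) * v10 + tx * v11))
    nod = float(layer.nodata)
    out = np.where(ok, interp, nod)
    return RasterLayer(target, out, nod, layer.semantics)
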