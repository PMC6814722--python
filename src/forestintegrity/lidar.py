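"""Foliage height diversity (FHD) from classified lidar point clouds.

Pipeline: ground-normalize vegetation returns with a k-nearest-neighbor
inverse-distance-squared interpolation of the ground surface (k = 6),
drop heights above 70 m (cloud/sensor noise), grid vegetation returns to
30 m cells, and compute per-cell FHD as the Shannon entropy of the
1-m-binned height distribution,

    FHD = -sum_i p_i ln(p_i),

where p_i is the proportion of the cell's vegetation returns in the i-th
1 m vertical interval. Cells sparser than 10 vegetation points per square
meter are flagged invalid and excluded.

Point clouds are read and written as whitespace- or comma-delimited text
with columns x, y, z, cls (``cls`` 2 = ground per the LAS convention,
anything else vegetation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from forestintegrity.grids import GridSpec, RasterLayer, NODATA_FLOAT

__all__ = [
    "PointCloud", "NormalizedCloud", "FHDGrid",
    "read_point_cloud", "write_point_cloud",
    "normalize_heights", "filter_points", "point_density", "compute_fhd",
    "MAX_HEIGHT_M", "DENSITY_MIN", "N_BINS",
]

GROUND = 0
VEGETATION = 1

#: vegetation heights above this are treated as cloud/sensor noise
MAX_HEIGHT_M = 70.0
#: minimum vegetation point density (pts/m^2) for a cell to enter the analysis
DENSITY_MIN = 10.0
#: number of 1 m vertical bins, covering [0, 70] m
N_BINS = 70


@dataclass
class PointCloud:
    """Classified lidar returns in a projected CRS.

    ``cls`` is 0 for ground and 1 for vegetation returns.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    cls: np.ndarray
    acquisition_year: int = 2015
    crs_id: int = 32722

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.cls = np.asarray(self.cls, dtype=np.int8)
        n = len(self.x)
        if not (len(self.y) == len(self.z) == len(self.cls) == n):
            raise ValueError("x, y, z, cls must have equal length")
        if n and not (np.isfinite(self.x).all() and np.isfinite(self.y).all()
                      and np.isfinite(self.z).all()):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def ground(self) -> np.ndarray:
        return self.cls == GROUND

    @property
    def vegetation(self) -> np.ndarray:
        return self.cls == VEGETATION


@dataclass
class NormalizedCloud:
    """Vegetation returns with height above the interpolated ground surface."""

    x: np.ndarray
    y: np.ndarray
    height: np.ndarray
    acquisition_year: int = 2015
    crs_id: int = 32722
    n_ground: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.height = np.asarray(self.height, dtype=float)

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class FHDGrid:
    """Per-cell foliage height diversity with a density-based validity mask."""

    fhd: RasterLayer
    density: RasterLayer
    valid: np.ndarray


def read_point_cloud(path, acquisition_year: int = 2015,
                     crs_id: int = 32722) -> PointCloud:
    """Read a delimited text cloud with columns x, y, z, cls.

    Lines starting with ``#`` are skipped; the delimiter may be whitespace
    or a comma. ``cls`` follows the LAS convention: 2 = ground, any other
    code = vegetation.
    """
    with open(path) as fh:
        first = fh.readline()
    delim = "," if "," in first else None
    data = np.loadtxt(path, delimiter=delim, comments="#", ndmin=2)
    if data.shape[1] < 4:
        raise ValueError(f"{path}: expected 4 columns (x, y, z, cls)")
    las_cls = data[:, 3].astype(int)
    cls = np.where(las_cls == 2, GROUND, VEGETATION)
    return PointCloud(data[:, 0], data[:, 1], data[:, 2], cls,
                      acquisition_year=acquisition_year, crs_id=crs_id)


def write_point_cloud(cloud: PointCloud, path) -> None:
    """Write a cloud as comma-delimited text (x, y, z, cls) with LAS codes."""
    las_cls = np.where(cloud.cls == GROUND, 2, 1)
    data = np.column_stack([cloud.x, cloud.y, cloud.z, las_cls])
    header = (f"x,y,z,cls  acquisition_year={cloud.acquisition_year} "
              f"crs_id={cloud.crs_id}")
    np.savetxt(path, data, delimiter=",", header=header,
               fmt=["%.3f", "%.3f", "%.3f", "%d"])


def normalize_heights(cloud: PointCloud, k: int = 6) -> NormalizedCloud:
    """Convert vegetation returns to heights above an interpolated ground.

    For each vegetation point the local ground elevation is the
    inverse-distance-squared weighted mean of its k nearest ground returns
    in the x-y plane (w_i = 1/d_i^2); a vegetation point exactly above a
    ground return takes that return's elevation. If the cloud holds fewer
    than k ground returns, all of them are used.
    """
    ground = cloud.ground
    n_ground = int(ground.sum())
    if n_ground == 0:
        raise ValueError("cloud has no ground returns; cannot normalize")
    veg = cloud.vegetation
    gx, gy, gz = cloud.x[ground], cloud.y[ground], cloud.z[ground]
    vx, vy, vz = cloud.x[veg], cloud.y[veg], cloud.z[veg]

    kk = min(k, n_ground)
    tree = cKDTree(np.column_stack([gx, gy]))
    d, idx = tree.query(np.column_stack([vx, vy]), k=kk)
    if kk == 1:
        d, idx = d[:, None], idx[:, None]

    exact = d[:, 0] == 0.0
    with np.errstate(divide="ignore"):
        w = 1.0 / d**2
    w[exact] = 0.0  # placeholder; exact hits handled below
    gsum = np.einsum("ij,ij->i", w, gz[idx])
    g = np.where(exact, gz[idx[:, 0]], gsum / np.where(exact, 1.0, w.sum(axis=1)))

    return NormalizedCloud(vx, vy, vz - g,
                           acquisition_year=cloud.acquisition_year,
                           crs_id=cloud.crs_id, n_ground=n_ground)


def filter_points(cloud: NormalizedCloud,
                  max_height: float = MAX_HEIGHT_M) -> NormalizedCloud:
    """Drop vegetation heights above ``max_height`` and clamp negatives to 0.

    Heights above 70 m are almost always cloud or sensor noise. Slightly
    negative normalized heights (returns below the interpolated ground)
    are kept at height 0 so they still count toward point density.
    """
    keep = cloud.height <= max_height
    return NormalizedCloud(cloud.x[keep], cloud.y[keep],
                           np.maximum(cloud.height[keep], 0.0),
                           acquisition_year=cloud.acquisition_year,
                           crs_id=cloud.crs_id, n_ground=cloud.n_ground)


def _cell_index(cloud: NormalizedCloud, spec: GridSpec
                ) -> tuple[np.ndarray, np.ndarray]:
    row, col = spec.cell_of(cloud.x, cloud.y)
    inside = spec.contains(row, col)
    return row * spec.n_cols + col, inside


def point_density(cloud: NormalizedCloud, spec: GridSpec) -> RasterLayer:
    """Vegetation returns per square meter for each grid cell."""
    flat, inside = _cell_index(cloud, spec)
    counts = np.bincount(flat[inside], minlength=spec.n_rows * spec.n_cols)
    dens = counts.reshape(spec.shape) / spec.cell_size**2
    return RasterLayer(spec, dens.astype(float), NODATA_FLOAT, "density")


def compute_fhd(cloud: NormalizedCloud, spec: GridSpec,
                density_min: float = DENSITY_MIN,
                log_base: float | None = None) -> FHDGrid:
    """Per-cell Shannon foliage height diversity on 1 m vertical bins.

    Heights are binned half-open [i, i+1) for i = 0..69 with the top bin
    closed (a 70 m return lands in bin 69). Cells with vegetation density
    below ``density_min`` points/m^2 are nodata in the FHD layer and False
    in the validity mask. ``log_base`` switches the entropy logarithm from
    the natural log default.
    """
    flat, inside = _cell_index(cloud, spec)
    n_cells = spec.n_rows * spec.n_cols

    bins = np.floor(cloud.height).astype(int)
    bins = np.clip(bins, 0, N_BINS - 1)

    counts = np.zeros((n_cells, N_BINS), dtype=np.int64)
    np.add.at(counts, (flat[inside], bins[inside]), 1)

    total = counts.sum(axis=1)
    dens = total.reshape(spec.shape) / spec.cell_size**2
    valid = dens >= density_min

    fhd = np.full(n_cells, NODATA_FLOAT)
    has = total > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts[has] / total[has, None]
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    ent = -plogp.sum(axis=1)
    if log_base is not None:
        ent = ent / np.log(log_base)
    fhd[has] = ent
    fhd = fhd.reshape(spec.shape)
    fhd[~valid] = NODATA_FLOAT

    return FHDGrid(
        fhd=RasterLayer(spec, fhd, NODATA_FLOAT, "fhd"),
        density=RasterLayer(spec, dens, NODATA_FLOAT, "density"),
        valid=valid,
    )
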