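"""Voxel-based 3D habitat structure metrics from plot-level point clouds.

A plot's point cloud is height-normalized against a kNN/IDW digital terrain
model, discretized into 0.5 m occupancy voxels, and summarized by eleven
metrics: occupied-voxel amounts overall and per vertical stratum
(understory 0-5 m, midstory 5-15 m, subcanopy 15-25 m, canopy > 25 m),
patch counts of the corresponding 2D presence rasters (8-connectivity),
and the variance of the 1 m vertical occupancy profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

#: default stratum boundaries (m): understory/midstory, midstory/subcanopy,
#: subcanopy/canopy.  Intervals are half-open [a, b).
STRATA_BOUNDS = (5.0, 15.0, 25.0)
STRATA = ("understory", "midstory", "subcanopy", "canopy")

#: fixed vertical profile extent: 70 one-metre bins, [0,1) ... [69,70).
N_PROFILE_BINS = 70

#: queen's-case connectivity for patch labelling.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass
class PointCloud:
    """Plot-level point cloud with an optional per-point ground flag."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    ground: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.shape == self.y.shape == self.z.shape):
            raise ValueError("x, y, z must have identical shapes")
        for arr in (self.x, self.y, self.z):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError("point coordinates must be finite")
        if self.ground is not None:
            self.ground = np.asarray(self.ground, dtype=bool)
            if self.ground.shape != self.x.shape:
                raise ValueError("ground flag must match point count")

    def __len__(self) -> int:
        return self.x.size

    @classmethod
    def from_xyz(cls, path) -> "PointCloud":
        """Read a whitespace-delimited text cloud: x y z [ground]."""
        arr = np.loadtxt(path, ndmin=2)
        if arr.shape[1] < 3:
            raise ValueError(f"{path}: expected at least 3 columns")
        ground = arr[:, 3].astype(bool) if arr.shape[1] >= 4 else None
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], ground)

    def to_xyz(self, path) -> None:
        cols = [self.x, self.y, self.z]
        fmt = ["%.6f", "%.6f", "%.6f"]
        if self.ground is not None:
            cols.append(self.ground.astype(int))
            fmt.append("%d")
        np.savetxt(path, np.column_stack(cols), fmt=fmt)


def identify_ground(cloud: PointCloud, cell: float = 2.0) -> np.ndarray:
    """Flag the lowest point of every ``cell`` x ``cell`` m column as ground.

    Deterministic fallback used when a cloud carries no ground
    classification; standard lowest-point seeding for terrain models.
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud has no ground points")
    ix = np.floor(cloud.x / cell).astype(np.int64)
    iy = np.floor(cloud.y / cell).astype(np.int64)
    key = ix * (iy.max() - iy.min() + 1 if iy.size else 1) + iy
    order = np.lexsort((cloud.z, key))
    sorted_key = key[order]
    first = np.ones(len(cloud), dtype=bool)
    first[1:] = sorted_key[1:] != sorted_key[:-1]
    ground = np.zeros(len(cloud), dtype=bool)
    ground[order[first]] = True
    return ground


def normalize_height(
    cloud: PointCloud,
    knn: int = 10,
    idw_power: float = 2.0,
    z_cap: float | str = float(N_PROFILE_BINS),
    ground_cell: float = 2.0,
) -> PointCloud:
    """Height-normalize a cloud against a kNN inverse-distance-weighted DTM.

    The terrain elevation under each point is interpolated from its ``knn``
    nearest ground points with weights ``1/d**idw_power``; the point's height
    becomes ``z - DTM(x, y)``.  Points falling below zero after normalization
    are removed, as are high outliers above ``z_cap``.  The default cap is
    the 70 m ceiling of the vertical profile (vegetation above it carries no
    information for any metric); ``"auto"`` instead uses the 99.9th
    percentile of normalized heights + 5 m, which is more adaptive but can
    clip genuinely sparse canopy.

    Parameters
    ----------
    cloud
        Input cloud.  If it has no ground flags, ground is identified as the
        lowest point per ``ground_cell`` m grid cell.
    """
    ground = cloud.ground if cloud.ground is not None else identify_ground(cloud, ground_cell)
    n_ground = int(ground.sum())
    if n_ground == 0:
        raise ValueError("cloud contains no ground points")
    if knn > n_ground:
        warnings.warn(
            f"knn={knn} exceeds ground-point count {n_ground}; clamping", stacklevel=2
        )
        knn = n_ground

    tree = cKDTree(np.column_stack([cloud.x[ground], cloud.y[ground]]))
    gz = cloud.z[ground]
    dist, idx = tree.query(np.column_stack([cloud.x, cloud.y]), k=knn)
    dist = np.atleast_2d(dist.T).T  # k=1 returns 1-D
    idx = np.atleast_2d(idx.T).T
    with np.errstate(divide="ignore"):
        w = 1.0 / dist**idw_power
    # exact hit on a ground point: use its elevation directly
    exact = dist[:, 0] < 1e-12
    w[~np.isfinite(w)] = 0.0
    wsum = w.sum(axis=1)
    dtm = np.where(
        exact,
        gz[idx[:, 0]],
        (w * gz[idx]).sum(axis=1) / np.where(wsum > 0, wsum, 1.0),
    )
    z_norm = cloud.z - dtm

    keep = z_norm >= 0.0
    if z_cap == "auto":
        if np.any(keep):
            cap = float(np.percentile(z_norm[keep], 99.9)) + 5.0
        else:
            cap = np.inf
    else:
        cap = float(z_cap)
    keep &= z_norm <= cap
    return PointCloud(
        cloud.x[keep],
        cloud.y[keep],
        z_norm[keep],
        ground[keep],
    )


@dataclass
class VoxelGrid:
    """Sparse boolean occupancy on a 0.5 m lattice.

    ``indices`` holds the integer lattice coordinates ``(ix, iy, iz)`` of the
    occupied voxels; a voxel is the half-open cell
    ``[ix*r, (ix+1)*r) x [iy*r, (iy+1)*r) x [iz*r, (iz+1)*r)`` on the
    absolute lattice (``r`` = resolution), so binning is independent of the
    cloud's bounding box up to a deterministic shift.
    """

    indices: np.ndarray
    resolution: float = 0.5

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64).reshape(-1, 3)
        if self.indices.size:
            self.indices = np.unique(self.indices, axis=0)

    @property
    def n_occupied(self) -> int:
        return self.indices.shape[0]

    def center_heights(self) -> np.ndarray:
        """Height (m) of each occupied voxel's center."""
        return (self.indices[:, 2] + 0.5) * self.resolution


def voxelize(cloud: PointCloud, resolution: float = 0.5, include_ground: bool = False) -> VoxelGrid:
    """Discretize a normalized cloud into occupancy voxels.

    A voxel is occupied iff at least one (vegetation) point falls inside its
    half-open cell; ground returns are excluded by default so occupancy
    reflects vegetation structure.  Idempotent at the grid level.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    mask = np.ones(len(cloud), dtype=bool)
    if not include_ground and cloud.ground is not None:
        mask &= ~cloud.ground
    if not np.any(mask):
        return VoxelGrid(np.empty((0, 3), dtype=np.int64), resolution)
    idx = np.floor(
        np.column_stack([cloud.x[mask], cloud.y[mask], cloud.z[mask]]) / resolution
    ).astype(np.int64)
    return VoxelGrid(idx, resolution)


def _stratum_range(stratum: str, bounds=STRATA_BOUNDS) -> tuple[float, float]:
    lows = (0.0,) + tuple(bounds)
    highs = tuple(bounds) + (np.inf,)
    try:
        i = STRATA.index(stratum)
    except ValueError:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}") from None
    return lows[i], highs[i]


def strata_amounts(grid: VoxelGrid, bounds=STRATA_BOUNDS) -> dict[str, int]:
    """Occupied-voxel counts per stratum (by voxel-center height) plus total.

    Strata are half-open ``[0,5), [5,15), [15,25), [25,inf)`` by default, so
    the four amounts partition the total exactly.
    """
    h = grid.center_heights()
    out: dict[str, int] = {}
    for s in STRATA:
        lo, hi = _stratum_range(s, bounds)
        out[s] = int(np.count_nonzero((h >= lo) & (h < hi)))
    out["total"] = int(grid.n_occupied)
    return out


def _presence_raster(grid: VoxelGrid, lo: float, hi: float) -> np.ndarray:
    h = grid.center_heights()
    sel = (h >= lo) & (h < hi)
    if not np.any(sel):
        return np.zeros((0, 0), dtype=bool)
    xy = grid.indices[sel, :2]
    off = xy.min(axis=0)
    xy = xy - off
    raster = np.zeros(xy.max(axis=0) + 1, dtype=bool)
    raster[xy[:, 0], xy[:, 1]] = True
    return raster


def patch_count(grid: VoxelGrid, stratum: str | None = None, bounds=STRATA_BOUNDS) -> int:
    """Number of patches (NP) of a stratum's 2D presence raster.

    Voxels in the height range are collapsed vertically into a presence
    raster (a cell is present iff its column holds >= 1 occupied voxel) and
    patches are connected components under 8-connectivity (queen's case).
    ``stratum=None`` uses all voxels (the 2D configuration metric).
    """
    lo, hi = (0.0, np.inf) if stratum is None else _stratum_range(stratum, bounds)
    raster = _presence_raster(grid, lo, hi)
    if raster.size == 0:
        return 0
    _, n = ndimage.label(raster, structure=_STRUCTURE_8)
    return int(n)


def vertical_profile(grid: VoxelGrid, n_bins: int = N_PROFILE_BINS) -> np.ndarray:
    """Occupied-voxel count per fixed 1 m height bin ([0,1) ... [69,70))."""
    h = grid.center_heights()
    h = h[(h >= 0) & (h < n_bins)]
    return np.bincount(np.floor(h).astype(int), minlength=n_bins)[:n_bins]


def vertical_variance(grid: VoxelGrid, n_bins: int = N_PROFILE_BINS) -> float:
    """Sample variance (ddof=1) of the fixed 70-bin vertical profile."""
    return float(np.var(vertical_profile(grid, n_bins), ddof=1))


@dataclass
class StructureMetrics:
    """The eleven per-plot habitat composition/configuration metrics."""

    total_a: int
    can_a: int
    sub_a: int
    mid_a: int
    und_a: int
    total_c: int
    can_c: int
    sub_c: int
    mid_c: int
    und_c: int
    vert_v: float

    #: column order used throughout the package and in CSV output.
    NAMES = (
        "Total_A", "Can_A", "Sub_A", "Mid_A", "Und_A",
        "Total_C", "Can_C", "Sub_C", "Mid_C", "Und_C", "Vert_V",
    )

    def as_series(self) -> pd.Series:
        return pd.Series(
            [
                self.total_a, self.can_a, self.sub_a, self.mid_a, self.und_a,
                self.total_c, self.can_c, self.sub_c, self.mid_c, self.und_c,
                self.vert_v,
            ],
            index=list(self.NAMES),
        )


def compute_metrics(grid: VoxelGrid, bounds=STRATA_BOUNDS) -> StructureMetrics:
    """All eleven structure metrics of an occupancy grid."""
    amounts = strata_amounts(grid, bounds)
    return StructureMetrics(
        total_a=amounts["total"],
        can_a=amounts["canopy"],
        sub_a=amounts["subcanopy"],
        mid_a=amounts["midstory"],
        und_a=amounts["understory"],
        total_c=patch_count(grid, None, bounds),
        can_c=patch_count(grid, "canopy", bounds),
        sub_c=patch_count(grid, "subcanopy", bounds),
        mid_c=patch_count(grid, "midstory", bounds),
        und_c=patch_count(grid, "understory", bounds),
        vert_v=vertical_variance(grid),
    )


def metrics_from_cloud(
    cloud: PointCloud,
    knn: int = 10,
    idw_power: float = 2.0,
    resolution: float = 0.5,
    z_cap: float | str = "auto",
) -> StructureMetrics:
    """Convenience: normalize, voxelize and summarize a raw cloud."""
    norm = normalize_height(cloud, knn=knn, idw_power=idw_power, z_cap=z_cap)
    return compute_metrics(voxelize(norm, resolution))


def plot_profile(grid: VoxelGrid, ax=None):
    """Bar plot of the 1 m vertical occupancy profile (diagnostic)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    prof = vertical_profile(grid)
    ax.barh(np.arange(len(prof)) + 0.5, prof, height=1.0)
    ax.set_xlabel("occupied voxels")
    ax.set_ylabel("height bin (m)")
    return ax
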