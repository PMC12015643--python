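"""Parametric vegetation scenes with an exact construction oracle.

Scenes are built directly on the 0.5 m voxel lattice: each stratum receives a
requested number of disc-shaped vegetation patches (non-overlapping across
the whole scene, separated by >= 2 empty columns so 8-connectivity can never
merge them), every patch column is filled to the stratum's target occupancy,
and >= 1 point is emitted inside every occupied voxel.  The generator records
the voxels and patches it placed, giving downstream structure metrics an
exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..habitat import (
    N_PROFILE_BINS,
    STRATA,
    STRATA_BOUNDS,
    PointCloud,
    StructureMetrics,
)

#: vertical extent (m) used for canopy voxels; the canopy stratum is
#: open-ended upward, generated vegetation stops here.
CANOPY_TOP = 35.0

_DEF_OCC = {"understory": 0.30, "midstory": 0.20, "subcanopy": 0.15, "canopy": 0.10}
_DEF_PATCHES = {"understory": 3, "midstory": 2, "subcanopy": 2, "canopy": 1}


@dataclass
class SceneSpec:
    """Parameters of one synthetic vegetation scene.

    Defaults mimic a mixed-forest survey plot: understory through canopy all
    present, patchier low strata, ~4 returns per square metre (the survey
    instrument's floor), flat terrain, and a trace of vertical outlier noise.
    ``plot_radius`` defaults to the survey's 250 m disc; test suites use
    smaller discs for speed.
    """

    plot_radius: float = 250.0
    strata_occupancy: dict = field(default_factory=lambda: dict(_DEF_OCC))
    patch_count_target: dict = field(default_factory=lambda: dict(_DEF_PATCHES))
    ground_relief_amplitude: float = 0.0
    point_density: float = 4.0
    noise_fraction: float = 0.001
    base_elevation: float = 150.0
    seed: int = 0
    resolution: float = 0.5

    def __post_init__(self) -> None:
        if self.plot_radius <= 0:
            raise ValueError("plot_radius must be positive")
        if self.point_density <= 0:
            raise ValueError("point_density must be positive")
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must be in [0, 1)")
        for s, v in self.strata_occupancy.items():
            if s not in STRATA:
                raise ValueError(f"unknown stratum {s!r}")
            if not 0 <= v <= 1:
                raise ValueError(f"occupancy for {s} must be in [0, 1]")
        for s, v in self.patch_count_target.items():
            if s not in STRATA:
                raise ValueError(f"unknown stratum {s!r}")
            if v < 0 or int(v) != v:
                raise ValueError("patch counts must be non-negative integers")


@dataclass
class SceneTruth:
    """Exact record of what the generator constructed.

    ``voxels`` maps stratum -> (n, 3) integer lattice indices of occupied
    voxels; ``patch_counts`` holds the per-stratum and total patch counts
    guaranteed by the non-overlap construction.
    """

    voxels: dict
    patch_counts: dict
    resolution: float = 0.5

    def amounts(self) -> dict:
        out = {s: int(self.voxels[s].shape[0]) for s in STRATA}
        out["total"] = sum(out.values())
        return out

    def vertical_profile(self) -> np.ndarray:
        counts = np.zeros(N_PROFILE_BINS, dtype=int)
        for s in STRATA:
            vox = self.voxels[s]
            if vox.size:
                h = (vox[:, 2] + 0.5) * self.resolution
                counts += np.bincount(np.floor(h).astype(int), minlength=N_PROFILE_BINS)[
                    :N_PROFILE_BINS
                ]
        return counts

    def metrics(self) -> StructureMetrics:
        a = self.amounts()
        return StructureMetrics(
            total_a=a["total"],
            can_a=a["canopy"],
            sub_a=a["subcanopy"],
            mid_a=a["midstory"],
            und_a=a["understory"],
            total_c=self.patch_counts["total"],
            can_c=self.patch_counts["canopy"],
            sub_c=self.patch_counts["subcanopy"],
            mid_c=self.patch_counts["midstory"],
            und_c=self.patch_counts["understory"],
            vert_v=float(np.var(self.vertical_profile(), ddof=1)),
        )


@dataclass
class SyntheticScene:
    cloud: PointCloud
    truth: SceneTruth
    spec: SceneSpec


def _relief(x: np.ndarray, y: np.ndarray, amplitude: float, radius: float) -> np.ndarray:
    """Smooth terrain surface; zero everywhere when amplitude is zero."""
    if amplitude == 0:
        return np.zeros_like(np.asarray(x, dtype=float))
    k = 2 * np.pi / (4.0 * radius)
    return amplitude * 0.5 * (np.sin(k * x) + np.cos(k * y + 1.0))


def _stratum_z_cells(stratum: str, resolution: float) -> np.ndarray:
    lows = (0.0,) + STRATA_BOUNDS
    highs = STRATA_BOUNDS + (CANOPY_TOP,)
    i = STRATA.index(stratum)
    return np.arange(int(round(lows[i] / resolution)), int(round(highs[i] / resolution)))


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Build one scene from its spec; same seed gives identical arrays.

    Raises ``ValueError`` when the requested patches cannot be placed with
    the mandatory 2-column gaps inside the plot disc.
    """
    rng = np.random.default_rng(spec.seed)
    res = spec.resolution
    R = spec.plot_radius

    # columns whose full footprint lies inside the disc
    n_cells = int(np.ceil(R / res)) + 1
    ii = np.arange(-n_cells, n_cells)
    ix, iy = np.meshgrid(ii, ii, indexing="ij")
    cx = (ix + 0.5) * res
    cy = (iy + 0.5) * res
    corner = res * np.sqrt(0.5)
    inside = np.hypot(cx, cy) + corner <= R
    cols = np.column_stack([ix[inside], iy[inside]])
    if cols.shape[0] == 0:
        raise ValueError("plot too small to contain any voxel column")

    # --- place patches: discs of columns, globally non-overlapping with
    # >= 2-column gaps so 8-connectivity cannot merge them anywhere
    col_set = {tuple(c) for c in map(tuple, cols)}
    blocked: set[tuple[int, int]] = set()
    patch_columns: dict[str, list[np.ndarray]] = {s: [] for s in STRATA}
    order = [s for s in STRATA if spec.patch_count_target.get(s, 0) > 0]
    max_patch_radius = max(2, min(5, n_cells // 4))
    def disc_members(c, pr):
        dd = np.arange(-pr, pr + 1)
        dx, dy = np.meshgrid(dd, dd, indexing="ij")
        disc = np.hypot(dx, dy) <= pr + 0.01
        return np.column_stack([c[0] + dx[disc], c[1] + dy[disc]])

    def try_place(c, pr):
        members = disc_members(c, pr)
        mt = [tuple(m) for m in members]
        if not all(m in col_set for m in mt):
            return None
        if any(m in blocked for m in mt):
            return None
        # reserve members plus a 2-column halo so nothing can touch them
        for gx in range(-2, 3):
            for gy in range(-2, 3):
                for m in mt:
                    blocked.add((m[0] + gx, m[1] + gy))
        return members

    for s in order:
        for _ in range(int(spec.patch_count_target[s])):
            placed = None
            for attempt in range(300):
                pr = int(rng.integers(1, max_patch_radius + 1)) if attempt < 150 else 1
                placed = try_place(cols[rng.integers(cols.shape[0])], pr)
                if placed is not None:
                    break
            if placed is None:
                # deterministic sweep: take any remaining radius-1 slot
                for c in cols[rng.permutation(cols.shape[0])]:
                    placed = try_place(c, 1)
                    if placed is not None:
                        break
            if placed is None:
                raise ValueError(
                    f"could not place {spec.patch_count_target[s]} patches in "
                    f"stratum {s!r}: plot radius {R} m too small for the request"
                )
            patch_columns[s].append(placed)

    # --- fill voxels within patch columns to the stratum occupancy target
    vox_by_stratum: dict[str, np.ndarray] = {}
    for s in STRATA:
        zcells = _stratum_z_cells(s, res)
        nz = zcells.size
        occ = spec.strata_occupancy.get(s, 0.0)
        n_fill = max(1, int(round(occ * nz))) if patch_columns[s] else 0
        rows = []
        for members in patch_columns[s]:
            for col in members:
                zz = rng.choice(zcells, size=n_fill, replace=False)
                for z in zz:
                    rows.append((col[0], col[1], z))
        vox_by_stratum[s] = (
            np.array(sorted(rows), dtype=np.int64).reshape(-1, 3)
            if rows
            else np.empty((0, 3), dtype=np.int64)
        )

    patch_counts = {s: len(patch_columns[s]) for s in STRATA}
    patch_counts["total"] = sum(patch_counts[s] for s in STRATA)
    truth = SceneTruth(vox_by_stratum, patch_counts, res)

    # --- emit points: ground at column centers, vegetation inside voxels
    g_x = (cols[:, 0] + 0.5) * res
    g_y = (cols[:, 1] + 0.5) * res
    g_z = spec.base_elevation + _relief(g_x, g_y, spec.ground_relief_amplitude, R)

    all_vox = (
        np.concatenate([vox_by_stratum[s] for s in STRATA])
        if any(vox_by_stratum[s].size for s in STRATA)
        else np.empty((0, 3), dtype=np.int64)
    )
    margin = 1e-4
    per_voxel = 1 + rng.poisson(max(spec.point_density * res * res - 1.0, 0.0), size=all_vox.shape[0])
    reps = np.repeat(np.arange(all_vox.shape[0]), per_voxel)
    u = rng.uniform(margin, 1 - margin, size=(reps.size, 3))
    v_x = (all_vox[reps, 0] + u[:, 0]) * res
    v_y = (all_vox[reps, 1] + u[:, 1]) * res
    v_h = (all_vox[reps, 2] + u[:, 2]) * res
    v_z = spec.base_elevation + _relief(v_x, v_y, spec.ground_relief_amplitude, R) + v_h

    n_noise = int(round(spec.noise_fraction * max(v_x.size, 1)))
    if n_noise and v_x.size:
        pick = rng.integers(0, v_x.size, size=n_noise)
        nx = v_x[pick]
        ny = v_y[pick]
        below = rng.random(n_noise) < 0.5
        nz = np.where(
            below,
            spec.base_elevation - rng.uniform(1.0, 5.0, n_noise),
            spec.base_elevation + CANOPY_TOP + rng.uniform(60.0, 100.0, n_noise),
        )
    else:
        nx = ny = nz = np.empty(0)

    cloud = PointCloud(
        x=np.concatenate([g_x, v_x, nx]),
        y=np.concatenate([g_y, v_y, ny]),
        z=np.concatenate([g_z, v_z, nz]),
        ground=np.concatenate(
            [
                np.ones(g_x.size, dtype=bool),
                np.zeros(v_x.size + nx.size, dtype=bool),
            ]
        ),
    )
    return SyntheticScene(cloud=cloud, truth=truth, spec=spec)
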