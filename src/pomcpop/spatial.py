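"""3D spatial statistics on atlas-registered neuron coordinates.

Compares the spatial distributions of two labeled neuron populations in
a common atlas frame (coordinates in µm; x medio-lateral, y
dorso-ventral, z antero-posterior):

* an isotropic Gaussian kernel density estimate of the merged point
  cloud on a regular grid (the isosurface-density field);
* a cube partition of the populations' common bounding box, with
  per-animal counts per cube as the unit of replication;
* a density-factor correction (n_Glp1r / n_Lepr) that rescales the
  larger population's per-cube counts so both groups contribute equal
  corrected totals;
* a per-cube two-sided two-sample Student's t-test between groups;
* coronal cross-sections (antero-posterior slabs) and region-of-interest
  projection densities normalized to neuron number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import AnalysisError, InputError
from .stats import benjamini_hochberg_adjust

__all__ = [
    "PointCloud",
    "DensityField",
    "VoxelGrid",
    "VoxelTestResult",
    "ProjectionDensity",
    "kde_density",
    "voxelize",
    "apply_density_factor",
    "voxel_ttest",
    "coronal_sections",
    "projection_density",
    "common_bounding_box",
]


@dataclass(frozen=True)
class PointCloud:
    """Per-animal 3D neuron coordinates (µm) with a group label."""

    animal_id: str
    group: str
    coordinates: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError("coordinates must be an (n, 3) array")
        if coords.shape[0] < 1:
            raise InputError("a point cloud needs at least one point")
        if not np.all(np.isfinite(coords)):
            raise InputError("coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_points(self) -> int:
        return int(self.coordinates.shape[0])


@dataclass(frozen=True)
class DensityField:
    grid_origin: np.ndarray  # (3,) µm, center of the first voxel
    grid_spacing: np.ndarray  # (3,) µm
    values: np.ndarray  # (nx, ny, nz), nonnegative
    bandwidth: float  # µm

    def grid_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.grid_origin[d] + np.arange(self.values.shape[d]) * self.grid_spacing[d]
            for d in range(3)
        )

    def integral(self) -> float:
        return float(self.values.sum() * np.prod(self.grid_spacing))


@dataclass(frozen=True)
class VoxelGrid:
    """Per-animal counts per cube over a shared bounding box."""

    cube_edge: float  # µm
    bounding_box: np.ndarray  # (3, 2)
    shape: tuple[int, int, int]
    counts: Mapping[str, np.ndarray]  # animal_id -> flat per-cube vector
    groups: Mapping[str, str]  # animal_id -> group label
    density_factor: float = 1.0

    def cube_centroids(self) -> np.ndarray:
        axes = [
            self.bounding_box[d, 0] + (np.arange(self.shape[d]) + 0.5) * self.cube_edge
            for d in range(3)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([g.ravel() for g in grid])

    def group_total(self, group: str) -> float:
        return float(
            sum(v.sum() for a, v in self.counts.items() if self.groups[a] == group)
        )


@dataclass(frozen=True)
class VoxelTestResult:
    t: np.ndarray
    p: np.ndarray
    direction: np.ndarray  # group label with the higher mean, "" where t == 0
    centroids: np.ndarray  # (n_cubes, 3) µm
    tested: np.ndarray  # False where both groups were degenerate (flagged out)
    p_adjusted: np.ndarray | None = None


@dataclass(frozen=True)
class ProjectionDensity:
    roi_name: str
    raw_intensity: float  # a.u.
    n_neurons: int
    normalized_density: float  # a.u. per neuron


def common_bounding_box(clouds: Sequence[PointCloud], pad: float = 0.0) -> np.ndarray:
    """Axis-aligned bounding box (3, 2) of the union of the clouds."""
    if not clouds:
        raise InputError("no point clouds given")
    pts = np.vstack([c.coordinates for c in clouds])
    box = np.column_stack([pts.min(axis=0) - pad, pts.max(axis=0) + pad])
    return box


def kde_density(
    points: np.ndarray,
    bandwidth: float | None = None,
    grid_shape: tuple[int, int, int] = (25, 25, 25),
    bounding_box: np.ndarray | None = None,
    pad_bandwidths: float = 3.0,
) -> DensityField:
    """Isotropic Gaussian kernel density of a merged point cloud.

    Each point contributes a 3D Gaussian of standard deviation
    ``bandwidth`` (µm); the field is the average kernel evaluated at
    every grid node, so its Riemann sum times the voxel volume is ~1
    when the grid covers the mass.  ``bandwidth=None`` selects Scott's
    rule, n**(-1/7) times the mean per-axis SD.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError("points must be an (n, 3) array")
    n = pts.shape[0]
    if n < 2:
        raise InputError("need at least 2 points for a density estimate")
    if bandwidth is None:
        sd = float(np.mean(pts.std(axis=0, ddof=1)))
        bandwidth = sd * n ** (-1.0 / 7.0)  # Scott's rule, d = 3
    if bandwidth <= 0:
        raise AnalysisError("bandwidth must be positive (degenerate point set?)")

    if bounding_box is None:
        bounding_box = np.column_stack(
            [pts.min(axis=0) - pad_bandwidths * bandwidth, pts.max(axis=0) + pad_bandwidths * bandwidth]
        )
    box = np.asarray(bounding_box, dtype=float)
    axes = [np.linspace(box[d, 0], box[d, 1], grid_shape[d]) for d in range(3)]
    spacing = np.array([ax[1] - ax[0] if ax.size > 1 else 1.0 for ax in axes])

    # separable kernel: accumulate exp terms axis by axis
    inv2h2 = 1.0 / (2.0 * bandwidth**2)
    gx = np.exp(-((axes[0][:, None] - pts[:, 0][None, :]) ** 2) * inv2h2)  # (nx, n)
    gy = np.exp(-((axes[1][:, None] - pts[:, 1][None, :]) ** 2) * inv2h2)
    gz = np.exp(-((axes[2][:, None] - pts[:, 2][None, :]) ** 2) * inv2h2)
    values = np.einsum("xn,yn,zn->xyz", gx, gy, gz)
    values /= n * (2.0 * math.pi) ** 1.5 * bandwidth**3
    return DensityField(
        grid_origin=np.array([ax[0] for ax in axes]),
        grid_spacing=spacing,
        values=values,
        bandwidth=float(bandwidth),
    )


def voxelize(
    clouds: Sequence[PointCloud],
    cube_edge: float = 100.0,
    bounding_box: np.ndarray | None = None,
) -> VoxelGrid:
    """Partition the common bounding box into cubes and count per animal.

    Cubes are half-open ``[lo, lo + edge)`` intervals; a point exactly
    on an interior boundary goes to the higher cube.  The box must
    cover every point (compute it from the union first).
    """
    if cube_edge <= 0:
        raise InputError("cube_edge must be positive")
    if bounding_box is None:
        bounding_box = common_bounding_box(clouds)
    box = np.asarray(bounding_box, dtype=float)
    extent = box[:, 1] - box[:, 0]
    shape = tuple(int(max(math.ceil(e / cube_edge), 1)) for e in extent)

    counts: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for cloud in clouds:
        rel = cloud.coordinates - box[:, 0]
        if np.any(rel < 0) or np.any(cloud.coordinates > box[:, 1]):
            raise InputError(f"points of {cloud.animal_id} fall outside the bounding box")
        idx = np.floor(rel / cube_edge).astype(int)
        # points exactly on the upper box face land in the last cube
        idx = np.minimum(idx, np.array(shape) - 1)
        flat = np.ravel_multi_index(tuple(idx.T), shape)
        vec = np.bincount(flat, minlength=int(np.prod(shape))).astype(float)
        counts[cloud.animal_id] = vec
        groups[cloud.animal_id] = cloud.group
    return VoxelGrid(
        cube_edge=cube_edge, bounding_box=box, shape=shape, counts=counts, groups=groups
    )


def apply_density_factor(
    grid: VoxelGrid, group_a: str = "Glp1r", group_b: str = "Lepr"
) -> tuple[VoxelGrid, float]:
    """Equalize group totals with the density factor n_a / n_b.

    The factor (by default the number of Glp1r neurons over the number
    of Lepr neurons) multiplies every per-cube count of group_b, so both
    groups have the same corrected total.  Which group is rescaled is a
    parameter, as the correction direction is a convention.
    """
    total_a = grid.group_total(group_a)
    total_b = grid.group_total(group_b)
    if total_a <= 0 or total_b <= 0:
        raise AnalysisError("both groups need a positive total count")
    factor = total_a / total_b
    corrected = {
        animal: vec * factor if grid.groups[animal] == group_b else vec.copy()
        for animal, vec in grid.counts.items()
    }
    return replace(grid, counts=corrected, density_factor=factor), factor


def voxel_ttest(
    grid: VoxelGrid,
    group_a: str = "Glp1r",
    group_b: str = "Lepr",
    adjust: bool = False,
) -> VoxelTestResult:
    """Two-sided two-sample Student's t-test per cube.

    The unit of replication is the per-animal (corrected) count in the
    cube.  Cubes where both groups have zero variance and equal means
    carry no information and are flagged untested (t = 0, p = 1).  Raw
    two-sided p-values are reported; ``adjust=True`` adds a
    Benjamini–Hochberg column without changing the raw values.
    """
    a_ids = [a for a, g in grid.groups.items() if g == group_a]
    b_ids = [a for a, g in grid.groups.items() if g == group_b]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise AnalysisError("need at least 2 animals per group for a t-test")
    a = np.stack([grid.counts[i] for i in a_ids])  # (n_a, n_cubes)
    b = np.stack([grid.counts[i] for i in b_ids])

    import warnings

    with warnings.catch_warnings():
        # cubes with (near-)identical counts trip scipy's precision warning;
        # they are flagged untested below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, axis=0, equal_var=True)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0) & (a.mean(axis=0) == b.mean(axis=0))
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    tested = ~degenerate

    direction = np.where(t > 0, group_a, np.where(t < 0, group_b, ""))
    direction = np.asarray(direction, dtype=object)

    p_adj = benjamini_hochberg_adjust(p[tested]) if adjust else None
    p_adjusted = None
    if p_adj is not None:
        p_adjusted = np.ones_like(p)
        p_adjusted[tested] = p_adj
    return VoxelTestResult(
        t=t,
        p=p,
        direction=direction,
        centroids=grid.cube_centroids(),
        tested=tested,
        p_adjusted=p_adjusted,
    )


def coronal_sections(
    cloud: PointCloud, ap_slab: tuple[float, float], ap_axis: int = 2
) -> np.ndarray:
    """Project points within an antero-posterior slab onto the coronal plane.

    Returns the (n, 2) coordinates of the non-AP axes for points whose
    AP coordinate lies in ``[min, max)``.  An empty slab yields an empty
    array with a warning.
    """
    lo, hi = ap_slab
    if hi <= lo:
        raise InputError("ap_slab must have positive extent")
    ap = cloud.coordinates[:, ap_axis]
    mask = (ap >= lo) & (ap < hi)
    if not mask.any():
        import warnings

        warnings.warn(f"slab {ap_slab} contains no points of {cloud.animal_id}", stacklevel=2)
    keep_axes = [d for d in range(3) if d != ap_axis]
    return cloud.coordinates[np.ix_(mask, keep_axes)]


def projection_density(roi_name: str, raw_intensity: float, n_neurons: int) -> ProjectionDensity:
    """Projection intensity normalized to the number of labeled neurons."""
    if n_neurons <= 0:
        raise InputError("n_neurons must be positive")
    return ProjectionDensity(
        roi_name=roi_name,
        raw_intensity=float(raw_intensity),
        n_neurons=int(n_neurons),
        normalized_density=float(raw_intensity) / n_neurons,
    )
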