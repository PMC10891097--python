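"""Implant geometry and cylindrical ROI rasterization.

The implantable device carries nine circular ultrasound emitters on a flat
3x3 grid embedded in a plate that replaces a craniotomy bone flap.  Each
emitter insonifies (and opens the blood-brain barrier in) a roughly
cylindrical column of brain in front of it.  All downstream analyses --
per-emitter enhancement grading, in-field tumor volumetry, and radial
(distance-to-axis) coverage profiles -- are defined on cylindrical or
tube-shaped regions of interest anchored to the emitter axes.

Conventions
-----------
* World coordinates are millimetres, RAS+ as in NIfTI.
* Voxel indices are 0-based; a voxel belongs to a region iff its *center*
  lies inside the region.
* Volumes are voxel counts times the voxel volume |det(affine[:3,:3])|.
* The "axial coordinate" of a point with respect to an emitter is its
  signed projection onto that emitter's axis, measured from the emitter
  center (the plate plane); positive values point into the brain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "CylinderSpec",
    "EmitterArray",
    "VoxelGrid",
    "ROILabelMap",
    "DistanceMap",
    "InvalidGeometryError",
    "build_emitter_array",
    "rasterize_cylinder_rois",
    "axial_distance_map",
    "tube_shell_masks",
]

#: Emitter diameter of the implant (mm); the nine pistons are 10 mm wide.
EMITTER_DIAMETER_MM = 10.0

#: Default center-to-center spacing of the 3x3 emitter grid (mm).  The
#: implant plate replaces a 58 mm x 58 mm bone flap; 19.3 mm pitch keeps the
#: full footprint (2*pitch + diameter = 48.6 mm) inside the plate.
DEFAULT_PITCH_MM = 19.3

#: Sentinel stored in a :class:`DistanceMap` where no emitter's axial
#: extent covers the voxel.
DISTANCE_SENTINEL = np.inf


class InvalidGeometryError(ValueError):
    """Raised for geometrically impossible emitter or ROI configurations."""


@dataclass(frozen=True)
class CylinderSpec:
    """Dimensions of a sonicated cylindrical ROI.

    The native sonicated column is 10 mm diameter x 75 mm length; tumor
    field analyses extend it by a 5 mm diffusion margin (radially and at
    the distal end) to 20 mm x 80 mm.
    """

    radius_mm: float = 5.0
    length_mm: float = 75.0
    margin_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.length_mm <= 0:
            raise InvalidGeometryError("cylinder radius and length must be positive")
        if self.margin_mm < 0:
            raise InvalidGeometryError("margin must be non-negative")

    @property
    def effective_radius_mm(self) -> float:
        return self.radius_mm + self.margin_mm

    @property
    def effective_length_mm(self) -> float:
        return self.length_mm + self.margin_mm

    @property
    def analytic_volume_mm3(self) -> float:
        """Volume of one (margin-dilated) cylinder in mm^3."""
        return float(np.pi * self.effective_radius_mm**2 * self.effective_length_mm)


@dataclass(frozen=True)
class EmitterArray:
    """Positions and orientations of the nine implant emitters.

    ``centers`` lie in the plate plane; ``axes`` are unit vectors pointing
    into the brain.  Emitter ids are 1..9 in row-major plate order.
    """

    centers: np.ndarray  # (9, 3) world mm
    axes: np.ndarray  # (9, 3) unit vectors
    emitter_radius_mm: float = EMITTER_DIAMETER_MM / 2.0

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        axes = np.asarray(self.axes, dtype=float)
        if centers.shape != (9, 3) or axes.shape != (9, 3):
            raise InvalidGeometryError("an emitter array has exactly 9 centers and axes")
        if not np.allclose(np.linalg.norm(axes, axis=1), 1.0, atol=1e-9):
            raise InvalidGeometryError("emitter axes must be unit vectors")
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() <= 2 * self.emitter_radius_mm:
            raise InvalidGeometryError("emitters overlap: pairwise distance <= diameter")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "axes", axes)

    @property
    def n_emitters(self) -> int:
        return 9


def build_emitter_array(
    pitch_mm: float = DEFAULT_PITCH_MM,
    plate_center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0),
    emitter_radius_mm: float = EMITTER_DIAMETER_MM / 2.0,
) -> EmitterArray:
    """Build a flat 3x3 emitter array in the plane through ``plate_center``.

    ``normal`` points into the brain and becomes every emitter's axis (the
    flexible implant's curvature is not modeled).  Emitters are numbered
    row-major over the plate grid; with ``normal = +z`` the corner emitters
    sit at (+-pitch, +-pitch, 0) relative to the plate center.
    """
    if pitch_mm <= 2 * emitter_radius_mm:
        raise InvalidGeometryError(
            f"pitch {pitch_mm} mm must exceed the emitter diameter "
            f"{2 * emitter_radius_mm} mm"
        )
    n = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise InvalidGeometryError("normal must be nonzero")
    n = n / nn
    # deterministic in-plane frame: orthonormalize the cardinal axis least
    # aligned with the normal
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(n)))] = 1.0
    u = ref - np.dot(ref, n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    c0 = np.asarray(plate_center, dtype=float)
    offsets = [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)]
    centers = np.array([c0 + pitch_mm * (i * u + j * v) for i, j in offsets])
    axes = np.tile(n, (9, 1))
    return EmitterArray(centers=centers, axes=axes, emitter_radius_mm=emitter_radius_mm)


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D voxel lattice with a NIfTI-style voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # (4, 4)

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise InvalidGeometryError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) <= 0:
            raise InvalidGeometryError("affine must be invertible")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (n_voxels, 3)."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    @classmethod
    def isotropic(
        cls,
        shape: tuple[int, int, int],
        voxel_mm: float,
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "VoxelGrid":
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        affine[:3, 3] = origin
        return cls(shape=shape, affine=affine)


def _axial_radial_coords(
    array: EmitterArray, grid: VoxelGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Per-emitter axial (s) and radial (r) coordinates of every voxel center.

    Returns two (9, n_voxels) arrays.
    """
    x = grid.voxel_centers()  # (N, 3)
    d = x[None, :, :] - array.centers[:, None, :]  # (9, N, 3)
    s = np.einsum("kni,ki->kn", d, array.axes)  # (9, N)
    r2 = np.einsum("kni,kni->kn", d, d) - s**2
    r = np.sqrt(np.maximum(r2, 0.0))
    return s, r


@dataclass(frozen=True)
class ROILabelMap:
    """Per-emitter cylinder labels on a voxel grid (0 outside, 1..9 inside).

    Overlapping cylinders are disambiguated at construction so the nine
    per-emitter regions partition the labeled volume.
    """

    grid: VoxelGrid
    labels: np.ndarray  # uint8 volume, grid.shape

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise InvalidGeometryError("label volume shape must match grid")
        if labels.min() < 0 or labels.max() > 9:
            raise InvalidGeometryError("labels must lie in 0..9")
        object.__setattr__(self, "labels", labels.astype(np.uint8))

    def mask(self, emitter_id: int) -> np.ndarray:
        if not 1 <= emitter_id <= 9:
            raise ValueError("emitter_id must be 1..9")
        return self.labels == emitter_id

    @property
    def any_mask(self) -> np.ndarray:
        return self.labels > 0

    def volumes_mm3(self) -> np.ndarray:
        """Per-emitter labeled volume in mm^3, index 0 = emitter 1."""
        counts = np.bincount(self.labels.ravel(), minlength=10)[1:10]
        return counts * self.grid.voxel_volume_mm3

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.labels.astype(np.uint8), self.grid.affine)


def rasterize_cylinder_rois(
    array: EmitterArray, grid: VoxelGrid, spec: CylinderSpec
) -> ROILabelMap:
    """Label voxels by the emitter cylinder containing their center.

    A voxel belongs to cylinder ``k`` iff its radial distance to axis ``k``
    is <= radius+margin and its axial coordinate lies in [0, length+margin].
    Where dilated cylinders overlap, the voxel goes to the nearest axis
    (ties to the lowest emitter id) so per-emitter regions are disjoint.
    """
    s, r = _axial_radial_coords(array, grid)
    inside = (
        (r <= spec.effective_radius_mm)
        & (s >= 0.0)
        & (s <= spec.effective_length_mm)
    )
    labels = np.zeros(grid.n_voxels, dtype=np.uint8)
    best_r = np.full(grid.n_voxels, np.inf)
    for k in range(9):  # ascending id: strict < keeps the lowest id on ties
        sel = inside[k] & (r[k] < best_r)
        labels[sel] = k + 1
        best_r[sel] = r[k][sel]
    if not labels.any():
        warnings.warn("no cylinder intersects the voxel grid", stacklevel=2)
    return ROILabelMap(grid=grid, labels=labels.reshape(grid.shape))


@dataclass(frozen=True)
class DistanceMap:
    """Minimum radial distance (mm) to the nearest in-range emitter axis.

    Voxels whose axial coordinate falls outside [0, max_length] for every
    emitter carry the sentinel ``inf``.
    """

    grid: VoxelGrid
    radial_mm: np.ndarray  # float volume, grid.shape
    max_length_mm: float = field(default=75.0)

    def __post_init__(self) -> None:
        radial = np.asarray(self.radial_mm, dtype=np.float64)
        if radial.shape != self.grid.shape:
            raise InvalidGeometryError("distance volume shape must match grid")
        finite = radial[np.isfinite(radial)]
        if finite.size and finite.min() < 0:
            raise InvalidGeometryError("radial distances must be non-negative")
        object.__setattr__(self, "radial_mm", radial)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.radial_mm)

    def to_nifti(self) -> nib.Nifti1Image:
        out = np.where(np.isfinite(self.radial_mm), self.radial_mm, -1.0)
        return nib.Nifti1Image(out.astype(np.float32), self.grid.affine)


def axial_distance_map(
    array: EmitterArray, grid: VoxelGrid, max_length_mm: float = 75.0
) -> DistanceMap:
    """Per-voxel minimum distance to any emitter axis within its axial extent.

    Only emitters whose axial coordinate for the voxel lies in
    [0, max_length] participate in the minimum; the sentinel ``inf`` marks
    voxels outside every emitter's axial range.
    """
    if max_length_mm <= 0:
        raise InvalidGeometryError("max_length must be positive")
    s, r = _axial_radial_coords(array, grid)
    r = np.where((s >= 0.0) & (s <= max_length_mm), r, np.inf)
    radial = r.min(axis=0).reshape(grid.shape)
    return DistanceMap(grid=grid, radial_mm=radial, max_length_mm=max_length_mm)


def tube_shell_masks(dmap: DistanceMap, bin_edges: np.ndarray) -> list[np.ndarray]:
    """Disjoint tube-shaped ("ring") masks between successive radial edges.

    Mask ``i`` selects voxels with radial distance in [edge_i, edge_{i+1});
    the masks partition the tube between the first and last edge.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("need at least two bin edges")
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    return [
        (dmap.radial_mm >= lo) & (dmap.radial_mm < hi)
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
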