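"""Volume grids and in-memory containers for maps, masks and BOLD series.

All volumes in one analysis live on a single template grid: a voxel lattice
with a NIfTI-style 4x4 affine mapping 0-based voxel indices to MNI mm
coordinates.  No resampling is implemented; grids must match exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeGrid",
    "ScalarMap",
    "BinaryMask",
    "BoldSeries",
    "MAP_KINDS",
]

#: recognised semantic labels for 3D maps
MAP_KINDS = frozenset(
    {"degree_raw", "degree_z", "tstat", "gc_f", "gc_z", "gm_prob", "scalar"}
)

# affines within this (mm) are treated as equal across subjects
_AFFINE_ATOL = 1e-4


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel lattice in template (MNI) space.

    Parameters
    ----------
    dims : tuple of 3 int
        Voxels along each axis.
    affine : (4, 4) ndarray
        Maps homogeneous 0-based voxel indices to mm coordinates
        (NIfTI sform convention).
    """

    dims: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        affine = np.array(self.affine, dtype=float, copy=True)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", affine)
        affine.setflags(write=False)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be strictly positive")

    @classmethod
    def from_spacing(
        cls,
        dims: tuple[int, int, int],
        voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
        origin_mm: tuple[float, float, float] = (-27.0, -18.0, -21.0),
    ) -> "VolumeGrid":
        """Axis-aligned grid with given spacing and voxel-(0,0,0) mm origin."""
        affine = np.eye(4)
        affine[:3, :3] = np.diag(voxel_size)
        affine[:3, 3] = origin_mm
        return cls(tuple(dims), affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel spacing per axis in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def voxel_to_mm(self, ijk) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return self.affine[:3, :3] @ ijk + self.affine[:3, 3]

    def mm_to_voxel(self, xyz_mm, *, check_bounds: bool = True) -> tuple[int, int, int]:
        """Nearest voxel index for an MNI mm coordinate.

        Raises ``ValueError`` if the rounded index falls outside the grid
        (unless ``check_bounds`` is False).
        """
        xyz = np.asarray(xyz_mm, dtype=float)
        ijk = np.linalg.solve(self.affine[:3, :3], xyz - self.affine[:3, 3])
        idx = tuple(int(i) for i in np.round(ijk))
        if check_bounds and any(
            not (0 <= idx[a] < self.dims[a]) for a in range(3)
        ):
            raise ValueError(
                f"mm coordinate {tuple(xyz)} maps to voxel {idx}, outside grid {self.dims}"
            )
        return idx

    def sphere(self, center_mm, radius_mm: float) -> np.ndarray:
        """Boolean array marking voxels whose centers lie within radius of a point."""
        if radius_mm <= 0:
            raise ValueError("radius must be positive")
        center = np.asarray(center_mm, dtype=float)
        ii, jj, kk = np.meshgrid(
            np.arange(self.dims[0]),
            np.arange(self.dims[1]),
            np.arange(self.dims[2]),
            indexing="ij",
        )
        vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).T
        mm = self.affine[:3, :3] @ vox + self.affine[:3, 3][:, None]
        d2 = ((mm - center[:, None]) ** 2).sum(axis=0)
        return (d2 <= radius_mm**2).reshape(self.dims)

    def matches(self, other: "VolumeGrid") -> bool:
        """Exact dim equality and affine agreement within 1e-4 mm."""
        return self.dims == other.dims and bool(
            np.allclose(self.affine, other.affine, atol=_AFFINE_ATOL)
        )

    def __eq__(self, other):
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.matches(other)

    def __hash__(self):
        return hash((self.dims, self.affine.round(6).tobytes()))


def _require_same_grid(a: VolumeGrid, b: VolumeGrid, what: str = "volumes"):
    if not a.matches(b):
        raise ValueError(f"{what} are on different grids: {a.dims} vs {b.dims}")


@dataclass
class ScalarMap:
    """One 3D statistic/probability map on a grid."""

    grid: VolumeGrid
    data: np.ndarray
    kind: str = "scalar"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"map shape {self.data.shape} does not match grid {self.grid.dims}"
            )
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")


@dataclass
class BinaryMask:
    """Boolean voxel selection on a grid."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.data.shape} does not match grid {self.grid.dims}"
            )

    @property
    def n_true(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """(n_true, 3) voxel indices in C order (the canonical mask order)."""
        return np.argwhere(self.data)

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        _require_same_grid(self.grid, other.grid, "masks")
        return BinaryMask(self.grid, self.data & other.data)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        _require_same_grid(self.grid, other.grid, "masks")
        return BinaryMask(self.grid, self.data | other.data)


@dataclass
class BoldSeries:
    """One subject's 4D BOLD time series (x, y, z, t) on a grid."""

    grid: VolumeGrid
    data: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.data.shape[:3] != self.grid.dims:
            raise ValueError(
                f"BOLD spatial shape {self.data.shape[:3]} does not match grid {self.grid.dims}"
            )
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[3])

    def masked_timeseries(self, mask: BinaryMask) -> np.ndarray:
        """(T, N) matrix of in-mask voxel time courses, in mask C-order."""
        _require_same_grid(self.grid, mask.grid)
        return np.ascontiguousarray(self.data[mask.data].T)
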