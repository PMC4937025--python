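"""Voxel-wise degree centrality.

For each gray-matter voxel i the time course is Pearson-correlated with
every other mask voxel j; correlations r_ij > r_threshold (strictly; 0.25
by default) define edges.  Degree is either the edge count (binarized) or
the sum of suprathreshold r values (weighted).  Negative correlations never
contribute.  The degree map D is standardised to Z_i = (D_i - mean(D)) / sd(D)
over mask voxels, with the population (divide-by-N) standard deviation, so
every subject's Z map has in-mask mean 0 and SD 1 exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import BinaryMask, BoldSeries, ScalarMap

__all__ = [
    "DegreeResult",
    "DegreeCentralityModel",
    "voxel_correlations",
    "degree_map",
    "block_degree_map",
]


def _standardized_timeseries(bold: BoldSeries, mask: BinaryMask, dtype=np.float64):
    """(T, N) matrix with columns centred and scaled so X.T @ X = corr matrix.

    Zero-variance voxels become all-zero columns (no edges).  Returns the
    matrix and the boolean vector of zero-variance voxels.
    """
    X = bold.masked_timeseries(mask).astype(np.float64)
    X = X - X.mean(axis=0)
    norms = np.sqrt((X**2).sum(axis=0))
    degenerate = norms == 0
    norms[degenerate] = 1.0
    X /= norms
    X[:, degenerate] = 0.0
    return X.astype(dtype, copy=False), degenerate


def voxel_correlations(bold: BoldSeries, mask: BinaryMask, voxel: tuple[int, int, int]) -> np.ndarray:
    """Pearson correlation of one in-mask voxel with every mask voxel.

    Returned in mask C-order (the query voxel's own entry is 1, excluded
    downstream).  A zero-variance query voxel is flagged with a warning and
    yields all-zero correlations (no edges).
    """
    if not mask.data[tuple(voxel)]:
        raise ValueError(f"voxel {voxel} is not inside the mask")
    if bold.n_volumes < 3:
        raise ValueError("need at least 3 frames")
    X, degenerate = _standardized_timeseries(bold, mask)
    order = mask.indices()
    pos = int(np.flatnonzero((order == np.asarray(voxel)).all(axis=1))[0])
    if degenerate[pos]:
        warnings.warn(f"voxel {voxel} has zero variance; no edges", RuntimeWarning)
        return np.zeros(mask.n_true)
    r = X.T @ X[:, pos]
    r[pos] = 1.0
    return r


def _finalize(bold, mask, D, flavor, r_threshold, dtype) -> "DegreeResult":
    D = np.asarray(D, dtype=float)
    mean_d = float(D.mean())
    sd_d = float(D.std())  # population SD: standardises this fixed map
    if sd_d == 0:
        warnings.warn("degree map has zero variance; z map set to 0", RuntimeWarning)
        Z = np.zeros_like(D)
    else:
        Z = (D - mean_d) / sd_d
    raw3d = np.zeros(bold.grid.dims)
    z3d = np.zeros(bold.grid.dims)
    raw3d[mask.data] = D
    z3d[mask.data] = Z
    return DegreeResult(
        raw=ScalarMap(bold.grid, raw3d, kind="degree_raw"),
        z=ScalarMap(bold.grid, z3d, kind="degree_z"),
        flavor=flavor,
        r_threshold=r_threshold,
        mask=mask,
        mean_degree=mean_d,
        sd_degree=sd_d,
    )


def degree_map(
    bold: BoldSeries,
    mask: BinaryMask,
    r_threshold: float = 0.25,
    flavor: str = "weighted",
    dtype=np.float64,
) -> "DegreeResult":
    """Degree-centrality map over a mask (full correlation-matrix route).

    ``dtype=np.float32`` halves the matmul cost for large masks; the default
    double precision is used by all oracle comparisons.
    """
    _check_args(mask, r_threshold, flavor)
    X, _ = _standardized_timeseries(bold, mask, dtype=dtype)
    Xf = np.asfortranarray(X)  # F-order keeps the single-threaded gemm fast
    R = Xf.T @ Xf
    np.fill_diagonal(R, 0.0)  # self-correlation excluded
    A = R > r_threshold
    if flavor == "binarized":
        D = A.sum(axis=1, dtype=np.int64).astype(np.float64)
    else:
        D = np.where(A, R, 0).sum(axis=1, dtype=np.float64)
    return _finalize(bold, mask, D, flavor, r_threshold, dtype)


def block_degree_map(
    bold: BoldSeries,
    mask: BinaryMask,
    r_threshold: float = 0.25,
    flavor: str = "weighted",
    block_size: int = 1024,
    dtype=np.float64,
) -> "DegreeResult":
    """Same result as :func:`degree_map`, computed in row blocks.

    Never materialises the full N x N correlation matrix; memory is
    O(block_size x N).
    """
    _check_args(mask, r_threshold, flavor)
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    X, _ = _standardized_timeseries(bold, mask, dtype=dtype)
    N = X.shape[1]
    D = np.zeros(N)
    for start in range(0, N, block_size):
        stop = min(start + block_size, N)
        Rb = (X[:, start:stop].T @ X).astype(np.float64)
        rows = np.arange(start, stop)
        Rb[rows - start, rows] = 0.0
        Ab = Rb > r_threshold
        if flavor == "binarized":
            D[start:stop] = Ab.sum(axis=1)
        else:
            D[start:stop] = np.where(Ab, Rb, 0.0).sum(axis=1)
    return _finalize(bold, mask, D, flavor, r_threshold, dtype)


def _check_args(mask, r_threshold, flavor):
    if mask.n_true < 2:
        raise ValueError("degree centrality needs at least 2 mask voxels")
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must be in (0, 1)")
    if flavor not in ("binarized", "weighted"):
        raise ValueError("flavor must be 'binarized' or 'weighted'")


@dataclass
class DegreeResult:
    """Per-subject degree-centrality maps (raw D and standardised Z)."""

    raw: ScalarMap
    z: ScalarMap
    flavor: str
    r_threshold: float
    mask: BinaryMask
    mean_degree: float
    sd_degree: float

    def masked_raw(self) -> np.ndarray:
        return self.raw.data[self.mask.data]

    def masked_z(self) -> np.ndarray:
        return self.z.data[self.mask.data]

    def summary(self) -> str:
        d = self.masked_raw()
        lines = [
            "Degree centrality result",
            f"  flavor        : {self.flavor}",
            f"  r threshold   : > {self.r_threshold}",
            f"  mask voxels   : {self.mask.n_true}",
            f"  mean degree   : {self.mean_degree:.4f}",
            f"  sd degree     : {self.sd_degree:.4f}",
            f"  max degree    : {d.max():.4f}",
        ]
        return "\n".join(lines)


class DegreeCentralityModel:
    """Degree-centrality hub mapping for one subject.

    Parameters
    ----------
    bold : BoldSeries
        Preprocessed BOLD series.
    mask : BinaryMask
        Gray-matter mask restricting the correlation graph.
    r_threshold : float
        Edge threshold (strict ``r >``); suprathreshold positive
        correlations define the graph.
    flavor : {"weighted", "binarized"}
        Sum of edge weights vs edge count.
    """

    def __init__(self, bold, mask, r_threshold: float = 0.25, flavor: str = "weighted"):
        _check_args(mask, r_threshold, flavor)
        self.bold = bold
        self.mask = mask
        self.r_threshold = r_threshold
        self.flavor = flavor

    def fit(self, block_size: int | None = None, dtype=np.float64) -> DegreeResult:
        if block_size is None:
            return degree_map(self.bold, self.mask, self.r_threshold, self.flavor, dtype=dtype)
        return block_degree_map(
            self.bold, self.mask, self.r_threshold, self.flavor, block_size, dtype=dtype
        )
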