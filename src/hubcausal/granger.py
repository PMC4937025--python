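"""Seed-to-whole-brain bivariate Granger causality mapping.

For a seed time series x and each voxel time series y, two vector
autoregressions of order p are compared per direction.  For x -> y the
restricted model regresses y_t on an intercept and its own p lags; the full
model adds x's p lags.  The residual-based statistic is

    F = [(RSS_restricted - RSS_full) / p] / [RSS_full / (T - 2p - 1)]

with T the series length, clamped at 0.  The reverse direction swaps roles.
Each direction's F map is standardised over mask voxels (subtract the
global mean, divide by the standard deviation) to give the Z maps used in
group inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import BinaryMask, BoldSeries, ScalarMap

__all__ = [
    "SeedSeries",
    "GCResult",
    "SeedGrangerModel",
    "extract_seed",
    "bivariate_gc",
    "gc_map",
]


@dataclass
class SeedSeries:
    """Mean time course of a spherical seed region."""

    values: np.ndarray
    center: tuple[float, float, float]
    radius_mm: float
    n_voxels: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("seed series must be 1D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("seed series contains non-finite values")
        if self.n_voxels < 1:
            raise ValueError("seed must average at least one voxel")


def extract_seed(
    bold: BoldSeries,
    center_mni: tuple[float, float, float],
    radius_mm: float,
    mask: BinaryMask,
) -> SeedSeries:
    """Mean time course over in-mask voxels within radius of an MNI point."""
    sphere = bold.grid.sphere(center_mni, radius_mm) & mask.data
    n = int(sphere.sum())
    if n == 0:
        raise ValueError(
            f"seed sphere at {tuple(center_mni)} (r={radius_mm} mm) contains no mask voxels"
        )
    series = bold.data[sphere].mean(axis=0)
    return SeedSeries(series, tuple(float(c) for c in center_mni), float(radius_mm), n)


def _lag_matrix(series: np.ndarray, order: int) -> np.ndarray:
    """(T - order, order) matrix of lags 1..p aligned to targets series[p:]."""
    T = len(series)
    return np.column_stack([series[order - l : T - l] for l in range(1, order + 1)])


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _f_from_rss(rss_r: float, rss_f: float, order: int, T: int) -> float:
    df2 = T - 2 * order - 1
    if rss_f <= 0:
        # exact linear dependence: infinite evidence, report a large finite F
        return float((rss_r * df2) / order / max(rss_f, np.finfo(float).tiny))
    return max(0.0, ((rss_r - rss_f) / order) / (rss_f / df2))


def bivariate_gc(
    x: SeedSeries | np.ndarray, y: np.ndarray, order: int = 1
) -> tuple[float, float, bool]:
    """Directional F statistics for one seed/voxel pair.

    Returns ``(F_x_to_y, F_y_to_x, degenerate)``; a constant series makes the
    regressions singular, in which case both F are 0 and the flag is set.
    """
    xv = x.values if isinstance(x, SeedSeries) else np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    T = len(xv)
    if order < 1:
        raise ValueError("order must be >= 1")
    if T <= 2 * order + 2:
        raise ValueError(f"series length {T} too short for order {order}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return 0.0, 0.0, True
    ones = np.ones(T - order)
    xl, yl = _lag_matrix(xv, order), _lag_matrix(yv, order)
    # x -> y
    rss_r = _ols_rss(np.column_stack([ones, yl]), yv[order:])
    rss_f = _ols_rss(np.column_stack([ones, yl, xl]), yv[order:])
    f_xy = _f_from_rss(rss_r, rss_f, order, T)
    # y -> x
    rss_r = _ols_rss(np.column_stack([ones, xl]), xv[order:])
    rss_f = _ols_rss(np.column_stack([ones, xl, yl]), xv[order:])
    f_yx = _f_from_rss(rss_r, rss_f, order, T)
    return f_xy, f_yx, False


def _batched_rss(shared: np.ndarray, pervox: np.ndarray | None, targets: np.ndarray) -> np.ndarray:
    """RSS of per-voxel OLS with shared regressors plus per-voxel lag blocks.

    shared : (n, s) regressors common to all voxels (intercept, seed lags...)
    pervox : (n, p, N) per-voxel regressors, or None
    targets : (n, N) per-voxel targets, or (n,) shared target
    """
    n, s = shared.shape
    if pervox is None:
        beta, *_ = np.linalg.lstsq(shared, targets, rcond=None)
        resid = targets - shared @ beta
        return np.atleast_1d((resid**2).sum(axis=0))
    p, N = pervox.shape[1], pervox.shape[2]
    k = s + p
    G = np.empty((N, k, k))
    G[:, :s, :s] = shared.T @ shared
    sTp = np.einsum("ns,npv->vsp", shared, pervox, optimize=True)
    G[:, :s, s:] = sTp
    G[:, s:, :s] = sTp.transpose(0, 2, 1)
    G[:, s:, s:] = np.einsum("npv,nqv->vpq", pervox, pervox, optimize=True)
    b = np.empty((N, k))
    if targets.ndim == 1:
        b[:, :s] = (shared.T @ targets)[None, :]
        b[:, s:] = np.einsum("npv,n->vp", pervox, targets, optimize=True)
        yty = float(targets @ targets)
    else:
        b[:, :s] = (shared.T @ targets).T
        b[:, s:] = np.einsum("npv,nv->vp", pervox, targets, optimize=True)
        yty = (targets**2).sum(axis=0)
    # tiny ridge keeps near-singular voxel systems solvable; flagged upstream
    G += np.eye(k) * 1e-12
    try:
        beta = np.linalg.solve(G, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.stack([np.linalg.lstsq(G[v], b[v], rcond=None)[0] for v in range(N)])
    rss = yty - np.einsum("vk,vk->v", beta, b)
    return np.maximum(rss, 0.0)


def gc_map(
    bold: BoldSeries,
    seed: SeedSeries,
    mask: BinaryMask,
    order: int = 1,
) -> "GCResult":
    """Bivariate GC maps from a seed to every mask voxel, both directions."""
    x = seed.values
    T = bold.n_volumes
    if len(x) != T:
        raise ValueError("seed series length does not match BOLD series")
    if T <= 2 * order + 2:
        raise ValueError(f"series length {T} too short for order {order}")
    Y = bold.masked_timeseries(mask)  # (T, N)
    N = Y.shape[1]
    degenerate = np.ptp(Y, axis=0) == 0
    seed_degenerate = np.ptp(x) == 0
    n = T - order
    ones = np.ones((n, 1))
    xl = _lag_matrix(x, order)  # (n, p)
    # (n, p, N) per-voxel lag stack
    yl = np.empty((n, order, N))
    for l in range(1, order + 1):
        yl[:, l - 1, :] = Y[order - l : T - l, :]
    yt = Y[order:, :]  # (n, N)
    xt = x[order:]

    # x -> y: restricted = [1, ylags]; full = [1, xlags, ylags]
    rss_r_xy = _batched_rss(ones, yl, yt)
    rss_f_xy = _batched_rss(np.column_stack([ones, xl]), yl, yt)
    # y -> x: restricted = [1, xlags] (shared); full adds per-voxel ylags
    rss_r_yx = _batched_rss(np.column_stack([ones, xl]), None, xt)[0]
    rss_f_yx = _batched_rss(np.column_stack([ones, xl]), yl, xt)

    df2 = T - 2 * order - 1
    tiny = np.finfo(float).tiny
    f_xy = np.maximum(0.0, ((rss_r_xy - rss_f_xy) / order) / (np.maximum(rss_f_xy, tiny) / df2))
    f_yx = np.maximum(0.0, ((rss_r_yx - rss_f_yx) / order) / (np.maximum(rss_f_yx, tiny) / df2))
    if seed_degenerate:
        degenerate = np.ones(N, dtype=bool)
        warnings.warn("seed series has zero variance; all F set to 0", RuntimeWarning)
    f_xy[degenerate] = 0.0
    f_yx[degenerate] = 0.0
    n_flagged = int(degenerate.sum())
    if n_flagged and not seed_degenerate:
        warnings.warn(f"{n_flagged} zero-variance voxels flagged; F set to 0", RuntimeWarning)

    def _zmap(f):
        sd = f.std()
        return (f - f.mean()) / sd if sd > 0 else np.zeros_like(f)

    def _to_map(vals, kind):
        out = np.zeros(bold.grid.dims)
        out[mask.data] = vals
        return ScalarMap(bold.grid, out, kind=kind)

    flags3d = np.zeros(bold.grid.dims, dtype=bool)
    flags3d[mask.data] = degenerate
    return GCResult(
        f_xy=_to_map(f_xy, "gc_f"),
        f_yx=_to_map(f_yx, "gc_f"),
        z_xy=_to_map(_zmap(f_xy), "gc_z"),
        z_yx=_to_map(_zmap(f_yx), "gc_z"),
        seed_center=seed.center,
        seed_radius_mm=seed.radius_mm,
        order=order,
        mask=mask,
        flagged=BinaryMask(bold.grid, flags3d),
    )


@dataclass
class GCResult:
    """Directional influence maps for one subject and one seed."""

    f_xy: ScalarMap
    f_yx: ScalarMap
    z_xy: ScalarMap
    z_yx: ScalarMap
    seed_center: tuple[float, float, float]
    seed_radius_mm: float
    order: int
    mask: BinaryMask
    flagged: BinaryMask

    def summary(self) -> str:
        fx = self.f_xy.data[self.mask.data]
        fy = self.f_yx.data[self.mask.data]
        return "\n".join(
            [
                "Granger causality result",
                f"  seed center   : {self.seed_center} mm (r={self.seed_radius_mm} mm)",
                f"  model order   : {self.order}",
                f"  mask voxels   : {self.mask.n_true}",
                f"  flagged voxels: {self.flagged.n_true}",
                f"  mean F x->y   : {fx.mean():.4f} (max {fx.max():.2f})",
                f"  mean F y->x   : {fy.mean():.4f} (max {fy.max():.2f})",
            ]
        )


class SeedGrangerModel:
    """Seed-based effective-connectivity mapping for one subject.

    Parameters
    ----------
    bold : BoldSeries
        Preprocessed BOLD series.
    mask : BinaryMask
        Analysis mask (gray matter).
    seed_center : mm triple
        MNI coordinate of the seed sphere center.
    seed_radius_mm : float
        Seed sphere radius (mean time course over in-mask voxels).
    order : int
        Autoregression order p.
    """

    def __init__(self, bold, mask, seed_center, seed_radius_mm: float = 6.0, order: int = 1):
        self.bold = bold
        self.mask = mask
        self.seed_center = tuple(float(c) for c in seed_center)
        self.seed_radius_mm = float(seed_radius_mm)
        self.order = int(order)

    def fit(self) -> GCResult:
        seed = extract_seed(self.bold, self.seed_center, self.seed_radius_mm, self.mask)
        return gc_map(self.bold, seed, self.mask, order=self.order)
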