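"""Temporal/spatial preprocessing of template-space BOLD series.

Stage order follows the protocol listing: discard initial volumes ->
spatial smoothing -> linear detrend -> band-pass.  Registration steps
(slice timing, realignment, normalisation) are out of scope: inputs are
already on a common template grid.  Motion QC consumes realignment
parameter files and only flags subjects for exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, BoldSeries, ScalarMap

__all__ = [
    "MotionTrace",
    "MotionQC",
    "discard_initial",
    "motion_qc",
    "detrend_linear",
    "bandpass",
    "smooth_gaussian",
    "gm_mask_from_prob",
    "preprocess_bold",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion parameters."""

    translations: np.ndarray  # (T, 3) mm
    rotations: np.ndarray  # (T, 3) degrees

    def __post_init__(self):
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be (T, 3)")
        if len(self.translations) == 0:
            raise ValueError("motion trace is empty")

    @property
    def n_volumes(self) -> int:
        return len(self.translations)


@dataclass
class MotionQC:
    passed: bool
    max_translation_mm: float
    max_rotation_deg: float
    limit_mm: float
    limit_deg: float


def discard_initial(bold: BoldSeries, n: int) -> BoldSeries:
    """Drop the first ``n`` volumes (signal-equilibration frames)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= bold.n_volumes:
        raise ValueError(f"cannot discard {n} of {bold.n_volumes} volumes")
    if n == 0:
        return BoldSeries(bold.grid, bold.data.copy(), tr_seconds=bold.tr_seconds)
    return BoldSeries(bold.grid, bold.data[..., n:].copy(), tr_seconds=bold.tr_seconds)


def motion_qc(trace: MotionTrace, limit_mm: float = 2.0, limit_deg: float = 2.0) -> MotionQC:
    """Fail iff any per-axis |translation| > limit_mm or |rotation| > limit_deg.

    Limits are strict: a value exactly at the limit passes.
    """
    max_t = float(np.abs(trace.translations).max())
    max_r = float(np.abs(trace.rotations).max())
    passed = not (max_t > limit_mm or max_r > limit_deg)
    return MotionQC(passed, max_t, max_r, limit_mm, limit_deg)


def detrend_linear(bold: BoldSeries) -> BoldSeries:
    """Remove the per-voxel least-squares line (intercept + slope)."""
    T = bold.n_volumes
    if T < 3:
        raise ValueError("detrending needs at least 3 frames")
    t = np.arange(T, dtype=float)
    t -= t.mean()
    data = np.asarray(bold.data, dtype=float)
    mean = data.mean(axis=3, keepdims=True)
    slope = (data @ t) / (t @ t)
    out = data - mean - slope[..., None] * t
    return BoldSeries(bold.grid, out, tr_seconds=bold.tr_seconds)


def bandpass(bold: BoldSeries, low_hz: float, high_hz: float) -> BoldSeries:
    """Ideal (rectangular) frequency-domain band-pass along time.

    DFT bins with ``low_hz <= f <= high_hz`` are retained, all others
    (including the DC bin when ``low_hz > 0``) are zeroed.
    """
    nyquist = 1.0 / (2.0 * bold.tr_seconds)
    if not 0 <= low_hz < high_hz < nyquist:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for TR {bold.tr_seconds}s"
        )
    T = bold.n_volumes
    freqs = np.fft.rfftfreq(T, d=bold.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(np.asarray(bold.data, dtype=float), axis=3)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=3)
    return BoldSeries(bold.grid, out, tr_seconds=bold.tr_seconds)


def _sigma_voxels(grid, fwhm_mm: float) -> np.ndarray:
    return fwhm_mm * FWHM_TO_SIGMA / grid.voxel_size


def smooth_gaussian(obj: ScalarMap | BoldSeries, fwhm_mm: float):
    """Isotropic (in mm) Gaussian smoothing; zero padding outside the volume.

    ``fwhm_mm = 0`` is the identity.  For 4D series each frame is smoothed
    independently.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        data = np.array(obj.data, dtype=float, copy=True)
    else:
        sigma = _sigma_voxels(obj.grid, fwhm_mm)
        data = np.asarray(obj.data, dtype=float)
        if data.ndim == 4:
            out = np.empty_like(data)
            ndimage.gaussian_filter(
                data, sigma=(*sigma, 0.0), mode="constant", cval=0.0, output=out
            )
            data = out
        else:
            data = ndimage.gaussian_filter(data, sigma=sigma, mode="constant", cval=0.0)
    if isinstance(obj, BoldSeries):
        return BoldSeries(obj.grid, data, tr_seconds=obj.tr_seconds)
    return ScalarMap(obj.grid, data, kind=obj.kind)


def smooth_masked(data: np.ndarray, mask: np.ndarray, grid, fwhm_mm: float) -> np.ndarray:
    """Smooth within a mask, renormalising by the smoothed mask.

    Avoids the edge attenuation of plain zero-padded smoothing; used by the
    Monte-Carlo null simulations.
    """
    if fwhm_mm == 0:
        return np.where(mask, data, 0.0)
    sigma = _sigma_voxels(grid, fwhm_mm)
    maskf = mask.astype(float)
    num = ndimage.gaussian_filter(data * maskf, sigma=sigma, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(maskf, sigma=sigma, mode="constant", cval=0.0)
    out = np.zeros_like(num)
    inside = mask.astype(bool)
    out[inside] = num[inside] / den[inside]
    return out


def gm_mask_from_prob(prob: ScalarMap, threshold: float = 0.20) -> BinaryMask:
    """Gray-matter mask: probability strictly greater than ``threshold``."""
    data = np.asarray(prob.data, dtype=float)
    if data.min() < 0 or data.max() > 1:
        raise ValueError("gray-matter probabilities must lie in [0, 1]")
    return BinaryMask(prob.grid, data > threshold)


def preprocess_bold(
    bold: BoldSeries,
    discard: int = 10,
    fwhm_mm: float = 6.0,
    band: tuple[float, float] = (0.01, 0.08),
) -> BoldSeries:
    """Full preprocessing chain: discard -> smooth -> detrend -> band-pass."""
    out = discard_initial(bold, discard)
    out = smooth_gaussian(out, fwhm_mm)
    out = detrend_linear(out)
    out = bandpass(out, band[0], band[1])
    if not np.all(np.isfinite(out.data)):
        raise ValueError("non-finite values after preprocessing")
    return out
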