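"""Run configuration: every numeric default of the analysis in one place.

Defaults mirror the study protocol this pipeline implements: correlation
threshold r > 0.25, gray-matter probability > 20%, voxel-wise p = 0.01 with
a Monte-Carlo corrected alpha of 0.01 over 5000 simulations, cluster
connection radius 5 mm, 6 mm FWHM smoothing, 0.01-0.08 Hz band-pass,
10 discarded volumes, 2.0 mm / 2.0 deg motion limits, lag-1 Granger model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

__all__ = ["StudyConfig", "load_config", "save_config"]


@dataclass
class StudyConfig:
    r_threshold: float = 0.25
    gm_prob_threshold: float = 0.20
    voxel_p: float = 0.01
    corrected_alpha: float = 0.01
    n_mc_sims: int = 5000
    fwhm_mm: float = 6.0
    connect_radius_mm: float = 5.0
    min_cluster_voxels: int = 40
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    discard_volumes: int = 10
    motion_limit_mm: float = 2.0
    motion_limit_deg: float = 2.0
    gc_order: int = 1
    seed_radius_mm: float = 6.0
    dc_flavor: str = "weighted"
    tr_seconds: float = 2.0
    rng_seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must be in (0, 1)")
        if not 0 <= self.gm_prob_threshold < 1:
            raise ValueError("gm_prob_threshold must be in [0, 1)")
        for name in ("voxel_p", "corrected_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_mc_sims < 1:
            raise ValueError("n_mc_sims must be positive")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")
        if self.connect_radius_mm <= 0:
            raise ValueError("connect_radius_mm must be positive")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not 0 <= self.band_low_hz < self.band_high_hz < nyquist:
            raise ValueError(
                f"band ({self.band_low_hz}, {self.band_high_hz}) Hz invalid for "
                f"TR {self.tr_seconds}s (Nyquist {nyquist} Hz)"
            )
        if self.discard_volumes < 0:
            raise ValueError("discard_volumes must be non-negative")
        if self.motion_limit_mm <= 0 or self.motion_limit_deg <= 0:
            raise ValueError("motion limits must be positive")
        if self.gc_order < 1:
            raise ValueError("gc_order must be >= 1")
        if self.seed_radius_mm <= 0:
            raise ValueError("seed_radius_mm must be positive")
        if self.dc_flavor not in ("binarized", "weighted"):
            raise ValueError("dc_flavor must be 'binarized' or 'weighted'")


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(StudyConfig)}


def load_config(path: str | Path) -> StudyConfig:
    """Read a ``key = value`` text file into a :class:`StudyConfig`.

    Unknown keys are rejected; missing keys keep their defaults.
    Lines starting with ``#`` and blank lines are ignored.
    """
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in _FIELD_TYPES:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key == "dc_flavor":
            kwargs[key] = value
        elif key in ("n_mc_sims", "min_cluster_voxels", "discard_volumes", "gc_order", "rng_seed"):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return StudyConfig(**kwargs)


def save_config(config: StudyConfig, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"{f.name} = {getattr(config, f.name)}" for f in dataclasses.fields(StudyConfig)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path
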