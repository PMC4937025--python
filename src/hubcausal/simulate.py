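"""Synthetic two-group resting-state BOLD cohort generator.

Generates a desk-scale cohort with the statistical structure the analysis
assumes: 24 tinnitus patients and 22 controls by default, TR = 2 s, 240
volumes on a 20x24x20 grid of 3 mm voxels in template space.  The signal
model per subject is

  * spatially white voxel-wise AR(1) Gaussian noise (coefficient 0.3),
    variance-scaled so that preprocessing's 6 mm smoothing brings it to unit
    variance at exactly the smoothness the cluster-level null assumes,
  * a small per-voxel linear drift,
  * 4 cohort-level low-frequency (0.01-0.08 Hz) network signals, orthonormal
    per subject over the retained window, mixed into gray matter with smooth
    random spatial loadings (shared across subjects so group-mean hub maps
    are stable),
  * patient-only injected effects: elevated hub connectivity in two mirrored
    spheres at (+/-18, 42, 27) and a lag-1 directed coupling from each hub
    sphere to a target sphere, with THQ scores correlated to the per-patient
    coupling strength.

Demographics are drawn to match the study's group summaries (age
50.8 +/- 12.4 vs 44.7 +/- 15.4 years, education 12.3 +/- 3.1 vs
13.4 +/- 3.8, sex 9:15 vs 9:13 odds, THQ 49.5 +/- 15.5, duration
46.5 +/- 39.1 months, hearing thresholds < 25 dB HL), truncated to the
printed ranges.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .grids import BoldSeries, ScalarMap, VolumeGrid
from .io import write_motion_trace, write_subjects_table, write_volume
from .preprocess import MotionTrace, smooth_gaussian

__all__ = ["EffectSpec", "Cohort", "generate_cohort", "inject_hub",
           "inject_directed_coupling", "assign_clinical_scores", "default_gm_prob"]

AR_COEF = 0.3
NOISE_FWHM_MM = 6.0  # target smoothness of the noise *after* preprocessing
N_NETWORKS = 4
NETWORK_LOADING_SD = 0.15
NETWORK_AMPLITUDE_SD = 0.0  # network engagement held equal across subjects
LOADING_FWHM_MM = 9.0
DRIFT_SLOPE_MAX = 0.005
GM_MIX_RATIO = 0.02  # faint hub-signal leak into the rest of gray matter, relative to gain

# Table-style demographic moments: (mean, sd, low, high)
_DEMOGRAPHICS = {
    "tinnitus": {
        "age": (50.8, 12.4, 26, 67),
        "education": (12.3, 3.1, 8, 18),
        "hearing_left": (13.0, 2.7, 0, 24.9),
        "hearing_right": (14.6, 3.6, 0, 24.9),
        "tinnitus_duration": (46.5, 39.1, 6, 120),
        "p_male": 9 / 24,
    },
    "control": {
        "age": (44.7, 15.4, 26, 70),
        "education": (13.4, 3.8, 8, 22),
        "hearing_left": (13.6, 2.2, 0, 24.9),
        "hearing_right": (13.9, 3.4, 0, 24.9),
        "p_male": 9 / 22,
    },
}
THQ_MEAN, THQ_SD = 49.5, 15.5


@dataclass
class EffectSpec:
    """Ground-truth effects injected into patient scans only."""

    hub_centers: tuple = ((-18.0, 42.0, 27.0), (18.0, 42.0, 27.0))
    hub_radius_mm: float = 9.0
    hub_gain: float = 0.9
    coupling_targets: tuple = ((-12.0, 0.0, 0.0), (12.0, 0.0, 0.0))
    coupling_radius_mm: float = 6.0
    coupling_strength: float = 0.6
    coupling_strength_sd: float = 0.2
    coupling_lag: int = 1
    thq_coupling_r: float = 0.5

    def __post_init__(self):
        if self.hub_gain < 0 or self.coupling_strength < 0:
            raise ValueError("effect magnitudes must be >= 0")
        if self.coupling_lag < 1:
            raise ValueError("coupling lag must be >= 1 volume")
        if not 0 <= self.thq_coupling_r < 1:
            raise ValueError("thq_coupling_r must be in [0, 1)")

    @classmethod
    def null(cls) -> "EffectSpec":
        """No injected effects: patients and controls are exchangeable."""
        return cls(hub_gain=0.0, coupling_strength=0.0, coupling_strength_sd=0.0,
                   thq_coupling_r=0.0)


def default_gm_prob(grid: VolumeGrid) -> ScalarMap:
    """Deterministic gray-matter probability phantom for a grid.

    Separable edge taper: the outermost voxel layer has probability weight
    0.05, the next 0.5, the interior 0.95; the map is the per-axis product.
    Thresholding at > 0.2 keeps the interior plus single- and double-edge
    voxels, giving a realistic mask fraction without excluding the near-edge
    hub spheres.
    """
    weights = []
    for d in grid.dims:
        w = np.full(d, 0.95)
        if d >= 2:
            w[[0, -1]] = 0.05
        if d >= 4:
            w[[1, -2]] = 0.5
        weights.append(w)
    prob = weights[0][:, None, None] * weights[1][None, :, None] * weights[2][None, None, :]
    return ScalarMap(grid, prob, kind="gm_prob")


def _bandlimited_signal(T: int, tr: float, rng: np.random.Generator,
                        low: float = 0.01, high: float = 0.08) -> np.ndarray:
    """Unit-SD signal with power confined to [low, high] Hz."""
    freqs = np.fft.rfftfreq(T, d=tr)
    spec = np.fft.rfft(rng.standard_normal(T))
    spec[(freqs < low) | (freqs > high)] = 0.0
    s = np.fft.irfft(spec, n=T)
    sd = s.std()
    return s / sd if sd > 0 else s


#: frames ignored when orthogonalising network signals (the protocol's
#: initial-volume discard), so the retained window carries exactly
#: uncorrelated network components
ORTHO_SKIP_FRAMES = 10


def _network_signals(T: int, tr: float, rng: np.random.Generator, k: int) -> np.ndarray:
    """(T, k) band-limited network signals, orthonormalised over the
    post-discard window.

    Finite-sample cross-correlations between network time courses would
    otherwise induce long-range, loading-shaped fluctuations in each
    subject's degree map — structure no fixed-smoothness cluster null can
    absorb.
    """
    S = np.column_stack([_bandlimited_signal(T, tr, rng) for _ in range(k)])
    skip = ORTHO_SKIP_FRAMES if T > 3 * ORTHO_SKIP_FRAMES else 0
    tail = S[skip:] - S[skip:].mean(axis=0)
    q, r = np.linalg.qr(tail)
    out = (S - S[skip:].mean(axis=0)) @ np.linalg.inv(r)
    return out * np.sqrt(len(tail))  # unit SD per column over the tail


def _noise_scale(grid: VolumeGrid, fwhm_mm: float) -> float:
    """SD multiplier so raw noise reaches unit-like variance after one
    downstream Gaussian smoothing pass at ``fwhm_mm``.

    Matches the noise level of a process smoothed once at generation and
    once in preprocessing: sigma0 = ||k*k||_2 / ||k||_2^2 for the smoothing
    kernel k (computed numerically from an impulse response).
    """
    if fwhm_mm == 0:
        return 1.0
    sigma = fwhm_mm * 0.42466 / np.asarray(grid.voxel_size)  # FWHM -> sigma
    from scipy import ndimage

    size = tuple(min(d, int(8 * s) * 2 + 1) for d, s in zip((99, 99, 99), sigma))
    imp = np.zeros(size)
    imp[size[0] // 2, size[1] // 2, size[2] // 2] = 1.0
    k1 = ndimage.gaussian_filter(imp, sigma=sigma, mode="constant")
    k2 = ndimage.gaussian_filter(k1, sigma=sigma, mode="constant")
    n1 = np.sqrt((k1**2).sum())
    n2 = np.sqrt((k2**2).sum())
    return float(n2 / n1**2)


def inject_hub(
    bold: BoldSeries,
    center: tuple[float, float, float],
    radius_mm: float,
    gain: float,
    shared_signal: np.ndarray,
    gm_mask: np.ndarray | None = None,
    gm_gain: float | None = None,
) -> BoldSeries:
    """Add a shared signal at full gain inside a sphere, faintly in gray matter.

    Raises voxel degree inside the sphere: sphere voxels become strongly
    intercorrelated and weakly correlated with the rest of gray matter.
    ``gain = 0`` returns the input unchanged.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    if gain < 0:
        raise ValueError("gain must be >= 0")
    if gain == 0:
        return bold
    sig = np.asarray(shared_signal, dtype=float)
    if len(sig) != bold.n_volumes:
        raise ValueError("shared signal length must match n_volumes")
    sphere = bold.grid.sphere(center, radius_mm)
    data = np.array(bold.data, dtype=float, copy=True)
    if gm_mask is not None:
        mix = GM_MIX_RATIO * gain if gm_gain is None else gm_gain
        data[gm_mask] += mix * sig
    data[sphere] += gain * sig
    return BoldSeries(bold.grid, data, tr_seconds=bold.tr_seconds)


def inject_directed_coupling(
    bold: BoldSeries,
    source_center: tuple[float, float, float],
    target_center: tuple[float, float, float],
    radius_mm: float,
    strength: float,
    lag: int = 1,
) -> BoldSeries:
    """Add a lagged copy of the source-sphere mean signal to target voxels.

    Target voxels at time t receive ``strength * mean_source(t - lag)``
    (zero before the first available lag); the source is untouched, so the
    induced influence is purely directional.  ``strength = 0`` is identity.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 volume")
    if strength < 0:
        raise ValueError("strength must be >= 0")
    if strength == 0:
        return bold
    src = bold.grid.sphere(source_center, radius_mm)
    tgt = bold.grid.sphere(target_center, radius_mm)
    if (src & tgt).any():
        raise ValueError("source and target spheres overlap")
    if not src.any() or not tgt.any():
        raise ValueError("source/target sphere outside the grid")
    src_mean = bold.data[src].mean(axis=0)
    delayed = np.zeros_like(src_mean)
    delayed[lag:] = src_mean[:-lag]
    data = np.array(bold.data, dtype=float, copy=True)
    data[tgt] += strength * delayed
    return BoldSeries(bold.grid, data, tr_seconds=bold.tr_seconds)


def assign_clinical_scores(
    records: pd.DataFrame,
    coupling_strengths: np.ndarray,
    target_r: float,
    seed: int,
    max_retries: int = 20,
) -> pd.DataFrame:
    """Draw patient THQ scores correlated with the injected coupling strengths.

    The scores are constructed so the sample Pearson correlation with the
    strengths equals ``target_r`` before clipping to [0, 100]; if clipping
    moves it outside ``target_r +/- 0.15`` the draw is repeated (bounded).
    Controls keep absent THQ.  Mean/SD match the study's 49.5 +/- 15.5.
    """
    if not 0 <= target_r < 1:
        raise ValueError("target_r must be in [0, 1)")
    is_pat = (records["group"] == "tinnitus").to_numpy()
    n_pat = int(is_pat.sum())
    if n_pat < 3:
        raise ValueError("need at least 3 patients")
    c = np.asarray(coupling_strengths, dtype=float)
    if len(c) != n_pat:
        raise ValueError("one coupling strength per patient required")
    rng = np.random.default_rng(seed)
    c_std = (c - c.mean())
    c_norm = c_std / c_std.std() if c_std.std() > 0 else np.zeros_like(c_std)
    out = records.copy()
    for _ in range(max_retries):
        e = rng.standard_normal(n_pat)
        if c_std.std() > 0:
            e = e - e.mean() - (e @ c_norm / n_pat) * c_norm  # orthogonal to c
        else:
            e = e - e.mean()
        e_sd = e.std()
        e = e / e_sd if e_sd > 0 else e
        z = target_r * c_norm + np.sqrt(1.0 - target_r**2) * e
        thq = np.clip(THQ_MEAN + THQ_SD * z, 0.0, 100.0)
        if c_std.std() == 0:
            break
        r = np.corrcoef(thq, c)[0, 1]
        if abs(r - target_r) <= 0.15:
            break
    out.loc[is_pat, "thq"] = np.round(thq, 1)
    out.loc[~is_pat, "thq"] = np.nan
    return out


def _truncated_normal(rng, mean, sd, low, high, size):
    vals = rng.normal(mean, sd, size)
    for _ in range(50):
        bad = (vals < low) | (vals > high)
        if not bad.any():
            break
        vals[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(vals, low, high)


def _draw_demographics(n_patients, n_controls, rng) -> pd.DataFrame:
    rows = []
    for group, n in (("tinnitus", n_patients), ("control", n_controls)):
        spec = _DEMOGRAPHICS[group]
        age = _truncated_normal(rng, *spec["age"], n)
        edu = _truncated_normal(rng, *spec["education"], n)
        hl = _truncated_normal(rng, *spec["hearing_left"], n)
        hr = _truncated_normal(rng, *spec["hearing_right"], n)
        sex = np.where(rng.random(n) < spec["p_male"], "male", "female")
        dur = (
            _truncated_normal(rng, *spec["tinnitus_duration"], n)
            if group == "tinnitus"
            else np.full(n, np.nan)
        )
        prefix = "tin" if group == "tinnitus" else "ctl"
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{prefix}{i + 1:03d}",
                    "group": group,
                    "age": round(float(age[i]), 1),
                    "sex": str(sex[i]),
                    "education": round(float(edu[i]), 1),
                    "tinnitus_duration": round(float(dur[i]), 1) if group == "tinnitus" else np.nan,
                    "thq": np.nan,
                    "hearing_left": round(float(hl[i]), 1),
                    "hearing_right": round(float(hr[i]), 1),
                }
            )
    return pd.DataFrame(rows)


def _motion_trace(rng, n_volumes: int, high_motion: bool = False) -> MotionTrace:
    steps_t = rng.normal(0.0, 0.035, (n_volumes, 3))
    steps_r = rng.normal(0.0, 0.030, (n_volumes, 3))
    trans = np.cumsum(steps_t, axis=0)
    rot = np.cumsum(steps_r, axis=0)
    # keep well-behaved subjects under the limits
    for arr, cap in ((trans, 1.6), (rot, 1.6)):
        peak = np.abs(arr).max()
        if peak > cap:
            arr *= cap / peak
    if high_motion:
        trans *= 2.6 / max(np.abs(trans).max(), 1e-9)
    return MotionTrace(trans, rot)


@dataclass
class Cohort:
    """A generated cohort; BOLD series are synthesised lazily per subject."""

    grid: VolumeGrid
    subjects: pd.DataFrame
    gm_prob: ScalarMap
    effects: EffectSpec
    n_volumes: int
    tr_seconds: float
    seed: int
    _subject_seeds: dict = field(repr=False, default_factory=dict)
    _loadings: np.ndarray = field(repr=False, default=None)
    _coupling: dict = field(repr=False, default_factory=dict)
    _motion: dict = field(repr=False, default_factory=dict)

    def bold_for(self, subject_id: str) -> BoldSeries:
        """Deterministically synthesise one subject's 4D BOLD series."""
        row = self.subjects[self.subjects["subject_id"] == subject_id]
        if len(row) != 1:
            raise KeyError(subject_id)
        row = row.iloc[0]
        rng = np.random.default_rng(self._subject_seeds[subject_id])
        T, grid, eff = self.n_volumes, self.grid, self.effects
        gm = self.gm_prob.data > 0.2

        # spatially white AR(1) noise; preprocessing's 6 mm smoothing brings
        # it to the target smoothness (generating it pre-smoothed would make
        # the maps smoother than the Monte-Carlo null assumes)
        noise = rng.standard_normal((*grid.dims, T)).astype(np.float32)
        noise = sp_signal.lfilter([1.0], [1.0, -AR_COEF], noise, axis=3)
        data = np.asarray(noise, dtype=float)
        data *= _noise_scale(grid, NOISE_FWHM_MM) / data[gm].std()
        signals = _network_signals(T, self.tr_seconds, rng, self._loadings.shape[0])
        for k in range(self._loadings.shape[0]):
            a_k = max(0.2, rng.normal(1.0, NETWORK_AMPLITUDE_SD))
            data += a_k * self._loadings[k][..., None] * signals[:, k]
        slope = rng.uniform(-DRIFT_SLOPE_MAX, DRIFT_SLOPE_MAX, grid.dims)
        t = np.arange(T) - (T - 1) / 2.0
        data += slope[..., None] * t
        series = BoldSeries(grid, data, tr_seconds=self.tr_seconds)

        if row["group"] == "tinnitus":
            if eff.hub_gain > 0:
                hub_sig = _bandlimited_signal(T, self.tr_seconds, rng)
                for i, center in enumerate(eff.hub_centers):
                    series = inject_hub(
                        series, center, eff.hub_radius_mm, eff.hub_gain, hub_sig,
                        gm_mask=gm if i == 0 else None,  # faint GM mix added once
                    )
            strength = self._coupling.get(subject_id, 0.0)
            if strength > 0:
                for src, tgt in zip(eff.hub_centers, eff.coupling_targets):
                    series = inject_directed_coupling(
                        series, src, tgt, eff.coupling_radius_mm, strength,
                        lag=eff.coupling_lag,
                    )
        return series

    def motion_for(self, subject_id: str) -> MotionTrace:
        return self._motion[subject_id]

    def manifest(self) -> dict:
        """Ground truth injected into this cohort, for recovery checks."""
        return {
            "seed": self.seed,
            "n_volumes": self.n_volumes,
            "tr_seconds": self.tr_seconds,
            "effects": asdict(self.effects),
            "coupling_strength_by_subject": {k: float(v) for k, v in self._coupling.items()},
        }

    def write(self, out_dir: str | Path) -> Path:
        """Materialise the cohort: NIfTI volumes, subjects CSV, motion files,
        GM map and a JSON ground-truth manifest."""
        out = Path(out_dir)
        (out / "bold").mkdir(parents=True, exist_ok=True)
        (out / "motion").mkdir(parents=True, exist_ok=True)
        write_volume(self.gm_prob, out / "gm_prob.nii.gz")
        write_subjects_table(self.subjects, out / "subjects.csv")
        for sid in self.subjects["subject_id"]:
            write_volume(self.bold_for(sid), out / "bold" / f"{sid}.nii.gz")
            tr = self.motion_for(sid)
            write_motion_trace(tr.translations, tr.rotations, out / "motion" / f"{sid}.txt")
        (out / "effects_manifest.json").write_text(
            json.dumps(self.manifest(), sort_keys=True, indent=2)
        )
        return out


def generate_cohort(
    n_patients: int = 24,
    n_controls: int = 22,
    grid: VolumeGrid | None = None,
    n_volumes: int = 240,
    effects: EffectSpec | None = None,
    seed: int = 0,
    tr_seconds: float = 2.0,
    high_motion_subject: bool = False,
) -> Cohort:
    """Generate a two-group synthetic rs-fMRI cohort.

    ``high_motion_subject`` appends one extra patient whose motion trace
    exceeds the 2.0 mm limit, exercising the exclusion path.
    """
    if n_patients < 1 or n_controls < 1:
        raise ValueError("group sizes must be positive")
    if grid is None:
        grid = VolumeGrid.from_spacing((20, 24, 20))
    effects = effects if effects is not None else EffectSpec()
    if effects.hub_gain > 0:
        for center in effects.hub_centers:
            grid.mm_to_voxel(center)  # raises if the hub is outside the grid
    ss = np.random.SeedSequence(seed)
    demo_seed, loading_seed, thq_seed, *rest = ss.spawn(3 + n_patients + n_controls + 1)
    rng_demo = np.random.default_rng(demo_seed)

    subjects = _draw_demographics(n_patients, n_controls, rng_demo)
    if high_motion_subject:
        extra = subjects[subjects["group"] == "tinnitus"].iloc[[0]].copy()
        extra["subject_id"] = f"tin{n_patients + 1:03d}"
        subjects = pd.concat([subjects, extra], ignore_index=True)

    # cohort-level network loadings: smooth random fields restricted to GM
    gm_prob = default_gm_prob(grid)
    gm = gm_prob.data > 0.2
    rng_load = np.random.default_rng(loading_seed)
    loadings = np.zeros((N_NETWORKS, *grid.dims))
    for k in range(N_NETWORKS):
        raw = smooth_gaussian(
            ScalarMap(grid, rng_load.standard_normal(grid.dims)), LOADING_FWHM_MM
        ).data
        raw = raw / raw[gm].std() * NETWORK_LOADING_SD
        loadings[k] = np.where(gm, raw, 0.0)

    # per-patient coupling strengths (controls: zero)
    pat_ids = list(subjects.loc[subjects["group"] == "tinnitus", "subject_id"])
    rng_cpl = np.random.default_rng(thq_seed)
    if effects.coupling_strength > 0:
        strengths = np.clip(
            rng_cpl.normal(effects.coupling_strength, effects.coupling_strength_sd, len(pat_ids)),
            0.1, None,
        )
    else:
        strengths = np.zeros(len(pat_ids))
    coupling = dict(zip(pat_ids, strengths))

    subject_seeds = {}
    motion = {}
    all_ids = list(subjects["subject_id"])
    for sid, child in zip(all_ids, rest):
        subject_seeds[sid] = child
        high = high_motion_subject and sid == f"tin{n_patients + 1:03d}"
        motion[sid] = _motion_trace(np.random.default_rng(child.spawn(1)[0]), n_volumes, high)
    subjects["max_translation"] = [
        round(float(np.abs(motion[s].translations).max()), 3) for s in all_ids
    ]
    subjects["max_rotation"] = [
        round(float(np.abs(motion[s].rotations).max()), 3) for s in all_ids
    ]
    subjects["excluded"] = False

    cohort = Cohort(
        grid=grid,
        subjects=subjects,
        gm_prob=gm_prob,
        effects=effects,
        n_volumes=n_volumes,
        tr_seconds=tr_seconds,
        seed=seed,
        _subject_seeds=subject_seeds,
        _loadings=loadings,
        _coupling=coupling,
        _motion=motion,
    )
    # THQ correlated with the injected coupling strengths (patients only)
    strengths_arr = np.array([coupling[s] for s in pat_ids])
    target_r = effects.thq_coupling_r if effects.coupling_strength > 0 else 0.0
    if len(pat_ids) >= 3:
        cohort.subjects = assign_clinical_scores(
            subjects, strengths_arr, target_r, seed=int(rng_cpl.integers(2**31 - 1))
        )
    else:  # too few patients for a meaningful correlation: marginal draw only
        is_pat = (subjects["group"] == "tinnitus").to_numpy()
        subjects.loc[is_pat, "thq"] = np.round(
            np.clip(rng_cpl.normal(THQ_MEAN, THQ_SD, int(is_pat.sum())), 0, 100), 1
        )
        cohort.subjects = subjects
    return cohort
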