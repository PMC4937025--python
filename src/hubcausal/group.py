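"""Group-level statistics.

One-sample and covariate-adjusted two-sample voxel-wise inference on
per-subject maps, the combined-significance analysis mask, cluster-mean
extraction, covariate-adjusted (partial) Pearson clinical correlations with
Bonferroni control, and demographics-table statistics (pooled-variance t,
chi-square without continuity correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import McResult, apply_correction
from .grids import BinaryMask, ScalarMap

__all__ = [
    "DesignMatrix",
    "build_design",
    "one_sample_map",
    "two_sample_glm_map",
    "combine_group_masks",
    "cluster_mean_values",
    "partial_pearson",
    "demographics_table",
    "two_sample_t_from_summary",
    "chi_square_2x2",
    "correlation_report",
    "GroupContrastGLM",
    "GroupGLMResults",
]

NUISANCE_COVARIATES = ("age", "sex", "education")


def _included(subjects: pd.DataFrame) -> pd.DataFrame:
    if "excluded" in subjects.columns:
        return subjects[~subjects["excluded"].astype(bool)]
    return subjects


@dataclass
class DesignMatrix:
    """Design for the group-contrast GLM.

    Columns: intercept, group contrast (+1 tinnitus / -1 control), then
    mean-centered nuisance covariates (sex coded male=1/female=0 before
    centering).  Rows follow the subject order of the map stack.
    """

    matrix: np.ndarray
    columns: list[str]
    subject_ids: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.columns):
            raise ValueError("design matrix shape does not match column names")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def group_column(self) -> int:
        return self.columns.index("group")


def build_design(
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = NUISANCE_COVARIATES,
) -> DesignMatrix:
    """Build the GLM design from a subjects table (excluded rows dropped).

    Constant covariate columns are dropped (they are collinear with the
    intercept after centering), reducing to a plain two-sample design when
    all covariates are equal.
    """
    df = _included(subjects).reset_index(drop=True)
    n = len(df)
    if n < 4:
        raise ValueError("need at least 4 included subjects")
    cols = [np.ones(n)]
    names = ["intercept"]
    group = np.where(df["group"] == "tinnitus", 1.0, -1.0)
    if len(np.unique(group)) < 2:
        raise ValueError("both groups must be present")
    cols.append(group)
    names.append("group")
    for cov in covariates:
        if cov == "sex":
            vals = np.where(df[cov].astype(str).str.lower().isin(("male", "m", "1")), 1.0, 0.0)
        else:
            vals = df[cov].to_numpy(dtype=float)
        vals = vals - vals.mean()
        if np.ptp(vals) == 0:
            continue  # constant covariate carries no information
        cols.append(vals)
        names.append(cov)
    return DesignMatrix(np.column_stack(cols), names, list(df["subject_id"].astype(str)))


def _stack_values(maps: list[ScalarMap], mask: BinaryMask) -> np.ndarray:
    grid = mask.grid
    for m in maps:
        if not m.grid.matches(grid):
            raise ValueError("maps and mask are on different grids")
    return np.stack([m.data[mask.data] for m in maps])  # (S, N)


def one_sample_map(maps: list[ScalarMap], mask: BinaryMask) -> ScalarMap:
    """Voxel-wise one-sample t of subject values against zero (df = n - 1)."""
    if len(maps) < 3:
        raise ValueError("need at least 3 subjects")
    V = _stack_values(maps, mask)
    n = V.shape[0]
    mean = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    n_degenerate = int((~ok & (mean != 0)).sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} zero-variance voxels with nonzero mean; t set to 0",
            RuntimeWarning,
        )
    out = np.zeros(mask.grid.dims)
    out[mask.data] = t
    return ScalarMap(mask.grid, out, kind="tstat")


def two_sample_glm_map(
    maps: list[ScalarMap], design: DesignMatrix, mask: BinaryMask
) -> ScalarMap:
    """Voxel-wise GLM t map for the group contrast, nuisance covariates adjusted."""
    V = _stack_values(maps, mask)  # (S, N)
    X = design.matrix
    if V.shape[0] != X.shape[0]:
        raise ValueError("number of maps does not match design rows")
    n, k = X.shape
    if n <= k:
        raise ValueError("more design columns than subjects")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ V)  # (k, N)
    resid = V - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    g = design.group_column
    se = np.sqrt(sigma2 * XtX_inv[g, g])
    t = np.zeros(V.shape[1])
    ok = se > 0
    t[ok] = beta[g, ok] / se[ok]
    out = np.zeros(mask.grid.dims)
    out[mask.data] = t
    return ScalarMap(mask.grid, out, kind="tstat")


def glm_dof(design: DesignMatrix) -> int:
    return design.matrix.shape[0] - design.matrix.shape[1]


def combine_group_masks(
    group_t_maps: list[ScalarMap],
    mask: BinaryMask,
    mc: McResult,
    stat_thresholds: list[float],
    connect_radius_mm: float | None = None,
) -> BinaryMask:
    """Union of FWE-surviving positive one-sample clusters across groups.

    The two-sample analysis is restricted to this mask.  An empty union
    falls back to the full analysis mask with a warning.
    """
    if len(group_t_maps) != len(stat_thresholds):
        raise ValueError("one threshold per group map required")
    union = np.zeros(mask.grid.dims, dtype=bool)
    for tmap, thr in zip(group_t_maps, stat_thresholds):
        table, surv = apply_correction(
            tmap, mask, thr, mc, connect_radius_mm, sign="positive"
        )
        union |= table.labels.data > 0
    if not union.any():
        warnings.warn(
            "no significant one-sample clusters in either group; "
            "falling back to the full analysis mask",
            RuntimeWarning,
        )
        return BinaryMask(mask.grid, mask.data.copy())
    return BinaryMask(mask.grid, union)


def cluster_mean_values(maps: list[ScalarMap], cluster: BinaryMask) -> np.ndarray:
    """Per-subject mean of in-cluster voxel values."""
    if cluster.n_true == 0:
        raise ValueError("cluster mask is empty")
    return _stack_values(maps, cluster).mean(axis=1)


def partial_pearson(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after removing covariates from both.

    Residualises x and y on [intercept, covariates] by least squares,
    correlates the residuals, and tests with
    t = r * sqrt((n - k - 2) / (1 - r^2)) on n - k - 2 degrees of freedom
    (k covariates, two-tailed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if y.shape != x.shape:
        raise ValueError("x and y must have equal length")
    if covariates is None or (np.asarray(covariates).size == 0):
        C = np.empty((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariates must have one row per subject")
    k = C.shape[1]
    if n <= k + 2:
        raise ValueError(f"n={n} too small for {k} covariates")
    X = np.column_stack([np.ones(n), C])
    H = X @ np.linalg.pinv(X)
    rx = x - H @ x
    ry = y - H @ y
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate residual variance")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t-test from printed group summaries."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:  # both groups constant
        return (0.0, 1.0) if mean1 == mean2 else (float("inf"), 0.0)
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), p


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


def demographics_table(subjects: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SD and between-group p per demographic/clinical variable.

    Continuous variables: pooled-variance two-sample t (two-tailed).
    Sex: Pearson chi-square without continuity correction.  Variables absent
    in one group (THQ, duration) get no p-value.
    """
    included = _included(subjects)
    pat = included[included["group"] == "tinnitus"]
    ctl = included[included["group"] == "control"]
    if len(pat) == 0 or len(ctl) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []

    def _fmt(series):
        vals = series.dropna().to_numpy(dtype=float)
        return f"{vals.mean():.1f} ± {vals.std(ddof=1):.1f}", vals

    for var in ("age", "education", "tinnitus_duration", "thq", "hearing_left", "hearing_right"):
        if var not in subjects.columns:
            continue
        s_pat, v_pat = _fmt(pat[var]) if pat[var].notna().any() else ("-", np.array([]))
        s_ctl, v_ctl = _fmt(ctl[var]) if ctl[var].notna().any() else ("-", np.array([]))
        if len(v_pat) > 1 and len(v_ctl) > 1:
            _, p = two_sample_t_from_summary(
                v_pat.mean(), v_pat.std(ddof=1), len(v_pat),
                v_ctl.mean(), v_ctl.std(ddof=1), len(v_ctl),
            )
            p_str = f"{p:.3f}"
        else:
            p_str = "-"
        rows.append({"variable": var, "tinnitus": s_pat, "control": s_ctl, "p": p_str})
    if "sex" in subjects.columns:
        tab = np.array(
            [
                [(pat["sex"] == "male").sum(), (pat["sex"] == "female").sum()],
                [(ctl["sex"] == "male").sum(), (ctl["sex"] == "female").sum()],
            ]
        )
        _, p = chi_square_2x2(tab)
        rows.append(
            {
                "variable": "sex (male:female)",
                "tinnitus": f"{tab[0, 0]}:{tab[0, 1]}",
                "control": f"{tab[1, 0]}:{tab[1, 1]}",
                "p": f"{p:.3f}",
            }
        )
    return pd.DataFrame(rows, columns=["variable", "tinnitus", "control", "p"])


def correlation_report(
    cluster_values: dict[str, np.ndarray],
    clinical: dict[str, np.ndarray],
    covariates: np.ndarray | None,
) -> pd.DataFrame:
    """Partial Pearson correlations of cluster means vs clinical variables.

    Bonferroni correction uses (clusters tested) x (clinical variables) as
    the number of tests; both raw and corrected p are reported.
    """
    n_tests = len(cluster_values) * len(clinical)
    rows = []
    for cid, vals in cluster_values.items():
        for cname, cvals in clinical.items():
            ok = np.isfinite(cvals) & np.isfinite(vals)
            r, p = partial_pearson(
                vals[ok], cvals[ok], covariates[ok] if covariates is not None else None
            )
            rows.append(
                {
                    "cluster_id": cid,
                    "clinical_variable": cname,
                    "r": r,
                    "p_raw": p,
                    "p_bonferroni": min(1.0, p * n_tests),
                    "n": int(ok.sum()),
                    "n_tests": n_tests,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "clinical_variable", "r", "p_raw", "p_bonferroni", "n", "n_tests"],
    )


@dataclass
class GroupGLMResults:
    """Fitted group-contrast GLM: t map, effect map, design, df."""

    tmap: ScalarMap
    design: DesignMatrix
    mask: BinaryMask
    dof: int

    def summary(self) -> str:
        t = self.tmap.data[self.mask.data]
        n_pat = int((self.design.matrix[:, self.design.group_column] > 0).sum())
        n_ctl = len(self.design.subject_ids) - n_pat
        return "\n".join(
            [
                "Group contrast GLM (tinnitus - control)",
                f"  subjects      : {n_pat} tinnitus vs {n_ctl} control",
                f"  covariates    : {', '.join(self.design.columns[2:]) or 'none'}",
                f"  df            : {self.dof}",
                f"  mask voxels   : {self.mask.n_true}",
                f"  t range       : [{t.min():.3f}, {t.max():.3f}]",
            ]
        )


class GroupContrastGLM:
    """Voxel-wise group-contrast GLM over per-subject maps.

    Build with :meth:`from_dataframe`, fit with :meth:`fit`; the result
    carries the contrast t map and ``summary()``.
    """

    def __init__(self, maps: list[ScalarMap], design: DesignMatrix, mask: BinaryMask):
        self.maps = maps
        self.design = design
        self.mask = mask

    @classmethod
    def from_dataframe(
        cls,
        maps: list[ScalarMap],
        subjects: pd.DataFrame,
        mask: BinaryMask,
        covariates: tuple[str, ...] = NUISANCE_COVARIATES,
    ) -> "GroupContrastGLM":
        design = build_design(subjects, covariates)
        if len(maps) != len(design.subject_ids):
            raise ValueError("one map per included subject required")
        return cls(maps, design, mask)

    def fit(self) -> GroupGLMResults:
        tmap = two_sample_glm_map(self.maps, self.design, self.mask)
        return GroupGLMResults(tmap, self.design, self.mask, glm_dof(self.design))
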