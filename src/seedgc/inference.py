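"""Group-level inference on CPC maps.

Voxelwise covariate-adjusted two-sample comparison (OLS with a group
contrast plus age, gender and mean-FD covariates), Monte-Carlo
cluster-extent correction in the style of AlphaSim (null maximum cluster
size of smooth Gaussian noise on the analysis mask), per-group one-sample
tests on cluster means, the t -> Cohen's d conversion, and the
activation-confound control analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure

__all__ = [
    "GroupDesign",
    "StatResult",
    "voxelwise_group_t",
    "one_sample_cluster_t",
    "estimate_smoothness",
    "alphasim_extent_threshold",
    "extract_clusters",
    "cluster_mean_cpc",
    "cohens_d_from_t",
    "activation_control",
]

_CONNECTIVITY_TO_SKIMAGE = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class StatResult:
    """A scalar test statistic with df, two-sided p and optional effect size."""

    statistic: float
    df: float
    p: float
    effect_size: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must be in [0, 1]")


@dataclass
class GroupDesign:
    """Design matrix for the group comparison.

    Columns: intercept, group contrast (+1 patient / -1 control), age,
    gender (F=1/M=0), mean FD at rest, mean FD during task. With the full
    sample of 60 subjects this leaves df = 60 - 6 = 54.
    """

    matrix: np.ndarray
    columns: list[str]
    subject_ids: list[str]
    group_col: int = 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def df(self) -> int:
        return self.matrix.shape[0] - self.matrix.shape[1]

    @classmethod
    def from_records(cls, records, patient_label: str = "SZ") -> "GroupDesign":
        rows, ids = [], []
        for r in records:
            rows.append(
                [
                    1.0,
                    1.0 if r.group == patient_label else -1.0,
                    float(r.age),
                    1.0 if r.gender == "F" else 0.0,
                    float(r.mean_fd_rest),
                    float(r.mean_fd_task),
                ]
            )
            ids.append(r.id)
        return cls(
            matrix=np.asarray(rows),
            columns=["intercept", "group", "age", "gender", "mean_fd_rest", "mean_fd_task"],
            subject_ids=ids,
        )


def _ols_t(X: np.ndarray, Y: np.ndarray, col: int) -> tuple[np.ndarray, int, np.ndarray]:
    """t statistic of one design column across many response vectors.

    Y: (n, V). Returns (t per response, df, residuals (n, V))."""
    n, p = X.shape
    if n - p < 1:
        raise ValueError(f"no residual degrees of freedom: n={n}, design columns={p}")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[col, col])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[col] / se
    return np.nan_to_num(t), df, resid


def voxelwise_group_t(cpc_stack: np.ndarray, design: GroupDesign
                      ) -> tuple[np.ndarray, int, np.ndarray]:
    """Covariate-adjusted two-sample comparison at every voxel.

    cpc_stack: (n_subjects, V) in-mask CPC values. Returns the group-contrast
    t map (V,), the residual df, and the (n, V) residual stack used for
    smoothness estimation.
    """
    Y = np.asarray(cpc_stack, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != design.n:
        raise ValueError("cpc_stack must be (n_subjects, V) matching the design")
    return _ols_t(design.matrix, Y, design.group_col)


def one_sample_cluster_t(values: np.ndarray, covariates: np.ndarray | None = None
                         ) -> StatResult:
    """One-sample t-test on per-subject cluster means.

    Plain mode (default): t = mean / (sd / sqrt(n)), df = n - 1. Adjusted
    mode: the intercept t after regressing on mean-centred covariates
    (df = n - 1 - k), asking whether the mean differs from zero once
    covariate effects are removed.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("need a 1-D vector with n >= 3")
    if v.std(ddof=1) == 0:
        raise ValueError("zero variance: one-sample t undefined")
    if covariates is None:
        t, p = stats.ttest_1samp(v, 0.0)
        return StatResult(float(t), v.size - 1, float(p))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    C = C - C.mean(axis=0)
    X = np.column_stack([np.ones(v.size), C])
    t_all, df, _ = _ols_t(X, v[:, None], col=0)
    t = float(t_all[0])
    p = float(2 * stats.t.sf(abs(t), df))
    return StatResult(t, df, p)


def estimate_smoothness(residual_stack: np.ndarray, mask: np.ndarray,
                        voxel_sizes: np.ndarray) -> np.ndarray:
    """Per-axis FWHM (mm) of residual maps via the first-difference estimator.

    For each axis: FWHM = voxel_size * sqrt(-2 ln 2 / ln(1 - varΔ / (2 var)))
    where varΔ is the variance of within-mask neighbour differences; averaged
    over maps and clamped to >= voxel size.
    """
    R = np.asarray(residual_stack, dtype=float)
    if R.ndim != 4:
        raise ValueError("residual_stack must be (n_maps, X, Y, Z)")
    if R.shape[0] < 2:
        raise ValueError("need at least two residual maps")
    mask = np.asarray(mask, dtype=bool)
    vs = np.asarray(voxel_sizes, dtype=float)
    fwhm = np.zeros(3)
    var = R[:, mask].var(axis=1).mean()
    if var == 0:
        raise ValueError("constant residual maps")
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(1, None)
        sl_b[ax] = slice(None, -1)
        pair = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        diffs = R[(slice(None), *sl_a)][:, pair] - R[(slice(None), *sl_b)][:, pair]
        var_d = diffs.var(axis=1).mean()
        ratio = var_d / (2.0 * var)
        if ratio >= 1.0 or ratio <= 0.0:
            fwhm[ax] = vs[ax]
        else:
            fwhm[ax] = vs[ax] * np.sqrt(-2.0 * np.log(2.0) / np.log1p(-ratio))
    return np.maximum(fwhm, vs)


def _label(mask3d: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    conn = _CONNECTIVITY_TO_SKIMAGE.get(connectivity)
    if conn is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    lab = measure.label(mask3d, connectivity=conn)
    return lab, lab.max()


def _max_cluster_size(supra_pos: np.ndarray, supra_neg: np.ndarray, connectivity: int) -> int:
    best = 0
    for supra in (supra_pos, supra_neg):
        if supra.any():
            lab, n = _label(supra, connectivity)
            if n:
                best = max(best, int(np.bincount(lab.ravel())[1:].max()))
    return best


def alphasim_extent_threshold(
    mask: np.ndarray,
    fwhm_mm: np.ndarray | float,
    voxel_sizes: np.ndarray,
    voxel_p: float = 0.01,
    alpha: float = 0.05,
    n_iter: int = 1000,
    connectivity: int = 26,
    rng: int | np.random.Generator = 0,
) -> tuple[int, np.ndarray]:
    """Monte-Carlo cluster-extent threshold on the analysis mask.

    Per iteration: Gaussian noise on the grid is smoothed to the estimated
    FWHM, re-standardised within the mask, thresholded two-sided at
    ``voxel_p``, and the largest suprathreshold cluster recorded (positive
    and negative tails clustered separately). The returned extent is the
    smallest k with P(max extent >= k) <= alpha, controlling familywise
    error at ``alpha``. Also returns the null max-extent distribution.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if not (0 < voxel_p < 1 and 0 < alpha < 1):
        raise ValueError("voxel_p and alpha must be in (0, 1)")
    if n_iter < 200:
        raise ValueError("n_iter must be >= 200 for a usable null distribution")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    vs = np.asarray(voxel_sizes, dtype=float)
    sigma_vox = (fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / vs
    z_crit = stats.norm.isf(voxel_p / 2.0)
    maxima = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        noise = rng.standard_normal(mask.shape)
        if np.any(sigma_vox > 1e-9):
            noise = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="constant")
        vals = noise[mask]
        z = np.zeros_like(noise)
        z[mask] = (vals - vals.mean()) / vals.std()
        maxima[i] = _max_cluster_size(z >= z_crit, z <= -z_crit, connectivity)
    # smallest k with tail probability <= alpha
    ks = np.arange(1, maxima.max() + 2)
    tail = np.array([(maxima >= k).mean() for k in ks])
    idx = np.argmax(tail <= alpha)
    return int(ks[idx]), maxima


def extract_clusters(
    t_map: np.ndarray,
    df: int,
    mask: np.ndarray,
    affine: np.ndarray,
    voxel_p: float = 0.01,
    extent_threshold: int = 1,
    connectivity: int = 26,
    null_maxima: np.ndarray | None = None,
) -> pd.DataFrame:
    """Suprathreshold clusters from a t map (two-sided voxel threshold).

    Positive and negative tails are clustered separately so opposite-signed
    clusters are never merged. Returns a table with label, sign, extent K,
    peak t, peak MNI coordinates and (if a null distribution is supplied)
    the cluster-corrected p = P(null max extent >= K).
    """
    t_map = np.asarray(t_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    t_crit = stats.t.isf(voxel_p / 2.0, df)
    rows = []
    label_map = np.zeros(mask.shape, dtype=int)
    next_label = 1
    for sign, supra in ((1, (t_map >= t_crit) & mask), (-1, (t_map <= -t_crit) & mask)):
        if not supra.any():
            continue
        lab, n = _label(supra, connectivity)
        for comp in range(1, n + 1):
            vox = lab == comp
            k = int(vox.sum())
            if k < extent_threshold:
                continue
            tv = np.where(vox, t_map, 0.0)
            peak_flat = np.abs(tv).argmax()
            peak_ijk = np.unravel_index(peak_flat, t_map.shape)
            peak_mm = (affine[:3, :3] @ np.asarray(peak_ijk, float)) + affine[:3, 3]
            peak_t = float(t_map[peak_ijk])
            cluster_p = (
                float((null_maxima >= k).mean()) if null_maxima is not None else np.nan
            )
            label_map[vox] = next_label
            rows.append(
                {
                    "label": next_label,
                    "sign": sign,
                    "extent": k,
                    "peak_t": peak_t,
                    "peak_p": float(2 * stats.t.sf(abs(peak_t), df)),
                    "peak_x": float(peak_mm[0]),
                    "peak_y": float(peak_mm[1]),
                    "peak_z": float(peak_mm[2]),
                    "cluster_p": cluster_p,
                }
            )
            next_label += 1
    df_out = pd.DataFrame(
        rows,
        columns=[
            "label", "sign", "extent", "peak_t", "peak_p",
            "peak_x", "peak_y", "peak_z", "cluster_p",
        ],
    )
    df_out.attrs["label_map"] = label_map
    df_out.attrs["df"] = df
    return df_out


def cluster_mean_cpc(cpc_stack: np.ndarray, mask: np.ndarray,
                     cluster_mask: np.ndarray) -> np.ndarray:
    """Per-subject mean CPC over a cluster's voxels.

    cpc_stack: (n_subjects, V) in-mask values; cluster_mask: 3-D boolean.
    """
    mask = np.asarray(mask, dtype=bool)
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if not cluster_mask.any():
        raise ValueError("empty cluster")
    if (cluster_mask & ~mask).any():
        raise ValueError("cluster extends outside the analysis mask")
    sel = cluster_mask[mask]
    return np.asarray(cpc_stack, dtype=float)[:, sel].mean(axis=1)


def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Two-sample effect size from a t statistic: d = t * sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    return float(t * np.sqrt(1.0 / n1 + 1.0 / n2))


def activation_control(
    cluster_cpc: np.ndarray,
    design: GroupDesign,
    activation_betas: np.ndarray,
) -> StatResult:
    """Group test on cluster CPC with task-activation betas as extra covariates.

    Asks whether the group difference in CPC survives adjustment for
    per-subject task activation (e.g. the 2-back GLM beta in the seed and in
    the cluster). Raises if the augmented design is collinear.
    """
    A = np.asarray(activation_betas, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    X = np.hstack([design.matrix, A - A.mean(axis=0)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("activation covariates are collinear with the design")
    t_all, df, _ = _ols_t(X, np.asarray(cluster_cpc, float)[:, None], col=design.group_col)
    t = float(t_all[0])
    p = float(2 * stats.t.sf(abs(t), df))
    n1 = int((design.matrix[:, design.group_col] > 0).sum())
    n2 = design.n - n1
    return StatResult(t, df, p, effect_size=cohens_d_from_t(t, n1, n2))
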