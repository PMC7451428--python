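"""Demographic-table statistics and cluster-level clinical associations.

Correlation machinery (Pearson / Spearman, plain and partial, with the
t-approximation p-value), the Fisher r-to-Z comparison of two independent
correlations, the Pearson chi-square on 2x2 demographic tables (no
continuity correction), a pooled-variance two-sample t-test from group
summaries, and the configurable association battery run on per-cluster
subject mean CPCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .inference import StatResult

__all__ = [
    "CorrelationResult",
    "correlate",
    "fisher_r_to_z_compare",
    "chi_square_2x2",
    "two_sample_t_summary",
    "AssociationTest",
    "association_battery",
]

_METHODS = ("pearson", "spearman", "partial-pearson", "partial-spearman")


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    n: int
    df: int
    p: float
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def _t_approx_p(r: float, df: int) -> float:
    """Two-sided p for a correlation via t = r * sqrt(df / (1 - r^2))."""
    if df <= 0:
        raise ValueError("non-positive df")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2 * stats.t.sf(abs(t), df))


def correlation_p(r: float, n: int, n_covariates: int = 0) -> float:
    """p-value for an observed correlation r at sample size n (t approximation)."""
    return _t_approx_p(r, n - 2 - n_covariates)


def _residualise(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(v.size), C])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "pearson",
    covariates: np.ndarray | None = None,
    covariate_names: tuple[str, ...] = (),
) -> CorrelationResult:
    """Correlation between x and y with optional covariate adjustment.

    Spearman is Pearson on average ranks. Partial correlations correlate the
    OLS residuals of x and y on the covariates (ranks are taken first for
    partial-spearman). p comes from the t approximation with
    df = n - 2 - #covariates.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x.size
    k = 0
    C = None
    if method.startswith("partial"):
        if covariates is None:
            C = np.empty((n, 0))
        else:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
        k = C.shape[1]
    if n < 4 + k:
        raise ValueError("sample too small for the requested correlation")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    if "spearman" in method:
        x = stats.rankdata(x)
        y = stats.rankdata(y)
        if C is not None and C.size:
            C = np.column_stack([stats.rankdata(c) for c in C.T])
    if C is not None and C.size:
        x = _residualise(x, C)
        y = _residualise(y, C)
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2 - k
    return CorrelationResult(method, r, n, df, _t_approx_p(r, df), tuple(covariate_names))


def fisher_r_to_z_compare(r1: float, n1: int, r2: float, n2: int,
                          tail: str = "greater") -> tuple[float, float]:
    """Compare two independent correlations via the arctanh transform.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)). ``tail``:
    'greater' tests r1 > r2 (upper-tail p), 'less' tests r1 < r2,
    'two-sided' doubles the smaller tail.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the Fisher transform")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both groups")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    if tail == "greater":
        p = float(stats.norm.sf(z))
    elif tail == "less":
        p = float(stats.norm.cdf(z))
    elif tail == "two-sided":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError("tail must be 'greater', 'less' or 'two-sided'")
    return float(z), p


def chi_square_2x2(table: np.ndarray) -> StatResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    T = np.asarray(table, dtype=float)
    if T.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(T < 0):
        raise ValueError("counts must be non-negative")
    if np.any(T.sum(axis=0) == 0) or np.any(T.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    chi2, p, df, _ = stats.chi2_contingency(T, correction=False)
    return StatResult(float(chi2), int(df), float(p))


def two_sample_t_summary(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int) -> StatResult:
    """Pooled-variance two-sample t from group summaries, df = n1 + n2 - 2."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return StatResult(float(t), n1 + n2 - 2, float(p))


@dataclass(frozen=True)
class AssociationTest:
    """One configured association: a subject variable against cluster CPC."""

    variable: str
    method: str  # 'pearson' | 'spearman'
    threshold: float  # significance threshold for this hypothesis
    group: str | None = None  # restrict to one group; None = pooled
    hypothesised: bool = False


DEFAULT_BATTERY = (
    AssociationTest("hit_rate", "spearman", 0.05, group=None),
    AssociationTest("hit_rate", "spearman", 0.05, group="HC"),
    AssociationTest("hit_rate", "spearman", 0.05, group="SZ"),
    AssociationTest("psychomotor_poverty", "spearman", 0.025, group="SZ", hypothesised=True),
    AssociationTest("disorganization", "spearman", 0.025, group="SZ", hypothesised=True),
    AssociationTest("reality_distortion", "spearman", 0.025, group="SZ", hypothesised=True),
    AssociationTest("sofas", "pearson", 0.05, group="SZ"),
    AssociationTest("sspi_total", "pearson", 0.05, group="SZ"),
    AssociationTest("dose_ddd", "spearman", 0.05, group="SZ"),
    AssociationTest("lifetime_exposure", "spearman", 0.05, group="SZ"),
)


def association_battery(
    cluster_means: pd.DataFrame,
    records: pd.DataFrame,
    tests: tuple[AssociationTest, ...] = DEFAULT_BATTERY,
    fisher_variables: tuple[str, ...] = ("hit_rate",),
    fisher_tail: str = "greater",
) -> pd.DataFrame:
    """Run the configured correlations for every cluster.

    ``cluster_means``: one column per cluster (name = cluster id), one row
    per subject, indexed consistently with ``records`` (which must carry a
    'group' column and every variable named by the tests). For each variable
    in ``fisher_variables`` the HC-vs-SZ correlation difference is tested by
    the one-tailed Fisher r-to-Z comparison. Returns a tidy results table.
    """
    if "group" not in records.columns:
        raise ValueError("records must contain a 'group' column")
    needed = {t.variable for t in tests} | set(fisher_variables)
    missing = sorted(needed - set(records.columns))
    if missing:
        raise ValueError(f"records missing score columns: {missing}")
    rows = []
    for cluster in cluster_means.columns:
        cpc = cluster_means[cluster].to_numpy(float)
        for t in tests:
            sel = np.ones(len(records), dtype=bool)
            if t.group is not None:
                sel = (records["group"] == t.group).to_numpy()
            v = records[t.variable].to_numpy(float)[sel]
            c = cpc[sel]
            ok = np.isfinite(v) & np.isfinite(c)
            v, c = v[ok], c[ok]
            if v.size < 4 or v.std() == 0 or c.std() == 0:
                continue
            res = correlate(c, v, method=t.method)
            rows.append(
                {
                    "cluster": cluster,
                    "variable": t.variable,
                    "method": t.method,
                    "group": t.group or "all",
                    "r": res.r,
                    "n": res.n,
                    "p": res.p,
                    "threshold": t.threshold,
                    "significant": res.p < t.threshold,
                    "test": "correlation",
                }
            )
        for var in fisher_variables:
            per_group = {}
            for g in ("HC", "SZ"):
                sel = (records["group"] == g).to_numpy()
                v = records[var].to_numpy(float)[sel]
                c = cpc[sel]
                ok = np.isfinite(v) & np.isfinite(c)
                if ok.sum() < 4 or v[ok].std() == 0 or c[ok].std() == 0:
                    per_group = {}
                    break
                per_group[g] = (float(np.corrcoef(c[ok], v[ok])[0, 1]), int(ok.sum()))
            if not per_group:
                continue
            (r_hc, n_hc), (r_sz, n_sz) = per_group["HC"], per_group["SZ"]
            z, p = fisher_r_to_z_compare(r_hc, n_hc, r_sz, n_sz, tail=fisher_tail)
            rows.append(
                {
                    "cluster": cluster,
                    "variable": var,
                    "method": "fisher_r_to_z",
                    "group": "HC_vs_SZ",
                    "r": z,  # the z statistic occupies the statistic column
                    "n": n_hc + n_sz,
                    "p": p,
                    "threshold": 0.05,
                    "significant": p < 0.05,
                    "test": "correlation_difference",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cluster", "variable", "method", "group", "r", "n", "p",
                 "threshold", "significant", "test"],
    )
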