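"""Seed-based effective connectivity via lag-1 Granger path coefficients.

The path coefficient (PC) between a source series x and a target series y is
the signed ordinary-least-squares coefficient of x_{t-1} in

    y_t = c + a * y_{t-1} + b * x_{t-1} + e_t

computed on z-scored series, so b is a standardised directed-influence
measure: past x predicting present y beyond y's own past. Maps are formed in
both directions (seed -> every voxel, every voxel -> seed), for the resting
state (full retained series) and the task state (within-condition blocks,
detrended and normalised per block, averaged across blocks). The change of
path coefficient (CPC) is the voxelwise task - rest difference — the central
statistic of the rest-to-task shifting analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .design import TaskDesign
from .volumes import Volume4D

__all__ = [
    "PCMap",
    "CPCMap",
    "path_coefficient",
    "seed_pc_map",
    "blockwise_task_pc",
    "cpc_map",
    "fc_change_map",
]

log = logging.getLogger(__name__)

SEED_TO_BRAIN = "seed_to_brain"
BRAIN_TO_SEED = "brain_to_seed"
_DIRECTIONS = (SEED_TO_BRAIN, BRAIN_TO_SEED)

MIN_BLOCK_VOLUMES = 6


@dataclass
class PCMap:
    """Per-voxel signed path coefficients for one direction and state."""

    values: np.ndarray  # 3-D grid, zero outside mask
    direction: str
    state: str  # "rest" | "task"
    mask: np.ndarray
    affine: np.ndarray
    n_blocks: int | None = None
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite path coefficients inside mask")

    def flat(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class CPCMap:
    """Voxelwise change of path coefficient: task minus rest."""

    values: np.ndarray
    direction: str
    mask: np.ndarray
    affine: np.ndarray

    def flat(self) -> np.ndarray:
        return self.values[self.mask]


def _zscore(a: np.ndarray, axis: int = -1) -> np.ndarray:
    m = a.mean(axis=axis, keepdims=True)
    s = a.std(axis=axis, keepdims=True)
    s = np.where(s > 0, s, 1.0)
    return (a - m) / s


def path_coefficient(x: np.ndarray, y: np.ndarray, lag: int = 1) -> float:
    """Signed lag coefficient of x on y (both z-scored) in a bivariate AR fit.

    Fits ``y_t ~ 1 + y_{t-lag} + x_{t-lag}`` by OLS and returns the x
    coefficient. Raises on constant series or series too short to fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    T = x.size
    if T < lag + 3:
        raise ValueError(f"series of length {T} too short for lag {lag}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant series has no defined path coefficient")
    xz, yz = _zscore(x), _zscore(y)
    X = np.column_stack([np.ones(T - lag), yz[:-lag], xz[:-lag]])
    beta, *_ = np.linalg.lstsq(X, yz[lag:], rcond=None)
    return float(beta[2])


def _batch_pc_to_targets(src: np.ndarray, targets: np.ndarray, lag: int) -> tuple[np.ndarray, int]:
    """PC of one source series into many target series (z-scored rows).

    targets: (V, T); returns (V,) coefficients and the degenerate-row count.
    Degenerate (zero-variance) targets get coefficient 0.
    """
    V, T = targets.shape
    sd = targets.std(axis=1)
    degen = sd == 0
    tz = _zscore(targets)
    sz = _zscore(src)
    a = tz[:, :-lag]  # y_{t-1}, per voxel
    b = sz[:-lag]  # x_{t-1}, shared
    c = tz[:, lag:]  # y_t
    return _solve_lag_regression(a, b, c, degen), int(degen.sum())


def _batch_pc_from_sources(sources: np.ndarray, tgt: np.ndarray, lag: int) -> tuple[np.ndarray, int]:
    """PC of many source series into one target series."""
    sd = sources.std(axis=1)
    degen = sd == 0
    sz = _zscore(sources)
    tz = _zscore(tgt)
    a = np.broadcast_to(tz[:-lag], (sources.shape[0], tgt.size - lag))
    b_rows = sz[:, :-lag]
    c = np.broadcast_to(tz[lag:], a.shape)
    return _solve_lag_regression(a, b_rows, c, degen), int(degen.sum())


def _solve_lag_regression(a, b, c, degen) -> np.ndarray:
    """Rowwise OLS of c on [1, a, b_row]; returns the b coefficient per row.

    ``a`` and ``c`` are (V, n); ``b`` is (n,) shared or (V, n) rowwise.
    Solved via per-row 3x3 normal equations.
    """
    V, n = a.shape
    if b.ndim == 1:
        b = np.broadcast_to(b, (V, n))
    Sa = a.sum(axis=1)
    Sb = b.sum(axis=1)
    Sc = c.sum(axis=1)
    Saa = (a * a).sum(axis=1)
    Sbb = (b * b).sum(axis=1)
    Sab = (a * b).sum(axis=1)
    Sac = (a * c).sum(axis=1)
    Sbc = (b * c).sum(axis=1)
    G = np.empty((V, 3, 3))
    G[:, 0, 0] = n
    G[:, 0, 1] = G[:, 1, 0] = Sa
    G[:, 0, 2] = G[:, 2, 0] = Sb
    G[:, 1, 1] = Saa
    G[:, 1, 2] = G[:, 2, 1] = Sab
    G[:, 2, 2] = Sbb
    rhs = np.stack([Sc, Sac, Sbc], axis=1)
    coef = np.zeros(V)
    ok = ~degen
    if ok.any():
        try:
            sol = np.linalg.solve(G[ok], rhs[ok][..., None])[..., 0]
        except np.linalg.LinAlgError:
            sol = np.stack(
                [np.linalg.lstsq(Gi, ri, rcond=None)[0] for Gi, ri in zip(G[ok], rhs[ok])]
            )
        coef[ok] = sol[:, 2]
    return coef


def seed_pc_map(vol: Volume4D, seed_ts: np.ndarray, direction: str, lag: int = 1,
                state: str = "rest") -> PCMap:
    """Whole-brain PC map between the seed series and every in-mask voxel."""
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    seed_ts = np.asarray(seed_ts, dtype=float)
    if seed_ts.shape != (vol.n_vols,):
        raise ValueError("seed series length must match volume count")
    series = vol.masked_series()
    if direction == SEED_TO_BRAIN:
        coef, n_degen = _batch_pc_to_targets(seed_ts, series, lag)
    else:
        coef, n_degen = _batch_pc_from_sources(series, seed_ts, lag)
    if n_degen:
        log.info("seed_pc_map: %d degenerate voxels set to 0", n_degen)
    return PCMap(
        values=vol.map_like(coef),
        direction=direction,
        state=state,
        mask=vol.mask.copy(),
        affine=vol.affine.copy(),
        n_degenerate=n_degen,
    )


def _detrend_demean(a: np.ndarray) -> np.ndarray:
    """Remove a linear trend (and hence the mean) along the last axis."""
    n = a.shape[-1]
    t = np.arange(n) - (n - 1) / 2.0
    slope = (a * t).sum(axis=-1, keepdims=True) / (t * t).sum()
    out = a - slope * t
    return out - out.mean(axis=-1, keepdims=True)


def block_volume_indices(design: TaskDesign, tr: float, n_vols: int,
                         condition: str = "2-back", offset: float = 0.0) -> list[np.ndarray]:
    """Volume indices per condition window, by acquisition midpoint.

    A volume belongs to a window iff its midpoint (i + 0.5) * tr + offset
    falls inside [start, end).
    """
    mid = (np.arange(n_vols) + 0.5) * tr + offset
    out = []
    for start, end in design.condition_windows(condition):
        idx = np.flatnonzero((mid >= start) & (mid < end))
        if idx.size:
            out.append(idx)
    return out


def blockwise_task_pc(
    vol: Volume4D,
    seed_ts: np.ndarray,
    design: TaskDesign,
    condition: str = "2-back",
    direction: str = SEED_TO_BRAIN,
    lag: int = 1,
    zscore_blocks: bool = True,
    block_offset: float = 0.0,
) -> PCMap:
    """Task-state PC map from within-condition blocks.

    Each block's volumes are linearly detrended and mean-centred (z-scored
    by default); the PC is computed per block and averaged (unweighted)
    across blocks. Blocks with fewer than 6 volumes are dropped with a
    warning; estimation fails if none survive.
    """
    blocks = block_volume_indices(design, vol.tr, vol.n_vols, condition, block_offset)
    usable = [b for b in blocks if b.size >= MIN_BLOCK_VOLUMES]
    dropped = len(blocks) - len(usable)
    if dropped:
        log.warning("blockwise_task_pc: dropped %d blocks shorter than %d volumes",
                    dropped, MIN_BLOCK_VOLUMES)
    if len(usable) == 0:
        raise ValueError("no usable blocks for condition %r" % condition)
    series = vol.masked_series()
    seed_ts = np.asarray(seed_ts, dtype=float)
    acc = np.zeros(series.shape[0])
    n_degen = 0
    for idx in usable:
        sv = _detrend_demean(series[:, idx])
        ss = _detrend_demean(seed_ts[idx])
        if zscore_blocks:
            sd = sv.std(axis=1, keepdims=True)
            sv = sv / np.where(sd > 0, sd, 1.0)
            s_sd = ss.std()
            ss = ss / (s_sd if s_sd > 0 else 1.0)
        if direction == SEED_TO_BRAIN:
            coef, nd = _batch_pc_to_targets_pre(ss, sv, lag)
        elif direction == BRAIN_TO_SEED:
            coef, nd = _batch_pc_from_sources_pre(sv, ss, lag)
        else:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")
        acc += coef
        n_degen = max(n_degen, nd)
    mean_coef = acc / len(usable)
    return PCMap(
        values=vol.map_like(mean_coef),
        direction=direction,
        state="task",
        mask=vol.mask.copy(),
        affine=vol.affine.copy(),
        n_blocks=len(usable),
        n_degenerate=n_degen,
    )


def _batch_pc_to_targets_pre(src, targets, lag):
    """As _batch_pc_to_targets but on already-normalised block segments."""
    degen = targets.std(axis=1) == 0
    return _solve_lag_regression(targets[:, :-lag], src[:-lag], targets[:, lag:], degen), int(degen.sum())


def _batch_pc_from_sources_pre(sources, tgt, lag):
    degen = sources.std(axis=1) == 0
    V = sources.shape[0]
    n = tgt.size - lag
    a = np.broadcast_to(tgt[:-lag], (V, n))
    c = np.broadcast_to(tgt[lag:], (V, n))
    return _solve_lag_regression(a, sources[:, :-lag], c, degen), int(degen.sum())


def cpc_map(pc_task: PCMap, pc_rest: PCMap) -> CPCMap:
    """Change of path coefficient: voxelwise task minus rest."""
    if pc_task.direction != pc_rest.direction:
        raise ValueError("PC maps have different directions")
    if pc_task.values.shape != pc_rest.values.shape or not np.array_equal(
        pc_task.mask, pc_rest.mask
    ):
        raise ValueError("PC maps are on different grids/masks")
    if not np.allclose(pc_task.affine, pc_rest.affine):
        raise ValueError("PC maps have different affines")
    values = np.where(pc_task.mask, pc_task.values - pc_rest.values, 0.0)
    return CPCMap(
        values=values,
        direction=pc_task.direction,
        mask=pc_task.mask.copy(),
        affine=pc_task.affine.copy(),
    )


def fc_change_map(
    vol_rest: Volume4D,
    seed_rest: np.ndarray,
    vol_task: Volume4D,
    seed_task: np.ndarray,
    design: TaskDesign,
    condition: str = "2-back",
) -> CPCMap:
    """Functional-connectivity change control: Pearson r (task) - r (rest).

    Rest correlation uses the full preprocessed rest series; the task
    correlation is computed per condition block (after detrend/demean) and
    averaged across blocks, mirroring the PC estimation protocol but with an
    undirected statistic.
    """
    rest_series = vol_rest.masked_series()
    r_rest = _rowwise_corr(rest_series, np.asarray(seed_rest, float))

    blocks = block_volume_indices(design, vol_task.tr, vol_task.n_vols, condition)
    usable = [b for b in blocks if b.size >= MIN_BLOCK_VOLUMES]
    if not usable:
        raise ValueError("no usable blocks for condition %r" % condition)
    task_series = vol_task.masked_series()
    seed_task = np.asarray(seed_task, float)
    acc = np.zeros(task_series.shape[0])
    for idx in usable:
        acc += _rowwise_corr(_detrend_demean(task_series[:, idx]), _detrend_demean(seed_task[idx]))
    r_task = acc / len(usable)
    values = vol_rest.map_like(r_task - r_rest)
    return CPCMap(values=values, direction=SEED_TO_BRAIN,
                  mask=vol_rest.mask.copy(), affine=vol_rest.affine.copy())


def _rowwise_corr(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((rc * rc).sum(axis=1) * (vc * vc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rc @ vc) / denom
    return np.nan_to_num(r)
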