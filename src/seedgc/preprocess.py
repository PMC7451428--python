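"""Preprocessing chain for already-normalised BOLD volumes.

Implements the stages applied before connectivity estimation: initial-volume
discard, framewise displacement (FD), motion/performance exclusion screening,
motion scrubbing by temporal interpolation, isotropic Gaussian smoothing,
ideal band-pass filtering (rest), HRF-convolved task regressors, nuisance
regression, and seed time-series extraction from an MNI sphere.

Default chain order (rest): discard -> scrub -> smooth -> band-pass ->
nuisance regression. The task chain replaces the band-pass with task-design
regressors appended to the nuisance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .design import TaskDesign
from .hrf import HRFParams, canonical_hrf
from .volumes import ConfoundSet, Volume4D

__all__ = [
    "SeedSpec",
    "discard_initial_volumes",
    "compute_fd",
    "exclusion_screen",
    "scrub_interpolate",
    "spatial_smooth",
    "temporal_bandpass",
    "build_task_regressors",
    "nuisance_regress",
    "extract_seed_ts",
    "preprocess_rest",
    "preprocess_task",
]

log = logging.getLogger(__name__)

FD_ROTATION_RADIUS_MM = 50.0


@dataclass(frozen=True)
class SeedSpec:
    """Spherical seed region in MNI mm (right anterior insula by default)."""

    center: tuple[float, float, float] = (33.0, 21.0, -3.0)
    radius: float = 6.0


def discard_initial_volumes(
    vol: Volume4D, confounds: ConfoundSet | None, n: int
) -> tuple[Volume4D, ConfoundSet | None]:
    """Drop the first ``n`` volumes (T1-equilibration) and matching confound rows."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= vol.n_vols:
        raise ValueError(f"cannot discard {n} of {vol.n_vols} volumes")
    if n == 0:
        return vol, confounds
    out_vol = vol.with_data(vol.data[..., n:])
    out_conf = confounds.sliced(slice(n, None)) if confounds is not None else None
    return out_vol, out_conf


def compute_fd(motion: np.ndarray, rotation_radius: float = FD_ROTATION_RADIUS_MM
               ) -> tuple[np.ndarray, float]:
    """Scalar framewise displacement (Power convention).

    fd_t = sum |Δ translations| + r * sum |Δ rotations|, rotations in radians
    converted to arc length on a sphere of radius ``rotation_radius`` (50 mm).
    fd_0 = 0; mean FD averages t >= 1.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a (T, 6) array")
    if motion.shape[0] < 2:
        raise ValueError("need at least two timepoints for FD")
    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + rotation_radius * np.abs(d[:, 3:]).sum(axis=1)
    fd = np.concatenate([[0.0], fd])
    return fd, float(fd[1:].mean())


def exclusion_screen(
    record,
    motion: np.ndarray,
    max_translation_mm: float = 3.0,
    max_rotation_deg: float = 3.0,
    min_hit_rate: float = 30.0,
    task: bool = True,
) -> tuple[bool, str]:
    """Apply the study's subject-exclusion rules.

    Excludes on head motion *exceeding* 3.0 mm translation or 3.0 degrees
    rotation (strict inequality), or a hit rate below 30% (task data only).

    Returns ``(keep, reason)`` with ``reason == ""`` when kept.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a (T, 6) array")
    if np.abs(motion[:, :3]).max() > max_translation_mm:
        return False, "motion: translation exceeds limit"
    if np.abs(np.degrees(motion[:, 3:])).max() > max_rotation_deg:
        return False, "motion: rotation exceeds limit"
    if task:
        hit = getattr(record, "hit_rate", None)
        if hit is None or (isinstance(hit, float) and np.isnan(hit)):
            raise ValueError("hit_rate required to screen task data")
        if hit < min_hit_rate:
            return False, "performance: hit rate below 30%"
    return True, ""


def scrub_interpolate(vol: Volume4D, fd: np.ndarray, threshold: float = 0.5) -> Volume4D:
    """Replace high-motion volumes by linear interpolation between clean neighbours.

    Timepoints with fd > threshold are rebuilt voxelwise from the nearest
    unflagged timepoints on either side (nearest-neighbour at the ends). A
    temporal-interpolation stand-in for repair-style deweighting.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (vol.n_vols,):
        raise ValueError("fd length must match volume count")
    bad = fd > threshold
    if not bad.any():
        return vol
    if bad.all():
        raise ValueError("all timepoints flagged for scrubbing")
    good_idx = np.flatnonzero(~bad)
    t = np.arange(vol.n_vols)
    data = vol.data.copy()
    flat = data.reshape(-1, vol.n_vols)
    # np.interp clamps at the ends -> nearest-neighbour endpoint handling
    for row in flat:
        row[bad] = np.interp(t[bad], good_idx, row[good_idx])
    return vol.with_data(flat.reshape(vol.data.shape))


def spatial_smooth(vol: Volume4D, fwhm: float) -> Volume4D:
    """Isotropic 3-D Gaussian smoothing with FWHM in mm; mask re-applied."""
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return vol
    vs = vol.voxel_sizes
    if np.any(vs <= 0):
        raise ValueError("voxel sizes must be positive")
    sigma_vox = (fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / vs
    data = ndimage.gaussian_filter(vol.data, sigma=(*sigma_vox, 0.0), mode="constant")
    data[~vol.mask] = 0.0
    return vol.with_data(data)


def temporal_bandpass(vol: Volume4D, low: float, high: float) -> Volume4D:
    """Ideal frequency-domain band-pass per voxel (DC removed).

    Retains Fourier bins with ``low <= |f| <= high``; everything else,
    including the DC term, is zeroed, so outputs are zero-mean.
    """
    nyq = 0.5 / vol.tr
    if not (0 <= low < high):
        raise ValueError("need 0 <= low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    T = vol.n_vols
    freqs = np.fft.rfftfreq(T, d=vol.tr)
    keep = (freqs >= low) & (freqs <= high) & (freqs > 0)
    spec = np.fft.rfft(vol.data, axis=-1)
    spec[..., ~keep] = 0.0
    data = np.fft.irfft(spec, n=T, axis=-1)
    data[~vol.mask] = 0.0
    return vol.with_data(data)


def build_task_regressors(
    design: TaskDesign,
    tr: float,
    n_vols: int,
    hrf_params: HRFParams | None = None,
    hrf_dt: float = 0.1,
    labels: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """One HRF-convolved boxcar regressor column per condition label.

    Boxcars are built on a fine grid (``hrf_dt`` s), convolved session-wise
    with the canonical HRF, then sampled at volume midpoints.
    """
    if tr <= 0 or n_vols <= 0:
        raise ValueError("tr and n_vols must be positive")
    total = n_vols * tr
    if design.blocks and design.total_duration > total + tr:
        raise ValueError(
            f"design spans {design.total_duration:.0f}s but scan covers {total:.0f}s"
        )
    labels = labels if labels is not None else design.labels()
    n_fine = int(np.ceil(total / hrf_dt)) + 1
    t_fine = np.arange(n_fine) * hrf_dt
    kernel = canonical_hrf(np.arange(0.0, 32.0 + hrf_dt, hrf_dt), hrf_params)
    # unit-sum kernel: a sustained boxcar then plateaus at ~1 regardless of
    # the fine-grid resolution
    kernel = kernel / kernel.sum()
    t_mid = (np.arange(n_vols) + 0.5) * tr
    cols = np.zeros((n_vols, len(labels)))
    for j, lab in enumerate(labels):
        conv = np.zeros(n_fine)
        for ses in range(design.n_sessions):
            box = np.zeros(n_fine)
            for start, end in design.condition_windows(lab, session=ses):
                box[(t_fine >= start) & (t_fine < end)] = 1.0
            # session-wise convolution: response from one session never bleeds
            # into another beyond its own samples
            ses_lo = ses * design.session_duration
            ses_hi = (ses + 1) * design.session_duration if ses < design.n_sessions - 1 else np.inf
            in_ses = (t_fine >= ses_lo) & (t_fine < ses_hi)
            conv_ses = np.convolve(box[in_ses], kernel)[: in_ses.sum()]
            conv[in_ses] += conv_ses
        cols[:, j] = np.interp(t_mid, t_fine, conv)
    return cols, list(labels)


def nuisance_regress(vol: Volume4D, regressors: np.ndarray) -> Volume4D:
    """Per-voxel OLS residuals after projecting out [intercept | regressors]."""
    R = np.asarray(regressors, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    if R.shape[0] != vol.n_vols:
        raise ValueError("regressor rows must equal volume count")
    X = np.column_stack([np.ones(R.shape[0]), R])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the caller
        bad = []
        for j in range(1, X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(j - 1)
        raise ValueError(f"rank-deficient nuisance matrix; collinear columns: {bad}")
    Y = vol.masked_series().T  # (T, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    data = np.zeros_like(vol.data)
    data[vol.mask] = resid
    return vol.with_data(data)


def seed_voxel_indices(vol: Volume4D, seed: SeedSpec) -> np.ndarray:
    """(K, 3) voxel indices whose centres lie within the seed sphere and mask."""
    ijk = np.argwhere(vol.mask)
    mm = vol.ijk_to_mm(ijk)
    d = np.linalg.norm(mm - np.asarray(seed.center), axis=1)
    inside = ijk[d <= seed.radius]
    if inside.size == 0:
        # fall back: a sub-voxel radius still selects the voxel containing the centre
        centre_ijk = np.round(vol.mm_to_ijk(np.asarray(seed.center))[0]).astype(int)
        if (
            np.all(centre_ijk >= 0)
            and np.all(centre_ijk < vol.shape)
            and vol.mask[tuple(centre_ijk)]
        ):
            inside = centre_ijk[None, :]
    return inside


def extract_seed_ts(vol: Volume4D, seed: SeedSpec) -> np.ndarray:
    """Mean time series over in-mask voxels within the seed sphere."""
    idx = seed_voxel_indices(vol, seed)
    if idx.size == 0:
        raise ValueError(f"seed sphere at {seed.center} mm does not intersect the mask")
    return vol.data[idx[:, 0], idx[:, 1], idx[:, 2], :].mean(axis=0)


# ---------------------------------------------------------------------------
# state-specific chains


def preprocess_rest(
    vol: Volume4D,
    confounds: ConfoundSet,
    n_discard: int = 5,
    scrub_threshold: float = 0.5,
    fwhm: float = 8.0,
    band: tuple[float, float] = (0.01, 0.08),
) -> tuple[Volume4D, ConfoundSet]:
    """Rest chain: discard -> scrub -> smooth -> band-pass -> nuisance regression."""
    vol, confounds = discard_initial_volumes(vol, confounds, n_discard)
    vol = scrub_interpolate(vol, confounds.fd, scrub_threshold)
    vol = spatial_smooth(vol, fwhm)
    vol = temporal_bandpass(vol, *band)
    vol = nuisance_regress(vol, confounds.regressors())
    return vol, confounds


def preprocess_task(
    vol: Volume4D,
    confounds: ConfoundSet,
    design: TaskDesign,
    scrub_threshold: float = 0.5,
    fwhm: float = 8.0,
    hrf_params: HRFParams | None = None,
) -> tuple[Volume4D, ConfoundSet]:
    """Task chain: scrub -> smooth -> nuisance + HRF-convolved task regressors.

    The state-specific global/WM/CSF signals recorded in ``confounds`` are
    regressed together with one regressor per condition, removing signal
    shared with the task design before connectivity estimation.
    """
    vol = scrub_interpolate(vol, confounds.fd, scrub_threshold)
    vol = spatial_smooth(vol, fwhm)
    task_cols, _ = build_task_regressors(design, vol.tr, vol.n_vols, hrf_params)
    R = np.hstack([confounds.regressors(), task_cols])
    vol = nuisance_regress(vol, R)
    return vol, confounds
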