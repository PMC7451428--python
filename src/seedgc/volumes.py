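"""In-memory containers for 4D BOLD-like data and per-timepoint confounds."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["Volume4D", "ConfoundSet", "MOTION_COLUMNS", "CONFOUND_COLUMNS"]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
CONFOUND_COLUMNS = MOTION_COLUMNS + ["global", "wm", "csf"]


@dataclass
class Volume4D:
    """A masked 4D voxel time-series grid with affine (voxel -> MNI mm) and TR.

    ``data`` has shape (X, Y, Z, T); ``mask`` has shape (X, Y, Z). Operations
    in the pipeline transform ``data`` but never the affine or the mask shape.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("Volume4D data must be 4-D (x, y, z, t)")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial shape")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_vols(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def ijk_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def mm_to_ijk(self, mm: np.ndarray) -> np.ndarray:
        mm = np.atleast_2d(np.asarray(mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ mm.T).T + inv[:3, 3]

    def volume_times(self, offset: float = 0.5) -> np.ndarray:
        """Acquisition midpoint (default) of each volume in seconds."""
        return (np.arange(self.n_vols) + offset) * self.tr

    # -- views --------------------------------------------------------------
    def masked_series(self) -> np.ndarray:
        """(V, T) array of in-mask voxel series."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray) -> "Volume4D":
        return Volume4D(data=data, affine=self.affine.copy(), tr=self.tr, mask=self.mask.copy())

    def map_like(self, flat: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a (V,) in-mask vector back onto the 3-D grid."""
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask] = flat
        return out

    # -- I/O ----------------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_sizes, self.tr))
        return img

    @classmethod
    def from_nifti(cls, img: "nib.Nifti1Image | str", tr: float | None = None,
                   mask: np.ndarray | None = None) -> "Volume4D":
        if isinstance(img, (str,)):
            img = nib.load(img)
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        if tr is None:
            zooms = img.header.get_zooms()
            tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        return cls(data=data, affine=np.asarray(img.affine), tr=tr, mask=mask)


@dataclass
class ConfoundSet:
    """Per-timepoint nuisance regressors plus framewise displacement.

    motion: (T, 6) — translations in mm then rotations in radians.
    tissue: (T, 3) — global / white-matter / CSF mean signals.
    """

    motion: np.ndarray
    tissue: np.ndarray
    fd: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.motion = np.asarray(self.motion, dtype=float)
        self.tissue = np.asarray(self.tissue, dtype=float)
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValueError("motion must have 6 columns")
        if self.tissue.shape != (self.motion.shape[0], 3):
            raise ValueError("tissue must be (T, 3): global, wm, csf")
        if self.fd is None:
            from .preprocess import compute_fd

            self.fd, _ = compute_fd(self.motion)
        self.fd = np.asarray(self.fd, dtype=float)
        if self.fd.shape != (self.motion.shape[0],):
            raise ValueError("fd length must equal motion length")

    def __len__(self) -> int:
        return self.motion.shape[0]

    @property
    def mean_fd(self) -> float:
        return float(self.fd[1:].mean()) if len(self) > 1 else 0.0

    def regressors(self) -> np.ndarray:
        """(T, 9) nuisance matrix: 6 motion + global + wm + csf."""
        return np.hstack([self.motion, self.tissue])

    def sliced(self, sl: slice | np.ndarray) -> "ConfoundSet":
        out = ConfoundSet(self.motion[sl], self.tissue[sl], fd=self.fd[sl])
        if len(out):
            out.fd = out.fd.copy()
            out.fd[0] = 0.0
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(np.hstack([self.motion, self.tissue]), columns=CONFOUND_COLUMNS)
        df["fd"] = self.fd
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConfoundSet":
        missing = [c for c in CONFOUND_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"confound table missing columns: {missing}")
        motion = df[MOTION_COLUMNS].to_numpy(float)
        tissue = df[["global", "wm", "csf"]].to_numpy(float)
        fd = df["fd"].to_numpy(float) if "fd" in df.columns else None
        return cls(motion, tissue, fd=fd)
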