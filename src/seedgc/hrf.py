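"""Canonical haemodynamic response function.

The double-gamma form used throughout block-design fMRI modelling: a
positive gamma density peaking ~5 s after stimulus onset minus a scaled
gamma density producing the post-stimulus undershoot. Defaults match the
conventional parameterisation (peak delay 6 s, undershoot delay 16 s,
unit dispersions, peak:undershoot ratio 6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HRFParams", "canonical_hrf"]


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF parameters (all times in seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0

    def validate(self) -> None:
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("HRF dispersion parameters must be positive")
        if self.peak_delay <= 0 or self.undershoot_delay <= 0:
            raise ValueError("HRF delay parameters must be positive")
        if self.ratio <= 0:
            raise ValueError("HRF peak:undershoot ratio must be positive")


def canonical_hrf(t_grid: np.ndarray, params: HRFParams | None = None) -> np.ndarray:
    """Sample the canonical double-gamma HRF on ``t_grid``.

    Parameters
    ----------
    t_grid:
        Non-negative, strictly increasing sample times in seconds.
    params:
        Double-gamma parameters; defaults give the standard kernel.

    Returns
    -------
    Kernel values normalised so the maximum equals 1. ``h(0) == 0`` and a
    negative undershoot follows the positive peak.
    """
    params = params or HRFParams()
    params.validate()
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(t < 0):
        raise ValueError("t_grid must be non-negative")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    # gamma density with shape = delay/dispersion, scale = dispersion puts
    # the mode at delay - dispersion (≈5 s for the default peak)
    peak = stats.gamma.pdf(
        t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    h = peak - under / params.ratio
    peak_val = h.max()
    if peak_val <= 0:
        raise ValueError("degenerate HRF: no positive peak on the given grid")
    return h / peak_val
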