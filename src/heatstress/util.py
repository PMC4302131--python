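"""Small shared helpers: signed-ratio fold changes and validation errors."""

from __future__ import annotations

import numpy as np


class ConfigurationError(ValueError):
    """Raised when an input table or configuration violates a precondition."""


def signed_ratio(ratio: float | np.ndarray) -> float | np.ndarray:
    """Convert a positive linear-scale ratio to the signed-ratio convention.

    A ratio r >= 1 is reported as +r; a ratio r < 1 as -1/r, so |FC| >= 1
    always and "2-fold down" prints as -2.0.
    """
    arr = np.asarray(ratio, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("ratios must be strictly positive")
    out = np.where(arr >= 1.0, arr, -1.0 / arr)
    if np.isscalar(ratio) or arr.ndim == 0:
        return float(out)
    return out


def unsigned_ratio(fc: float | np.ndarray) -> float | np.ndarray:
    """Invert :func:`signed_ratio`: map a signed fold change back to a ratio."""
    arr = np.asarray(fc, dtype=float)
    if np.any(np.abs(arr) < 1.0):
        raise ValueError("signed fold changes satisfy |FC| >= 1")
    out = np.where(arr >= 0, arr, -1.0 / arr)
    if np.isscalar(fc) or arr.ndim == 0:
        return float(out)
    return out
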