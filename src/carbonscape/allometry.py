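"""Canopy-height-to-carbon allometry.

Aboveground carbon density (ACD, Mg C ha^-1) is derived from mean
top-of-canopy height (TCH, m) by a fixed power law

    ACD = a * TCH**b,    a = 0.3124, b = 1.854

calibrated for western Amazonian forests.  The coefficients are frozen
constants here (upscaling results are insensitive to modest recalibration,
and refitting from plot data is out of scope); both are overridable through
:class:`AllometryParams` for sensitivity runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import Grid

__all__ = ["AllometryParams", "DEFAULT_ALLOMETRY", "acd_from_tch"]


@dataclass(frozen=True)
class AllometryParams:
    """Power-law coefficients ACD = a * TCH**b.

    ``a`` has units Mg C ha^-1 m^-b; ``b`` is dimensionless.  Both must be
    positive.
    """

    a: float = 0.3124
    b: float = 1.854

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"allometry coefficients must be positive, got a={self.a}, b={self.b}")


DEFAULT_ALLOMETRY = AllometryParams()


def acd_from_tch(tch, params: AllometryParams = DEFAULT_ALLOMETRY):
    """Convert top-of-canopy height to aboveground carbon density.

    Accepts a scalar, an array, or a :class:`Grid` (nodata propagates).
    Negative heights are a domain error; ACD(0) = 0 and ACD is strictly
    increasing in TCH.
    """
    if isinstance(tch, Grid):
        valid = tch.valid_mask()
        vals = np.asarray(tch.values, dtype=float)
        n_neg = int(np.count_nonzero(vals[valid] < 0))
        if n_neg:
            raise ValueError(f"TCH must be non-negative; {n_neg} pixel(s) are negative")
        out = np.full_like(vals, tch.nodata)
        out[valid] = params.a * np.power(vals[valid], params.b)
        return tch.like(out)
    arr = np.asarray(tch, dtype=float)
    n_neg = int(np.count_nonzero(arr < 0))
    if n_neg:
        raise ValueError(f"TCH must be non-negative; {n_neg} value(s) are negative")
    out = params.a * np.power(arr, params.b)
    return out if arr.ndim else float(out)
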