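"""delta-notation conversions between isotopologue mole fractions and delta13C."""

from __future__ import annotations

import numpy as np

from .constants import R_VPDB

__all__ = ["compute_delta", "split_isotopologues", "invert_discrimination"]


def compute_delta(x626, x636, r_vpdb: float = R_VPDB):
    """delta13C (permil, V-PDB) from the two isotopologue mole fractions.

    delta = ((x636/x626) / R_VPDB - 1) * 1000. Raises on x626 <= 0.
    """
    x626 = np.asarray(x626, dtype=float)
    if np.any(x626 <= 0):
        raise ValueError("x626 must be > 0")
    out = (np.asarray(x636, dtype=float) / x626 / r_vpdb - 1.0) * 1e3
    return float(out) if out.ndim == 0 else out


def split_isotopologues(c_total, delta_permil, r_vpdb: float = R_VPDB):
    """Exact inverse of :func:`compute_delta` at fixed total CO2.

    Returns ``(x626, x636)`` with x626 + x636 = c_total and
    x636/x626 = R_VPDB * (1 + delta/1000).
    """
    c = np.asarray(c_total, dtype=float)
    r = r_vpdb * (1.0 + np.asarray(delta_permil, dtype=float) / 1e3)
    x626 = c / (1.0 + r)
    return x626, c - x626


def invert_discrimination(disc_permil, xi, delta_in_permil):
    """Outlet delta13C (permil) realising a prescribed discrimination.

    Solves D = xi*(d_out - d_in) / (1 + d_out - xi*(d_out - d_in)) for
    d_out, all deltas handled as fractions internally. NaN propagates.
    """
    big_d = np.asarray(disc_permil, dtype=float) / 1e3
    d_in = np.asarray(delta_in_permil, dtype=float) / 1e3
    xi = np.asarray(xi, dtype=float)
    y = big_d / (1.0 + big_d)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_out = (y + xi * d_in) / (xi - y)
    out = d_out * 1e3
    return float(out) if np.ndim(out) == 0 else out
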