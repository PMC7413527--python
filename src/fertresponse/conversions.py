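"""Scalar measurement conversions and agronomic indices.

All functions accept scalars or numpy arrays and are vectorized.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "walkley_black_to_dumas",
    "ph_cacl2_to_water",
    "bray2_to_mehlich3",
    "specific_gravity",
    "elemental_to_oxide",
    "phosphorus_saturation_index",
    "P2O5_PER_P",
    "K2O_PER_K",
]

#: Elemental P -> P2O5 mass conversion factor (M(P2O5) / 2 M(P)).
P2O5_PER_P = 2.291
#: Elemental K -> K2O mass conversion factor (M(K2O) / 2 M(K)).
K2O_PER_K = 1.205

#: Floor for converted Mehlich-3 P, mg/kg. The Bray-2 regression crosses zero
#: near 40.2 mg/kg; concentrations below the floor are non-physical for
#: log-ratio work and get clamped + flagged.
MEHLICH3_P_FLOOR = 1.0


def walkley_black_to_dumas(c_wb):
    """Convert Walkley-Black soil carbon (%) to Dumas-combustion carbon (%).

    ``dumas = 0.126 + 1.25 * walkley_black``
    """
    c = np.asarray(c_wb, dtype=float)
    if np.any(c < 0):
        raise ValueError("carbon concentration cannot be negative")
    out = 0.126 + 1.25 * c
    return out.item() if np.isscalar(c_wb) else out


def ph_cacl2_to_water(ph):
    """Convert pH measured in 0.01 M CaCl2 to water pH.

    ``ph_water = 0.27 + 1.03 * ph_cacl2``; valid for pH in [2, 10].
    """
    p = np.asarray(ph, dtype=float)
    if np.any((p < 2) | (p > 10)):
        raise ValueError("pH outside the plausible range [2, 10]")
    out = 0.27 + 1.03 * p
    return out.item() if np.isscalar(ph) else out


def bray2_to_mehlich3(p_bray2, floor: float = MEHLICH3_P_FLOOR, return_flag: bool = False):
    """Convert Bray-2 extractable P to Mehlich-3 P (mg/kg).

    ``m3 = -34.6 + 0.86 * bray2``, floored at ``floor``.  With
    ``return_flag=True`` also returns a boolean mask of inputs whose raw
    conversion fell below the floor.
    """
    p = np.asarray(p_bray2, dtype=float)
    if np.any(p < 0):
        raise ValueError("Bray-2 P cannot be negative")
    raw = -34.6 + 0.86 * p
    flagged = raw < floor
    out = np.maximum(raw, floor)
    if np.isscalar(p_bray2):
        out = out.item()
        flagged = bool(flagged)
    return (out, flagged) if return_flag else out


def specific_gravity(weight_air, weight_water):
    """Tuber specific gravity from weight-in-air / weight-in-water.

    ``sg = w_air / (w_air - w_water)``; requires ``w_air > w_water >= 0``.
    """
    wa = np.asarray(weight_air, dtype=float)
    ww = np.asarray(weight_water, dtype=float)
    if np.any(ww < 0) or np.any(wa <= ww):
        raise ValueError("require weight_air > weight_water >= 0")
    out = wa / (wa - ww)
    return out.item() if np.isscalar(weight_air) and np.isscalar(weight_water) else out


def elemental_to_oxide(dose_p, dose_k):
    """Convert elemental P and K doses (kg/ha) to P2O5 and K2O doses."""
    p = np.asarray(dose_p, dtype=float)
    k = np.asarray(dose_k, dtype=float)
    if np.any(p < 0) or np.any(k < 0):
        raise ValueError("doses cannot be negative")
    p2o5 = p * P2O5_PER_P
    k2o = k * K2O_PER_K
    if np.isscalar(dose_p) and np.isscalar(dose_k):
        return p2o5.item(), k2o.item()
    return p2o5, k2o


def phosphorus_saturation_index(p_m3, al_m3, decimals: int = 1):
    """Phosphorus saturation environmental risk index, percent.

    ``100 * P_Mehlich3 / Al_Mehlich3`` rounded to ``decimals`` places.
    """
    p = np.asarray(p_m3, dtype=float)
    al = np.asarray(al_m3, dtype=float)
    if np.any(al <= 0):
        raise ValueError("Mehlich-3 Al must be strictly positive")
    if np.any(p < 0):
        raise ValueError("Mehlich-3 P cannot be negative")
    out = np.round(100.0 * p / al, decimals)
    return out.item() if np.isscalar(p_m3) and np.isscalar(al_m3) else out
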