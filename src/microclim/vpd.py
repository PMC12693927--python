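"""Psychrometric quantities: saturation vapor pressure, actual vapor
pressure and vapor pressure deficit (VPD).

VPD is the drying power of the air that the crop canopy experiences:
the gap, in kPa, between the water vapor the air could hold at its
current temperature (SVP) and the vapor it actually holds (AVP).
SVP follows a Tetens-type exponential in air temperature; AVP scales
SVP by relative humidity.

The default exponential base is the literal constant 2.7183 rather than
``math.e``; the difference is below one part in 10^4 over the
agronomically relevant range (0–50 °C) and a keyword switches to the
exact natural base.
"""

from __future__ import annotations

import numpy as np

__all__ = ["svp", "avp", "vpd", "add_vpd", "PRINTED_E"]

#: Exponential base as conventionally typeset in agronomy formulas.
PRINTED_E = 2.7183

# Tetens coefficients (kPa, dimensionless, °C).
_A = 0.6108
_B = 17.27
_C = 237.3


def svp(t_c, base: float = PRINTED_E):
    """Saturation vapor pressure in kPa at air temperature ``t_c`` (°C).

    SVP = 0.6108 * base^(17.27*T / (T + 237.3)).  Accepts scalars or
    arrays.  The formula's denominator changes sign at -237.3 °C;
    temperatures at or below that are a domain error.

    Parameters
    ----------
    t_c : float or array-like
        Air temperature in °C, each value > -237.3.
    base : float
        Base of the exponential; the printed constant 2.7183 by default,
        pass ``math.e`` for the exact natural base.
    """
    t = np.asarray(t_c, dtype=float)
    if base <= 0:
        raise ValueError("exponential base must be positive")
    finite = np.isfinite(t)
    if np.any(t[finite] <= -_C):
        raise ValueError(f"temperature must exceed {-_C} degC")
    out = _A * np.power(base, (_B * t) / (t + _C))
    return float(out) if np.isscalar(t_c) else out


def avp(t_c, rh_pct, base: float = PRINTED_E, strict: bool = True):
    """Actual vapor pressure in kPa: AVP = SVP * RH/100."""
    rh = np.asarray(rh_pct, dtype=float)
    rh = _check_rh(rh, strict)
    out = svp(t_c, base=base) * rh / 100.0
    return float(out) if np.isscalar(t_c) and np.isscalar(rh_pct) else out


def vpd(t_c, rh_pct, base: float = PRINTED_E, strict: bool = True):
    """Vapor pressure deficit in kPa: VPD = SVP - AVP = SVP * (1 - RH/100).

    Nonnegative whenever RH <= 100.  With ``strict`` (default) RH outside
    [0, 100] raises; otherwise RH is clamped into range first.
    """
    rh = np.asarray(rh_pct, dtype=float)
    rh = _check_rh(rh, strict)
    out = svp(t_c, base=base) * (1.0 - rh / 100.0)
    return float(out) if np.isscalar(t_c) and np.isscalar(rh_pct) else out


def _check_rh(rh: np.ndarray, strict: bool) -> np.ndarray:
    finite = np.isfinite(rh)
    bad = finite & ((rh < 0.0) | (rh > 100.0))
    if np.any(bad):
        if strict:
            raise ValueError(
                f"relative humidity outside [0, 100]: "
                f"{np.asarray(rh)[bad].ravel()[:5]}"
            )
        rh = np.clip(rh, 0.0, 100.0)
    return rh


def add_vpd(frame, t_col: str = "temp_c", rh_col: str = "rh_pct",
            out_col: str = "vpd_kpa", base: float = PRINTED_E):
    """Return a copy of a sensor DataFrame with a VPD column appended.

    Missing T or RH propagates to a missing VPD.
    """
    out = frame.copy()
    t = out[t_col].to_numpy(dtype=float)
    rh = out[rh_col].to_numpy(dtype=float)
    ok = np.isfinite(t) & np.isfinite(rh)
    v = np.full(len(out), np.nan)
    if ok.any():
        v[ok] = vpd(t[ok], rh[ok], base=base)
    out[out_col] = v
    return out
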