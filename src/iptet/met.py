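"""Meteorological physics for the greenhouse energy balance.

Saturation vapor pressure, vapor pressure deficit, the slope of the
saturation curve (Δ) and the psychrometric constant (γ) follow the
FAO-56 conventions used throughout the Priestley-Taylor literature.
All temperature-dependent quantities accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetDerived",
    "saturation_vapor_pressure",
    "vpd_from_t_rh",
    "delta_slope",
    "psychrometric_constant",
]

#: Valid air-temperature domain (°C) for the Magnus-type formulas below.
TA_MIN = -40.0
TA_MAX = 60.0


@dataclass(frozen=True)
class MetDerived:
    """Derived psychrometric quantities for one air temperature.

    Attributes
    ----------
    es : float
        Saturation vapor pressure, kPa.
    delta : float
        Slope of the saturation vapor pressure curve Δ, kPa K⁻¹.
    gamma : float
        Psychrometric constant γ, kPa K⁻¹ (site-level, from elevation).
    """

    es: float
    delta: float
    gamma: float


def _check_ta(Ta, label: str | None = None):
    Ta = np.asarray(Ta, dtype=float)
    bad = (Ta <= TA_MIN) | (Ta >= TA_MAX) | ~np.isfinite(Ta)
    if np.any(bad):
        where = f" at {label}" if label else ""
        offending = np.atleast_1d(Ta)[np.atleast_1d(bad)][:5]
        raise ValueError(
            f"air temperature outside ({TA_MIN}, {TA_MAX}) °C{where}: "
            f"{offending.tolist()}"
        )
    return Ta


def saturation_vapor_pressure(Ta, *, label: str | None = None):
    """Saturation vapor pressure e_s(Ta) in kPa (Tetens/Magnus form).

    e_s = 0.6108 · exp(17.27·Ta / (Ta + 237.3)) with Ta in °C.

    Parameters
    ----------
    Ta : float or array_like
        Air temperature, °C; must lie in (−40, 60).
    label : str, optional
        Identifier (e.g. a timestamp) included in the error message when
        Ta is out of range.
    """
    Ta = _check_ta(Ta, label)
    out = 0.6108 * np.exp(17.27 * Ta / (Ta + 237.3))
    return float(out) if out.ndim == 0 else out


def vpd_from_t_rh(Ta, RH, *, label: str | None = None):
    """Vapor pressure deficit (kPa) from air temperature and relative humidity.

    VPD = e_s(Ta)·(1 − RH/100), nonnegative by construction.
    """
    RH = np.asarray(RH, dtype=float)
    if np.any((RH < 0) | (RH > 100) | ~np.isfinite(RH)):
        where = f" at {label}" if label else ""
        raise ValueError(f"relative humidity outside [0, 100] %{where}")
    out = saturation_vapor_pressure(Ta, label=label) * (1.0 - RH / 100.0)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def delta_slope(Ta, *, label: str | None = None):
    """Slope Δ of the saturation vapor pressure curve, kPa K⁻¹.

    Δ = 4098·e_s(Ta) / (Ta + 237.3)²; strictly increasing in Ta over the
    valid domain.
    """
    Ta = _check_ta(Ta, label)
    es = 0.6108 * np.exp(17.27 * Ta / (Ta + 237.3))
    out = 4098.0 * es / (Ta + 237.3) ** 2
    return float(out) if out.ndim == 0 else out


def psychrometric_constant(elevation: float = 0.0) -> float:
    """Psychrometric constant γ (kPa K⁻¹) from site elevation (m).

    Atmospheric pressure follows the standard-atmosphere profile
    P = 101.3·((293 − 0.0065·z)/293)^5.26 and γ = 0.665×10⁻³·P.
    Computed once per site; pressure is assumed constant over a season.
    """
    if elevation < 0:
        raise ValueError("elevation must be nonnegative")
    pressure = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    return 0.665e-3 * pressure


def derive(Ta: float, elevation: float = 0.0) -> MetDerived:
    """Bundle e_s, Δ and γ for a single air temperature."""
    return MetDerived(
        es=saturation_vapor_pressure(Ta),
        delta=delta_slope(Ta),
        gamma=psychrometric_constant(elevation),
    )
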