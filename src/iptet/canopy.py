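"""Canopy structure: Beer–Lambert extinction, LAI interpolation, transmission.

The canopy intercepts net radiation following a Beer–Lambert decay with
extinction coefficient ``k``; the fraction τ = exp(−k·LAI) of net
radiation reaches the soil surface.  Weekly LAI observations are
interpolated to daily values with a shape-preserving piecewise cubic
Hermite polynomial (PCHIP), which passes exactly through the
observations and never overshoots between monotone knots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "CanopyParams",
    "extinction_coefficient",
    "fit_extinction_coefficient",
    "interpolate_lai",
    "transmission_fraction",
]


@dataclass(frozen=True)
class CanopyParams:
    """Season-constant canopy parameters.

    Attributes
    ----------
    k : float
        Beer–Lambert extinction coefficient (dimensionless), > 0.
    tau_c : float
        Critical transmission fraction τ_c at maximum canopy coverage.
    cdc : float
        Canopy decline coefficient (d⁻¹) driving leaf senescence.
    """

    k: float = 0.7
    tau_c: float = 0.55
    cdc: float = 0.08

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("extinction coefficient k must be > 0")
        if not 0 < self.tau_c < 1:
            raise ValueError("tau_c must lie in (0, 1)")
        if self.cdc < 0:
            raise ValueError("CDC must be nonnegative")


def extinction_coefficient(PARs, PARo, LAI) -> float:
    """Extinction coefficient from paired above/below-canopy PAR readings.

    k = −ln(PARs/PARo)/LAI where PARs and PARo are the photosynthetically
    active radiation (µmol m⁻² s⁻¹) at the ground and above the canopy.
    """
    PARs, PARo, LAI = float(PARs), float(PARo), float(LAI)
    if PARs <= 0 or PARo <= 0:
        raise ValueError("PAR readings must be positive")
    if PARs > PARo:
        raise ValueError(
            f"below-canopy PAR ({PARs}) exceeds above-canopy PAR ({PARo})"
        )
    if LAI <= 0:
        raise ValueError("LAI must be positive to fit an extinction coefficient")
    return -np.log(PARs / PARo) / LAI


def fit_extinction_coefficient(
    triples: Sequence[tuple[float, float, float]],
) -> float:
    """Season-level k as the median of per-measurement fits.

    Each triple is (PARs, PARo, LAI) from one weekly calibration run.
    The median is robust to the occasional sensor glitch and is
    deterministic for a fixed input set.
    """
    ks = []
    for PARs, PARo, LAI in triples:
        try:
            ks.append(extinction_coefficient(PARs, PARo, LAI))
        except ValueError:
            continue
    if not ks:
        raise ValueError("no valid (PARs, PARo, LAI) triples to fit k from")
    return float(np.median(ks))


def interpolate_lai(obs_dates, obs_values, target_dates) -> pd.Series:
    """Daily LAI (or height) series by monotone PCHIP interpolation.

    Parameters
    ----------
    obs_dates, obs_values
        Weekly observations; dates must be strictly increasing, at least
        two observations required.
    target_dates
        Dates to evaluate at; must lie within [first, last] observation
        (no extrapolation).

    Returns
    -------
    pandas.Series indexed by the target dates.
    """
    obs_dates = pd.DatetimeIndex(obs_dates)
    target_dates = pd.DatetimeIndex(target_dates)
    obs_values = np.asarray(obs_values, dtype=float)
    if len(obs_dates) < 2:
        raise ValueError("need at least two LAI observations to interpolate")
    x = obs_dates.asi8 / 86_400e9  # days since epoch
    if np.any(np.diff(x) <= 0):
        raise ValueError("observation dates must be strictly increasing")
    xt = target_dates.asi8 / 86_400e9
    if xt.min() < x[0] or xt.max() > x[-1]:
        raise ValueError(
            "target dates outside the observation range "
            f"[{obs_dates[0].date()}, {obs_dates[-1].date()}]; "
            "extrapolation is not supported"
        )
    interp = PchipInterpolator(x, obs_values)
    return pd.Series(interp(xt), index=target_dates, name="LAI")


def transmission_fraction(k, LAI):
    """Fraction τ ∈ (0, 1] of net radiation transmitted to the soil.

    τ = exp(−k·LAI): unity for bare soil, decaying toward zero as the
    canopy closes.
    """
    k = np.asarray(k, dtype=float)
    LAI = np.asarray(LAI, dtype=float)
    if np.any(k < 0) or np.any(LAI < 0):
        raise ValueError("k and LAI must be nonnegative")
    out = np.exp(-k * LAI)
    return float(out) if out.ndim == 0 else out
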