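"""Core improved Priestley-Taylor (IPT) evapotranspiration model.

The classical Priestley-Taylor model scales equilibrium evaporation by a
constant α = 1.26:

    λET = α · Δ/(Δ+γ) · (Rn − G)

The improved model partitions net radiation between soil and canopy with
the Beer–Lambert transmission fraction τ = exp(−k·LAI), applies the soil
water-stress, temperature and senescence constraints to the respective
energy-limited coefficients, and recombines them into a bulk dynamic
coefficient

    α_e = [f_sw·α_s0·(1−f_G)·τ + (1−f_s)·f_t·α_c0·(1−τ)] / (1 − f_G·τ)

where G = f_G·R_ns closes the soil heat flux.  With all constraints
inactive and f_G = 0, α_e collapses to α_0 = 1.26 for any LAI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import canopy as _canopy
from . import constraints as _constraints
from . import met as _met

__all__ = [
    "ModelParams",
    "SiteParams",
    "partition_radiation",
    "soil_heat_flux",
    "equilibrium_evaporation",
    "improved_pt_coefficient",
    "simulate_et",
    "aggregate_daily",
]

#: Density of water, kg m⁻³ (1 mm of water ≡ 1 kg m⁻² over 1 m²).
RHO_WATER = 1000.0


@dataclass(frozen=True)
class ModelParams:
    """Tunable IPT model parameters.

    Attributes
    ----------
    alpha_0 : float
        Recommended bulk Priestley-Taylor coefficient (1.26).
    k : float
        Canopy extinction coefficient.
    tau_c : float
        Critical transmission fraction at maximum canopy coverage.
    cdc : float
        Canopy decline coefficient, d⁻¹.
    t_opt : float
        Optimum air temperature for the crop, °C (26 for tomato).
    f_g : float
        Fraction of soil heat flux to soil-received radiation (0.45).
    lambda_v : float
        Latent heat of vaporization, J kg⁻¹.
    clip_negative_et : bool
        Clip negative (nighttime condensation) fluxes to zero.
    senescence_literal : bool
        Use the alternative literal senescence form (sensitivity only).
    """

    alpha_0: float = 1.26
    k: float = 0.7
    tau_c: float = 0.55
    cdc: float = 0.08
    t_opt: float = 26.0
    f_g: float = 0.45
    lambda_v: float = 2.45e6
    clip_negative_et: bool = True
    senescence_literal: bool = False

    def __post_init__(self):
        if self.alpha_0 <= 1:
            raise ValueError("alpha_0 must exceed 1")
        if not 0 <= self.f_g < 1:
            raise ValueError("f_g must lie in [0, 1)")
        if self.lambda_v <= 0:
            raise ValueError("lambda_v must be positive")


@dataclass(frozen=True)
class SiteParams:
    """Site constants: elevation and topsoil water retention bounds."""

    elevation: float = 78.0
    theta_s: float = 0.32
    theta_w: float = 0.09


def partition_radiation(Rn, tau):
    """Split net radiation between soil (R_ns = τ·Rn) and canopy (R_nc).

    The two parts sum to Rn exactly.
    """
    Rn = np.asarray(Rn, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any((tau <= 0) | (tau > 1)):
        raise ValueError("tau must lie in (0, 1]")
    Rns = tau * Rn
    Rnc = Rn - Rns
    if Rns.ndim == 0:
        return float(Rns), float(Rnc)
    return Rns, Rnc


def soil_heat_flux(Rns, f_g=0.45):
    """Modelled soil heat flux G = f_G·R_ns (negative at night)."""
    if not 0 <= f_g < 1:
        raise ValueError("f_g must lie in [0, 1)")
    out = f_g * np.asarray(Rns, dtype=float)
    return float(out) if out.ndim == 0 else out


def equilibrium_evaporation(Rn, G, delta, gamma):
    """Equilibrium latent heat flux λET_eq = Δ/(Δ+γ)·(Rn − G), W m⁻²."""
    delta = np.asarray(delta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(delta <= 0) or np.any(gamma <= 0):
        raise ValueError("delta and gamma must be positive")
    out = delta / (delta + gamma) * (np.asarray(Rn, dtype=float) - np.asarray(G, dtype=float))
    return float(out) if out.ndim == 0 else out


def improved_pt_coefficient(f_sw, f_t, f_s, a_s0, a_c0, tau, f_g=0.45):
    """Bulk improved PT coefficient α_e (dimensionless).

    α_e = [f_sw·α_s0·(1−f_G)·τ + (1−f_s)·f_t·α_c0·(1−τ)] / (1 − f_G·τ),
    the closed form obtained by assembling the soil and canopy latent
    heat fluxes with G = f_G·R_ns and dividing by the equilibrium rate.
    Equals (λE + λT)/λET_eq to machine precision by construction.
    """
    tau = np.asarray(tau, dtype=float)
    denom = 1.0 - f_g * tau
    if np.any(denom <= 0):
        raise ValueError("f_g * tau must be below 1")
    num = (
        np.asarray(f_sw, dtype=float) * np.asarray(a_s0, dtype=float) * (1.0 - f_g) * tau
        + (1.0 - np.asarray(f_s, dtype=float))
        * np.asarray(f_t, dtype=float)
        * np.asarray(a_c0, dtype=float)
        * (1.0 - tau)
    )
    out = num / denom
    return float(out) if out.ndim == 0 else out


def _require_hourly(index: pd.DatetimeIndex) -> None:
    """Fail loudly on duplicate or non-hourly gaps in the input clock."""
    if index.has_duplicates:
        dups = index[index.duplicated()].unique()[:5]
        raise ValueError(f"duplicate timestamps: {list(dups)}")
    if len(index) > 1:
        deltas = np.diff(index.asi8)
        hour = 3_600_000_000_000
        bad = np.nonzero(deltas != hour)[0]
        if bad.size:
            gaps = [str(index[i + 1]) for i in bad[:5]]
            raise ValueError(
                f"non-hourly gaps in meteorological series before: {gaps}"
            )


def simulate_et(
    met: pd.DataFrame,
    crop: pd.DataFrame,
    soil: pd.DataFrame | None = None,
    params: ModelParams | None = None,
    site: SiteParams | None = None,
    senescence_onset=None,
) -> pd.DataFrame:
    """Simulate hourly evapotranspiration for a full season.

    Parameters
    ----------
    met : DataFrame
        Hourly meteorology indexed by timestamp with columns ``Rn``
        (W m⁻²), ``Ta`` (°C), ``VPD`` (kPa) or ``RH`` (%), ``u2``
        (m s⁻¹) and optionally measured ``G`` (W m⁻²).  A measured G
        column overrides the f_G·R_ns closure in the flux computation.
    crop : DataFrame
        Daily crop state indexed by date with column ``LAI`` and
        optionally ``senescence_days``; broadcast to hours.
    soil : DataFrame, optional
        Hourly topsoil moisture with column ``theta`` (or ``theta_05``
        and ``theta_10``, averaged).  When omitted the soil is treated
        as unstressed (f_sw = 1).
    senescence_onset : date-like, optional
        Calendar date at which the senescence clock starts when the
        crop table carries no ``senescence_days`` column.

    Returns
    -------
    DataFrame indexed like ``met`` with the latent heat fluxes
    (``lambda_ET`` = ``lambda_E`` + ``lambda_T``, W m⁻²), the hourly
    depth ``ET`` (mm), the bulk coefficient ``alpha_e`` and all
    intermediate terms.
    """
    params = params or ModelParams()
    site = site or SiteParams()
    if not isinstance(met.index, pd.DatetimeIndex):
        raise TypeError("met must be indexed by timestamp")
    _require_hourly(met.index)

    if "Rn" not in met.columns or "Ta" not in met.columns:
        missing = {"Rn", "Ta"} - set(met.columns)
        raise ValueError(f"missing required meteorological columns: {sorted(missing)}")

    dates = met.index.normalize()
    crop_dates = pd.DatetimeIndex(crop.index).normalize()
    missing_days = dates.unique().difference(crop_dates)
    if len(missing_days):
        raise ValueError(
            "crop series does not cover meteorological days: "
            f"{[str(d.date()) for d in missing_days[:5]]}"
        )
    lai_daily = pd.Series(np.asarray(crop["LAI"], dtype=float), index=crop_dates)
    lai = lai_daily.reindex(dates).to_numpy()

    if "senescence_days" in crop.columns:
        sen_daily = pd.Series(
            np.asarray(crop["senescence_days"], dtype=float), index=crop_dates
        )
        sen_days = sen_daily.reindex(dates).to_numpy()
    elif senescence_onset is not None:
        onset = pd.Timestamp(senescence_onset).normalize()
        sen_days = np.maximum((dates - onset).days.to_numpy(), 0).astype(float)
    else:
        sen_days = np.zeros(len(met))

    Ta = met["Ta"].to_numpy(dtype=float)
    Rn = met["Rn"].to_numpy(dtype=float)

    delta = _met.delta_slope(Ta, label="met series")
    gamma = _met.psychrometric_constant(site.elevation)

    tau = _canopy.transmission_fraction(params.k, lai)
    Rns, Rnc = partition_radiation(Rn, tau)

    G_model = soil_heat_flux(Rns, params.f_g)
    if "G" in met.columns and met["G"].notna().all():
        G = met["G"].to_numpy(dtype=float)
    else:
        G = G_model

    if soil is not None:
        if "theta" in soil.columns:
            theta = soil["theta"]
        elif {"theta_05", "theta_10"}.issubset(soil.columns):
            theta = (soil["theta_05"] + soil["theta_10"]) / 2.0
        else:
            raise ValueError("soil table needs a theta (or theta_05/theta_10) column")
        theta = theta.reindex(met.index)
        if theta.isna().any():
            gaps = theta.index[theta.isna()][:5]
            raise ValueError(f"soil series misses timestamps: {[str(t) for t in gaps]}")
        se = _constraints.effective_saturation(
            theta.to_numpy(dtype=float), site.theta_s, site.theta_w
        )
        f_sw = _constraints.water_stress_coefficient(se)
    else:
        f_sw = np.ones(len(met))

    f_t = _constraints.temperature_constraint(Ta, params.t_opt)
    f_s = _constraints.senescence_index(
        sen_days, params.cdc, literal=params.senescence_literal
    )
    a_s0 = _constraints.alpha_s0(tau, params.tau_c, params.alpha_0)
    a_c0 = _constraints.alpha_c0(params.alpha_0, a_s0, tau)

    fac = delta / (delta + gamma)
    lam_E = f_sw * a_s0 * fac * (Rns - G)
    lam_T = (1.0 - f_s) * f_t * a_c0 * fac * Rnc
    if params.clip_negative_et:
        lam_E = np.maximum(lam_E, 0.0)
        lam_T = np.maximum(lam_T, 0.0)
    lam_ET = lam_E + lam_T

    alpha_e = improved_pt_coefficient(f_sw, f_t, f_s, a_s0, a_c0, tau, params.f_g)

    # mm per hour: λET [W m⁻²] × 3600 s / (λ_v [J kg⁻¹] · ρ_w [kg m⁻³]) × 1000 mm m⁻¹
    et_mm = lam_ET * 3600.0 / (params.lambda_v * RHO_WATER) * 1000.0

    return pd.DataFrame(
        {
            "lambda_ET": lam_ET,
            "lambda_E": lam_E,
            "lambda_T": lam_T,
            "ET": et_mm,
            "alpha_e": alpha_e,
            "Rns": Rns,
            "Rnc": Rnc,
            "G": G,
            "tau": tau,
            "LAI": lai,
            "f_sw": f_sw,
            "f_t": f_t,
            "f_s": f_s,
            "alpha_s0": a_s0,
            "alpha_c0": a_c0,
            "delta": delta,
            "lambda_ETeq": equilibrium_evaporation(Rn, G, delta, gamma),
        },
        index=met.index,
    )


def aggregate_daily(
    hourly: pd.DataFrame | pd.Series,
    max_missing_fraction: float = 0.0,
) -> pd.DataFrame:
    """Aggregate hourly ET depth (mm h⁻¹) to daily totals (mm d⁻¹).

    Days missing more than ``max_missing_fraction`` of their 24 hours
    are flagged (``complete = False``) but still summed over the hours
    present.
    """
    if isinstance(hourly, pd.DataFrame):
        if "ET" not in hourly.columns:
            raise ValueError("hourly table has no ET column")
        et = hourly["ET"]
    else:
        et = hourly
    if len(et) == 0:
        raise ValueError("empty hourly series")
    by_day = et.groupby(et.index.normalize())
    daily = by_day.sum().rename("ET")
    hours = by_day.count()
    complete = (24 - hours) <= max_missing_fraction * 24
    return pd.DataFrame({"ET": daily, "hours": hours, "complete": complete})
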