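"""Environmental constraint coefficients and partitioned PT coefficients.

Three multiplicative constraints modulate the energy-limited
Priestley-Taylor coefficients:

* ``f_sw`` — soil evaporative water stress, driven by topsoil effective
  saturation S_e (evaporation is unconstrained once S_e ≥ 0.75);
* ``f_t``  — a Gaussian penalty on air temperature away from the crop
  optimum T_opt;
* ``f_s``  — leaf senescence, growing from 0 at senescence onset toward 1
  at a rate set by the canopy decline coefficient CDC.

The energy-limited coefficients α_s0 (soil) and α_c0 (canopy) partition
the bulk coefficient α_0 so that α_s0·τ + α_c0·(1−τ) = α_0 exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SoilState",
    "ConstraintSet",
    "effective_saturation",
    "water_stress_coefficient",
    "temperature_constraint",
    "senescence_index",
    "alpha_s0",
    "alpha_c0",
]

#: Effective saturation above which soil evaporation is unconstrained.
SE_UNSTRESSED = 0.75


@dataclass(frozen=True)
class SoilState:
    """Topsoil (0–0.1 m) water status.

    theta is clipped to [theta_w, theta_s] before computing the
    effective saturation Se.
    """

    theta: float
    theta_s: float = 0.32
    theta_w: float = 0.09

    @property
    def se(self) -> float:
        return effective_saturation(self.theta, self.theta_s, self.theta_w)


@dataclass(frozen=True)
class ConstraintSet:
    """All constraint and PT coefficients for one time step."""

    f_s: float
    f_t: float
    f_sw: float
    alpha_s0: float
    alpha_c0: float
    alpha_e: float


def effective_saturation(theta, theta_s=0.32, theta_w=0.09):
    """Effective saturation S_e = (θ − θ_w)/(θ_s − θ_w), clipped to [0, 1].

    θ is the measured volumetric water content of the top 0.1 m
    (cm³ cm⁻³); θ_s and θ_w are the saturated and wilting contents.
    """
    if theta_w >= theta_s:
        raise ValueError(
            f"wilting content ({theta_w}) must be below saturated content ({theta_s})"
        )
    theta = np.clip(np.asarray(theta, dtype=float), theta_w, theta_s)
    out = (theta - theta_w) / (theta_s - theta_w)
    return float(out) if out.ndim == 0 else out


def water_stress_coefficient(Se):
    """Soil evaporative water stress f_sw: 1 when S_e ≥ 0.75, else S_e."""
    Se = np.asarray(Se, dtype=float)
    out = np.where(Se >= SE_UNSTRESSED, 1.0, Se)
    return float(out) if out.ndim == 0 else out


def temperature_constraint(Ta, T_opt=26.0):
    """Temperature constraint f_t = exp(−(Ta/T_opt − 1)²) ∈ (0, 1].

    Equals 1 exactly at the crop optimum and decays symmetrically in the
    relative deviation Ta/T_opt.
    """
    if T_opt <= 0:
        raise ValueError("T_opt must be positive")
    Ta = np.asarray(Ta, dtype=float)
    out = np.exp(-((Ta / T_opt - 1.0) ** 2))
    return float(out) if out.ndim == 0 else out


def senescence_index(t, cdc=0.08, *, literal=False):
    """Leaf senescence index f_s ∈ [0, 1] after t days of canopy decline.

    Default form: f_s = 0.05·(exp((CDC/0.98)·t) − 1), clipped to [0, 1],
    so the index starts at exactly 0 at senescence onset — the canopy-
    decline family used by AquaCrop-style models.  ``literal=True``
    selects the alternative reading 0.05·exp(CDC·0.98·t − 1) (nonzero at
    onset), kept for sensitivity checks only.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("days since senescence onset must be nonnegative")
    if literal:
        out = 0.05 * np.exp(cdc * 0.98 * t - 1.0)
    else:
        out = 0.05 * (np.exp((cdc / 0.98) * t) - 1.0)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def alpha_s0(tau, tau_c=0.55, alpha_0=1.26):
    """Energy-limited soil PT coefficient α_s0 ∈ [1, α_0].

    Unity under a closed canopy (τ ≤ τ_c); relaxes linearly toward α_0
    as the canopy opens:

        α_s0 = α_0 − (α_0 − 1)·(1 − τ)/(1 − τ_c)   for τ > τ_c.

    Continuous at τ = τ_c.
    """
    if not 0 < tau_c < 1:
        raise ValueError("tau_c must lie in (0, 1)")
    tau = np.asarray(tau, dtype=float)
    open_canopy = alpha_0 - (alpha_0 - 1.0) * (1.0 - tau) / (1.0 - tau_c)
    out = np.where(tau <= tau_c, 1.0, open_canopy)
    return float(out) if out.ndim == 0 else out


def alpha_c0(alpha_0, a_s0, tau):
    """Energy-limited canopy PT coefficient α_c0 = (α_0 − α_s0·τ)/(1 − τ).

    Defined so the energy-weighted identity α_s0·τ + α_c0·(1−τ) = α_0
    holds exactly.  At τ = 1 (bare soil) the canopy term carries zero
    energy; the limit α_0 is returned with a warning.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau > 1) or np.any(tau < 0):
        raise ValueError("tau must lie in [0, 1]")
    bare = tau >= 1.0
    if np.any(bare):
        warnings.warn(
            "alpha_c0 at tau=1 (bare soil) is indeterminate; returning alpha_0 "
            "(the canopy term carries zero energy)",
            RuntimeWarning,
            stacklevel=2,
        )
    a_s0 = np.asarray(a_s0, dtype=float)
    denom = np.where(bare, 1.0, 1.0 - tau)
    out = np.where(bare, alpha_0, (alpha_0 - a_s0 * tau) / denom)
    return float(out) if out.ndim == 0 else out
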