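# Methods

## Model

The improved Priestley-Taylor (IPT) model treats evapotranspiration as
radiation-limited: λET = α_e·Δ/(Δ+γ)·(Rn−G), with the bulk coefficient
α_e assembled from a soil and a canopy branch rather than fixed at the
classical 1.26. The assumptions inherited from that family are worth
stating plainly:

* advection and aerodynamic transport are negligible — defensible in a
  semi-closed greenhouse where wind speeds stay below ~0.5 m s⁻¹, and
  the reason wind speed appears only in the driver analysis, never in
  the flux equations;
* net radiation partitions between soil and canopy by Beer–Lambert
  decay, τ = exp(−k·LAI), with a single season-constant extinction
  coefficient k;
* soil heat flux is proportional to the radiation reaching the soil,
  G = f_G·R_ns; storage in plants, air and cover is ignored;
* stress enters multiplicatively: soil evaporation is scaled by f_sw,
  transpiration by (1−f_s)·f_t. No stomatal-conductance or root-zone
  water-balance model is attempted.

The energy-limited coefficients α_s0 and α_c0 partition α_0 so that
α_s0·τ + α_c0·(1−τ) = α_0 identically; the implementation enforces
this algebra rather than transcribing a printed formula, and the test
suite checks the closed-form α_e against the flux-by-flux assembly at
1e−10 relative over 1000 random parameter draws. With f_sw = f_t = 1,
f_s = 0 and f_G = 0 the model reduces exactly to classical
Priestley-Taylor at any LAI.

## Parameters

| parameter | default | units | meaning / why this value |
|---|---|---|---|
| α_0 | 1.26 | – | classical PT coefficient, the unconstrained limit |
| k | 0.7 | – | Beer–Lambert extinction; typical of greenhouse tomato canopies, and yields α_e ≈ 1.26 at LAI ≈ 2.5 with temperatures near the optimum, consistent with the model family's behaviour |
| τ_c | 0.55 | – | critical transmission at maximum canopy coverage |
| CDC | 0.08 | d⁻¹ | canopy decline coefficient for greenhouse tomato |
| T_opt | 26 | °C | optimum air temperature for tomato |
| f_G | 0.45 | – | soil heat flux fraction of soil-received radiation |
| λ_v | 2.45×10⁶ | J kg⁻¹ | latent heat of vaporization (FAO-56 convention) for the W m⁻² → mm conversion |
| θ_s, θ_w | 0.32, 0.09 | cm³ cm⁻³ | saturated and wilting topsoil (0–0.1 m) water content of the reference silt loam |
| elevation | 78 | m | reference site altitude, fixes γ ≈ 0.0668 kPa K⁻¹ once per season |

Every default is overridable in the YAML run configuration.

## Interpretation choices

Several published forms of this model family are typographically
ambiguous; the package adopts one reading each and documents it:

* **Senescence index.** f_s = 0.05·(exp((CDC/0.98)·t) − 1), clipped to
  [0, 1]. This is the AquaCrop-style canopy-decline family, starts at
  exactly 0 at senescence onset and grows monotonically. The
  alternative literal reading 0.05·exp(CDC·0.98·t − 1), which is
  nonzero at onset, is available via `senescence_index(..., literal=True)`
  for sensitivity work only. Senescence onset is a configured calendar
  date, defaulting to the first day of the late growth stage.
* **Transmission.** τ = exp(−k·LAI) with no leading scalar; any other
  scaling would push τ out of (0, 1] and break the α_s0/α_c0 partition.
* **MAE.** The standard pairwise mean |O_i − P_i|. The scatter measure
  mean |O_i − P̄| sometimes printed under the MAE label is exposed as
  `mae_literal` and not used anywhere.
* **Δ and γ.** FAO-56 closed forms (Tetens saturation curve,
  standard-atmosphere pressure); evaluated hourly from hourly Ta, with
  daily ET obtained by summing hourly depths, never by a daily-mean
  recomputation.
* **Path analysis.** Direct paths are standardized OLS coefficients
  solved from the normal equations R_xx·P = r_xy; sample statistics use
  n−1 denominators; the ventilation window 9:00–16:00 is inclusive on
  both ends (8 hourly rows per day). The identity
  r_i = P_i + Σ_{j≠i} r_ij·P_j holds to numerical precision for any
  dataset by this construction; when checking externally published
  tables the per-driver residual is reported rather than forced to
  zero (published wind-speed rows violate it; the radiation and
  temperature rows satisfy it).

## Numerical choices

* θ is clipped to [θ_w, θ_s] before computing effective saturation, so
  S_e ∈ [0, 1] by construction.
* α_c0 at τ = 1 (bare soil) is the 0/0 limit of its defining ratio;
  the package returns α_0 with a RuntimeWarning — the canopy term
  carries zero energy there, so the value never reaches a flux.
* Negative nighttime fluxes (Rn − G < 0) are clipped to zero per
  component (λE and λT separately), preserving λET = λE + λT; weighing
  lysimeters do not register condensation as negative ET. Configurable
  via `clip_negative_et`.
* The Willmott index of agreement is clamped to its mathematical
  range [0, 1] against last-ulp rounding spill.
* Daily LAI interpolation uses monotone PCHIP
  (`scipy.interpolate.PchipInterpolator`); extrapolation outside the
  observation span is refused. The test oracle is an independent
  Fritsch–Carlson implementation.
* Measured G, when a column is present, overrides the f_G·R_ns closure
  in the flux computation; the closed-form α_e reported alongside is
  defined with the closure (it is a diagnostic of the constraint
  state, not a ratio of realized fluxes, whenever measured G is used).

## Synthetic data

The generator emulates a drip-irrigated greenhouse tomato season:

* **Microclimate.** Net radiation is a half-sinusoid between 6:00 and
  18:00 peaking at 13:30, with lognormal day-to-day amplitude factors
  (CV 0.15) and small negative nighttime values; each growth stage's
  6:00–18:00 mean is rescaled onto the stage target. Air temperature
  and VPD follow net radiation with a 1 h lag plus AR(1) noise
  (ρ = 0.8) and are re-centred on whole-day stage-mean targets; wind
  speed is a low positive daytime-weighted signal with daily means
  near 0.1 m s⁻¹. The 2019-like and 2020-like presets carry the
  respective stage calendars and stage-mean targets.
* **Crop.** LAI and height knots trace the parabola-like trajectory —
  below 0.8 through the initial stage, peak (3.46 cm² cm⁻², 145 cm)
  midway through the middle stage, strict decline through the late
  stage — interpolated daily with the same PCHIP routine the model
  uses.
* **Soil.** Exponential drydown of topsoil moisture (3% of the
  plant-available span per day) with instantaneous irrigation recovery
  to 0.95·θ_s. No irrigation occurs during the initial stage after
  transplanting, producing the early-season water deficit
  (S_e < 0.75, f_sw < 1); from the development stage onward an
  irrigation triggers at S_e = 0.78, so f_sw stays at 1.
* **Observed ET.** Model output times (1 + ε), ε ~ N(0, CV) with
  CV = 0.05, truncated at zero — a stand-in for weighing-lysimeter
  measurements.

All randomness flows from explicit seeds; identical seeds give
byte-identical frames. What the generator does **not** contain:
weather fronts, vent-control feedback, humidity saturation at night,
spatially uneven drip wetting, or any plant feedback from water status
to LAI. Passing tests therefore demonstrate internal consistency of
the model and pipeline under realistic magnitudes and diurnal shapes,
not predictive skill on real greenhouse data — reproducing a measured
season's totals is explicitly out of scope.

## Problem sizes

The default season is 124 days × 24 h = 2976 hourly steps; a full
simulation takes milliseconds, so the acceptance pipeline (including a
19-point grid refit of f_G over the whole season and 1000 random α_e
oracle draws) completes in about a second.

## Known limitations

* k is a single season constant; no row structure, clumping or leaf
  angle distribution.
* γ is fixed per site; barometric variability over a season is
  ignored.
* The f_G closure ties soil heat flux to instantaneous radiation with
  no phase lag, which real soils show.
* Path analysis reports no significance tests on path coefficients,
  and the decomposition is only meaningful when drivers are not
  strongly collinear (a singular correlation matrix raises).
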