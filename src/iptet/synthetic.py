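"""Seeded synthetic greenhouse data: microclimate, crop, soil, observed ET.

Emulates the conditions of a drip-irrigated greenhouse tomato season:

* net radiation as a half-sinusoid daytime curve (6:00–18:00) peaking in
  early afternoon, scaled so each growth stage's 6:00–18:00 mean matches
  the stage target;
* air temperature and vapor pressure deficit following net radiation
  with a one-hour lag plus AR(1) noise, re-centred on stage-mean
  targets;
* low wind speed (daily means well below 0.5 m s⁻¹) as befits a
  semi-closed greenhouse;
* a parabola-like LAI/height trajectory rising from transplanting to a
  mid-season peak and declining with late-stage senescence;
* topsoil moisture with exponential drydown between irrigations — a
  water deficit during the initial stage, unstressed afterwards;
* lysimeter-like "observed" ET as the model output plus multiplicative
  noise, truncated at zero.

All randomness flows from an explicit seed; no global random state is
touched.  The same seed yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import canopy as _canopy
from . import met as _met

__all__ = [
    "ScenarioConfig",
    "scenario_2019",
    "scenario_2020",
    "generate_microclimate",
    "generate_crop",
    "generate_soil_moisture",
    "generate_observed_et",
]

STAGES = ("initial", "development", "middle", "late")
DAY_START, DAY_END = 6, 18  # hours defining the daytime radiation window


@dataclass(frozen=True)
class ScenarioConfig:
    """One growing season's worth of generator settings.

    Stage-mean targets are (initial, development, middle, late) tuples:
    the net-radiation targets are 6:00–18:00 means (W m⁻²); temperature
    (°C), VPD (kPa) and wind speed (m s⁻¹) targets are whole-day means.
    """

    name: str
    start: str
    end: str
    stage_starts: dict = field(default_factory=dict)
    rn_stage_means: tuple = (114.81, 125.65, 149.92, 148.44)
    ta_stage_means: tuple = (19.19, 21.26, 26.39, 28.23)
    vpd_stage_means: tuple = (1.031, 0.716, 1.419, 1.296)
    u2_stage_means: tuple = (0.118, 0.120, 0.102, 0.089)
    rn_peak_hour: float = 13.5
    lag_hours: int = 1
    night_rn: float = -5.0
    rn_day_cv: float = 0.15
    ta_amplitude: float = 5.0
    vpd_rel_amplitude: float = 0.9
    ar1_rho: float = 0.8
    ta_noise_sd: float = 0.5
    vpd_noise_sd: float = 0.05
    u2_noise_sd: float = 0.04
    lai_max: float = 3.46
    lai_transplant: float = 0.1
    height_max: float = 145.0
    theta_s: float = 0.32
    theta_w: float = 0.09
    irrigation_trigger_se: float = 0.78
    irrigation_recovery: float = 0.95
    drydown_per_day: float = 0.03
    et_noise_cv: float = 0.05

    def __post_init__(self):
        if any(m < 0 for m in self.rn_stage_means):
            raise ValueError("stage-mean net radiation targets must be nonnegative")
        for lvl in (self.rn_day_cv, self.ta_noise_sd, self.vpd_noise_sd,
                    self.u2_noise_sd, self.et_noise_cv):
            if lvl < 0:
                raise ValueError("noise levels must be nonnegative")
        if self.theta_w >= self.theta_s:
            raise ValueError("theta_w must be below theta_s")
        starts = [pd.Timestamp(self.stage_starts[s]) for s in STAGES]
        if starts != sorted(starts):
            raise ValueError("stage start dates must be ordered")
        if starts[0] != pd.Timestamp(self.start):
            raise ValueError("initial stage must begin at season start")

    @property
    def hourly_index(self) -> pd.DatetimeIndex:
        return pd.date_range(
            pd.Timestamp(self.start),
            pd.Timestamp(self.end) + pd.Timedelta(hours=23),
            freq="h",
        )

    @property
    def daily_index(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")

    def stage_of(self, dates) -> np.ndarray:
        """Stage label for each date (array of str)."""
        dates = pd.DatetimeIndex(dates).normalize()
        bounds = [pd.Timestamp(self.stage_starts[s]) for s in STAGES]
        idx = np.searchsorted(pd.DatetimeIndex(bounds).asi8, dates.asi8, side="right") - 1
        idx = np.clip(idx, 0, len(STAGES) - 1)
        return np.array(STAGES, dtype=object)[idx]

    @property
    def senescence_onset(self) -> pd.Timestamp:
        """Default senescence clock zero: first day of the late stage."""
        return pd.Timestamp(self.stage_starts["late"])


def scenario_2019() -> ScenarioConfig:
    """Preset mirroring the 2019-like season (stage means and calendar)."""
    return ScenarioConfig(
        name="season-2019",
        start="2019-03-12",
        end="2019-07-13",
        stage_starts={
            "initial": "2019-03-12",
            "development": "2019-04-03",
            "middle": "2019-05-12",
            "late": "2019-06-21",
        },
    )


def scenario_2020() -> ScenarioConfig:
    """Preset mirroring the 2020-like season."""
    return ScenarioConfig(
        name="season-2020",
        start="2020-03-04",
        end="2020-07-07",
        stage_starts={
            "initial": "2020-03-04",
            "development": "2020-03-26",
            "middle": "2020-05-06",
            "late": "2020-06-17",
        },
        rn_stage_means=(103.32, 131.53, 142.53, 154.09),
        ta_stage_means=(18.88, 20.82, 25.48, 27.03),
        vpd_stage_means=(0.791, 0.700, 1.172, 0.710),
        u2_stage_means=(0.114, 0.112, 0.145, 0.138),
    )


def _diurnal_shape(hours: np.ndarray, peak: float) -> np.ndarray:
    """Unit-amplitude daytime curve: 0 outside 6:00–18:00, 1 at the peak."""
    shape = np.zeros_like(hours, dtype=float)
    rising = (hours >= DAY_START) & (hours <= peak)
    falling = (hours > peak) & (hours <= DAY_END)
    shape[rising] = np.sin(np.pi / 2 * (hours[rising] - DAY_START) / (peak - DAY_START))
    shape[falling] = np.cos(np.pi / 2 * (hours[falling] - peak) / (DAY_END - peak))
    return shape


def _ar1(n: int, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    innovations = rng.normal(0.0, sd * np.sqrt(max(1.0 - rho**2, 1e-12)), n)
    out = np.empty(n)
    prev = 0.0
    for i in range(n):
        prev = rho * prev + innovations[i]
        out[i] = prev
    return out


def generate_microclimate(config: ScenarioConfig, seed: int) -> pd.DataFrame:
    """Hourly greenhouse meteorology (Rn, Ta, VPD, RH, u2) for one season."""
    rng = np.random.default_rng(seed)
    index = config.hourly_index
    hours = index.hour.to_numpy(dtype=float)
    dates = index.normalize()
    stage = config.stage_of(dates)

    shape = _diurnal_shape(hours, config.rn_peak_hour)
    # day-to-day amplitude variability (cloud/vent conditions)
    day_codes = pd.factorize(dates)[0]
    n_days = day_codes.max() + 1
    day_factor = rng.lognormal(mean=0.0, sigma=config.rn_day_cv, size=n_days)
    rn = shape * day_factor[day_codes]

    daytime = (hours >= DAY_START) & (hours <= DAY_END)
    for s, target in zip(STAGES, config.rn_stage_means):
        sel = (stage == s) & daytime
        mean_now = rn[sel].mean()
        if mean_now <= 0:
            raise ValueError(f"degenerate radiation curve in stage {s}")
        rn[stage == s] *= target / mean_now
    rn[~daytime] = config.night_rn + rng.normal(0.0, 1.0, (~daytime).sum())

    lagged = np.roll(shape * day_factor[day_codes], config.lag_hours)
    lagged[: config.lag_hours] = 0.0
    lagged_centered = lagged - lagged.mean()
    lagged_unit = lagged_centered / max(np.abs(lagged_centered).max(), 1e-12)

    ta = config.ta_amplitude * lagged_unit + _ar1(
        len(index), config.ar1_rho, config.ta_noise_sd, rng
    )
    vpd = config.vpd_rel_amplitude * lagged_unit + _ar1(
        len(index), config.ar1_rho, config.vpd_noise_sd, rng
    )
    u2 = 0.8 * np.abs(shape) + np.abs(
        _ar1(len(index), config.ar1_rho, config.u2_noise_sd, rng)
    ) + 0.05

    for s, t_ta, t_vpd, t_u2 in zip(
        STAGES, config.ta_stage_means, config.vpd_stage_means, config.u2_stage_means
    ):
        sel = stage == s
        ta[sel] += t_ta - ta[sel].mean()
        vpd[sel] *= t_vpd  # relative amplitude scales with the stage mean
        vpd[sel] += t_vpd - vpd[sel].mean()
        u2[sel] *= t_u2 / u2[sel].mean()

    vpd = np.maximum(vpd, 0.01)
    es = _met.saturation_vapor_pressure(ta)
    rh = np.clip(100.0 * (1.0 - vpd / es), 5.0, 100.0)

    return pd.DataFrame(
        {"Rn": rn, "Ta": ta, "VPD": vpd, "RH": rh, "u2": u2, "stage": stage},
        index=index,
    )


def generate_crop(config: ScenarioConfig) -> pd.DataFrame:
    """Daily LAI, plant height and senescence-day counter.

    Knots trace the parabola-like trajectory of greenhouse tomato: LAI
    below 0.8 throughout the initial stage, a peak (default 3.46) midway
    through the middle stage, and a strict decline through the late
    stage; interpolated daily with monotone PCHIP.
    """
    start = pd.Timestamp(config.start)
    end = pd.Timestamp(config.end)
    dev = pd.Timestamp(config.stage_starts["development"])
    mid = pd.Timestamp(config.stage_starts["middle"])
    late = pd.Timestamp(config.stage_starts["late"])

    def midpoint(a, b):
        return a + (b - a) / 2

    peak_date = midpoint(mid, late).normalize()
    lai_knots = [
        (start, config.lai_transplant),
        (midpoint(start, dev).normalize(), 0.3),
        (dev, 0.7),
        (midpoint(dev, mid).normalize(), 1.8),
        (mid, 3.1),
        (peak_date, config.lai_max),
        (late, config.lai_max * 0.95),
        (midpoint(late, end).normalize(), config.lai_max * 0.85),
        (end, config.lai_max * 0.70),
    ]
    height_knots = [
        (start, 18.0),
        (midpoint(start, dev).normalize(), 32.0),
        (dev, 48.0),
        (midpoint(dev, mid).normalize(), 95.0),
        (mid, 135.0),
        (peak_date, config.height_max),
        (late, config.height_max),
        (end, config.height_max * 0.97),
    ]

    days = config.daily_index
    lai = _canopy.interpolate_lai(*zip(*lai_knots), days)
    height = _canopy.interpolate_lai(*zip(*height_knots), days).rename("height")

    onset = config.senescence_onset
    sen = np.maximum((days - onset).days, 0).astype(float)
    return pd.DataFrame(
        {"LAI": lai.to_numpy(), "height": height.to_numpy(), "senescence_days": sen},
        index=days,
    )


def generate_soil_moisture(config: ScenarioConfig, seed: int) -> pd.DataFrame:
    """Hourly topsoil water content with drydown and irrigation events.

    The initial stage receives no irrigation after the transplant event,
    so effective saturation dips below the 0.75 stress threshold (the
    early-season water deficit); from the development stage onward an
    irrigation is triggered whenever S_e falls to the configured trigger
    and the topsoil recovers instantaneously toward 0.95·θ_s.
    """
    rng = np.random.default_rng(seed)
    index = config.hourly_index
    stage = config.stage_of(index.normalize())
    span = config.theta_s - config.theta_w
    decay = np.exp(-config.drydown_per_day / 24.0)

    theta = np.empty(len(index))
    current = config.theta_w + config.irrigation_recovery * span
    events = []
    for i, s in enumerate(stage):
        current = config.theta_w + (current - config.theta_w) * decay
        se = (current - config.theta_w) / span
        if s != "initial" and se <= config.irrigation_trigger_se:
            current = config.theta_w + config.irrigation_recovery * span
            events.append(index[i])
        theta[i] = current
    theta = theta + rng.normal(0.0, 0.0005, len(index))
    theta = np.clip(theta, config.theta_w, config.theta_s)

    out = pd.DataFrame({"theta": theta}, index=index)
    out.attrs["irrigation_events"] = events
    return out


def generate_observed_et(model_et, noise_cv: float = 0.05, seed: int = 0) -> pd.Series:
    """Lysimeter-like observed ET: model·(1 + ε), ε ~ N(0, noise_cv), ≥ 0."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    model_et = pd.Series(model_et)
    rng = np.random.default_rng(seed)
    noisy = model_et * (1.0 + rng.normal(0.0, noise_cv, len(model_et)))
    return noisy.clip(lower=0.0).rename("ET_obs")
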