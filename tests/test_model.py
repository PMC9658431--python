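"""Core IPT model: radiation partition, α_e, hourly simulation, aggregation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import iptet
from iptet import constraints, model


def test_partition_radiation_examples_and_conservation():
    assert model.partition_radiation(400.0, 1.0) == (400.0, 0.0)
    assert model.partition_radiation(400.0, 0.25) == (100.0, 300.0)
    rng = np.random.default_rng(0)
    Rn = rng.uniform(-50, 600, 100)
    tau = rng.uniform(0.01, 1.0, 100)
    Rns, Rnc = model.partition_radiation(Rn, tau)
    assert np.allclose(Rns + Rnc, Rn)


def test_soil_heat_flux_linear():
    assert model.soil_heat_flux(100.0, 0.45) == pytest.approx(45.0)
    assert model.soil_heat_flux(100.0, 0.0) == 0.0
    assert model.soil_heat_flux(-40.0, 0.45) == pytest.approx(-18.0)


def test_equilibrium_evaporation():
    assert model.equilibrium_evaporation(300.0, 300.0, 0.2, 0.067) == 0.0
    got = model.equilibrium_evaporation(300.0, 0.0, 0.199, 0.0668)
    assert got == pytest.approx(0.199 / (0.199 + 0.0668) * 300.0, rel=1e-12)
    assert got == pytest.approx(224.6, abs=0.1)
    # gamma -> 0 limit approaches available energy
    assert model.equilibrium_evaporation(300.0, 0.0, 0.2, 1e-9) == pytest.approx(
        300.0, rel=1e-6
    )


def _alpha_e_components(f_sw, f_t, f_s, tau, f_g, alpha_0=1.26, tau_c=0.55):
    """Oracle: assemble λE + λT from the flux equations and divide by λET_eq."""
    delta, gamma, Rn = 0.17, 0.0668, 430.0
    fac = delta / (delta + gamma)
    a_s0 = constraints.alpha_s0(tau, tau_c, alpha_0)
    a_c0 = constraints.alpha_c0(alpha_0, a_s0, tau)
    Rns, Rnc = tau * Rn, (1 - tau) * Rn
    G = f_g * Rns
    lam_E = f_sw * a_s0 * fac * (Rns - G)
    lam_T = (1 - f_s) * f_t * a_c0 * fac * Rnc
    lam_eq = fac * (Rn - G)
    return (lam_E + lam_T) / lam_eq, a_s0, a_c0


def test_alpha_e_equals_component_assembly_on_random_draws():
    """Closed-form α_e must reproduce the flux-assembled (λE+λT)/λET_eq."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        f_sw = rng.uniform(0.05, 1.0)
        f_t = rng.uniform(0.3, 1.0)
        f_s = rng.uniform(0.0, 0.9)
        tau = rng.uniform(0.01, 0.999)
        f_g = rng.uniform(0.0, 0.9)
        expected, a_s0, a_c0 = _alpha_e_components(f_sw, f_t, f_s, tau, f_g)
        got = model.improved_pt_coefficient(f_sw, f_t, f_s, a_s0, a_c0, tau, f_g)
        assert got == pytest.approx(expected, rel=1e-10)


def test_classical_pt_limit_recovers_alpha0_for_any_lai():
    """No soil heat flux, no stress: α_e = 1.26 whatever the canopy size."""
    for lai in np.linspace(0.0, 6.0, 25):
        tau = float(np.exp(-0.7 * lai))
        a_s0 = constraints.alpha_s0(tau, 0.55, 1.26)
        a_c0 = constraints.alpha_c0(1.26, a_s0, tau) if tau < 1 else 1.26
        got = model.improved_pt_coefficient(1.0, 1.0, 0.0, a_s0, a_c0, tau, 0.0)
        assert got == pytest.approx(1.26, abs=1e-12)


def test_alpha_e_bare_soil_limit_is_fsw_alpha0():
    got = model.improved_pt_coefficient(0.6, 0.9, 0.2, 1.26, 1.26, 1.0, 0.45)
    assert got == pytest.approx(0.6 * 1.26, rel=1e-12)


def test_alpha_e_closed_canopy_limit_is_canopy_term():
    tau = 1e-12
    a_s0 = constraints.alpha_s0(tau, 0.55, 1.26)
    a_c0 = constraints.alpha_c0(1.26, a_s0, tau)
    got = model.improved_pt_coefficient(0.5, 0.8, 0.3, a_s0, a_c0, tau, 0.45)
    assert got == pytest.approx((1 - 0.3) * 0.8 * a_c0, rel=1e-9)


def test_alpha_e_monotone_in_constraints():
    """α_e grows with f_sw and f_t and shrinks with f_s, all else fixed."""
    tau = 0.4
    a_s0 = constraints.alpha_s0(tau)
    a_c0 = constraints.alpha_c0(1.26, a_s0, tau)
    grid = np.linspace(0.0, 1.0, 21)
    up_sw = model.improved_pt_coefficient(grid, 0.8, 0.2, a_s0, a_c0, tau)
    up_t = model.improved_pt_coefficient(0.8, grid, 0.2, a_s0, a_c0, tau)
    down_s = model.improved_pt_coefficient(0.8, 0.8, grid, a_s0, a_c0, tau)
    assert np.all(np.diff(up_sw) > 0)
    assert np.all(np.diff(up_t) > 0)
    assert np.all(np.diff(down_s) < 0)


def test_unit_conversion_watts_to_mm():
    """245 W m⁻² sustained for an hour is 0.36 mm of water."""
    et = 245.0 * 3600.0 / (2.45e6 * model.RHO_WATER) * 1000.0
    assert et == pytest.approx(0.36, abs=1e-9)


class TestSimulateEt:
    def test_flux_identity_and_nonnegativity(self, hourly_et):
        assert np.allclose(
            hourly_et["lambda_ET"], hourly_et["lambda_E"] + hourly_et["lambda_T"]
        )
        assert (hourly_et["ET"] >= 0).all()
        assert np.allclose(
            hourly_et["Rns"] + hourly_et["Rnc"],
            hourly_et["Rns"] / hourly_et["tau"],
        )

    def test_alpha_e_times_equilibrium_matches_fluxes_when_unclipped(
        self, scenario, met, crop, soil
    ):
        params = iptet.ModelParams(clip_negative_et=False)
        out = iptet.simulate_et(
            met, crop, soil, params, senescence_onset=scenario.senescence_onset
        )
        day = out["lambda_ETeq"].abs() > 1.0
        ratio = (out["lambda_ET"][day] / out["lambda_ETeq"][day]).to_numpy()
        assert np.allclose(ratio, out["alpha_e"][day].to_numpy(), rtol=1e-10)

    def test_zero_energy_day_gives_zero_et(self, scenario, crop):
        index = pd.date_range("2019-05-01", periods=24, freq="h")
        met = pd.DataFrame(
            {"Rn": 0.0, "Ta": 20.0, "VPD": 0.5, "u2": 0.1}, index=index
        )
        out = iptet.simulate_et(met, crop)
        assert out["ET"].sum() == 0.0

    def test_met_gap_error_lists_timestamps(self, crop):
        index = pd.date_range("2019-05-01", periods=24, freq="h").delete(5)
        met = pd.DataFrame({"Rn": 100.0, "Ta": 20.0}, index=index)
        with pytest.raises(ValueError, match="2019-05-01 06:00"):
            iptet.simulate_et(met, crop)

    def test_missing_crop_day_error(self, scenario, crop):
        index = pd.date_range("2019-08-01", periods=24, freq="h")
        met = pd.DataFrame({"Rn": 100.0, "Ta": 20.0}, index=index)
        with pytest.raises(ValueError, match="2019-08-01"):
            iptet.simulate_et(met, crop)

    def test_measured_g_overrides_closure(self, crop):
        index = pd.date_range("2019-05-01", periods=24, freq="h")
        met = pd.DataFrame({"Rn": 300.0, "Ta": 22.0, "G": 0.0}, index=index)
        with_g = iptet.simulate_et(met, crop)
        without = iptet.simulate_et(met.drop(columns="G"), crop)
        assert (with_g["G"] == 0.0).all()
        assert (without["G"] > 0.0).all()
        assert with_g["lambda_E"].iloc[12] > without["lambda_E"].iloc[12]


class TestAggregateDaily:
    def test_constant_day(self):
        index = pd.date_range("2019-05-01", periods=24, freq="h")
        daily = model.aggregate_daily(pd.Series(0.1, index=index))
        assert daily["ET"].iloc[0] == pytest.approx(2.4)
        assert daily["complete"].iloc[0]

    def test_missing_hour_flagged_at_zero_tolerance(self):
        index = pd.date_range("2019-05-01", periods=24, freq="h").delete(3)
        daily = model.aggregate_daily(pd.Series(0.1, index=index))
        assert not daily["complete"].iloc[0]
        relaxed = model.aggregate_daily(
            pd.Series(0.1, index=index), max_missing_fraction=0.1
        )
        assert relaxed["complete"].iloc[0]

    def test_daily_sum_conserves_hourly_sum(self, hourly_et):
        daily = model.aggregate_daily(hourly_et)
        assert daily["ET"].sum() == pytest.approx(hourly_et["ET"].sum())
        assert daily["complete"].all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            model.aggregate_daily(pd.Series(dtype=float, index=pd.DatetimeIndex([])))


def test_model_params_validation():
    with pytest.raises(ValueError):
        model.ModelParams(alpha_0=0.9)
    with pytest.raises(ValueError):
        model.ModelParams(f_g=1.0)


def test_f_g_recovery_from_noisy_season(scenario, met, crop, soil):
    """Grid least squares on noisy λET recovers the soil heat flux fraction."""
    truth = iptet.simulate_et(
        met, crop, soil, senescence_onset=scenario.senescence_onset
    )
    rng = np.random.default_rng(7)
    observed = truth["lambda_ET"] * (1 + rng.normal(0, 0.05, len(truth)))
    grid = np.round(np.arange(0.0, 0.91, 0.05), 2)
    sse = []
    for fg in grid:
        params = dataclasses.replace(iptet.ModelParams(), f_g=fg)
        sim = iptet.simulate_et(
            met, crop, soil, params, senescence_onset=scenario.senescence_onset
        )
        sse.append(np.sum((sim["lambda_ET"] - observed) ** 2))
    recovered = grid[int(np.argmin(sse))]
    assert abs(recovered - 0.45) <= 0.05
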