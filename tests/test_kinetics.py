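from dataclasses import replace

import numpy as np
import pytest

from nutrikin import (
    Environment,
    InfeasibleConfigError,
    NutrikinError,
    OrganismConfig,
    QuotaParams,
    SaturationError,
    TransporterParams,
    empirical_tmax_curve,
    esd_scan,
    fit_rht2,
    gen_tmax_table,
    half_saturation_growth,
    kinetic_curve,
    kt_sensitivity,
    power_fit,
    solve_state_at_growth,
    trd_feasibility_surface,
)


class TestSolveState:
    def test_zero_growth_zero_everything(self, c150_10um, env):
        s = solve_state_at_growth(0.0, c150_10um, env)
        assert s.T == 0.0 and s.S0 == 0.0 and s.S_inf == 0.0

    def test_reference_half_growth_point(self, c150_10um, env):
        """Full chain at G_max/2 for the 10 μm fixed-density cell."""
        s = solve_state_at_growth(0.693 / 2, c150_10um, env)
        assert s.NC == pytest.approx(0.11190, abs=1e-5)
        assert s.T == pytest.approx(3.045, rel=1e-3)
        assert s.Tmax_cell == pytest.approx(116.0, rel=1e-3)
        assert s.S0 == pytest.approx(0.0270, rel=2e-3)
        assert s.S_inf == pytest.approx(0.0537, rel=2e-3)

    def test_flat_mode_saturates_at_gmax(self, env):
        cfg = OrganismConfig(ESD=10.0, tmax_mode="flat")
        with pytest.raises(SaturationError):
            solve_state_at_growth(cfg.quota.G_max, cfg, env)

    def test_gmax_saturates_exactly_in_every_mode(self, c150_10um, env):
        """At the replete quota the stress up-regulation vanishes, so
        demand meets capacity exactly at G = G_max; growth sweeps
        therefore stop short of the endpoint."""
        with pytest.raises(SaturationError):
            solve_state_at_growth(0.693, c150_10um, env)
        s = solve_state_at_growth(0.999 * 0.693, c150_10um, env)
        assert s.T < s.Tmax_cell

    def test_infeasible_config_raises_at_construction(self):
        with pytest.raises(InfeasibleConfigError):
            OrganismConfig(
                ESD=80.0, carbon_model="C150",
                quota=QuotaParams(G_max=1.4),
            )


class TestHalfSaturation:
    def test_reference_kg(self, c150_10um, env):
        res = half_saturation_growth(c150_10um, env)
        assert res.K_G == pytest.approx(0.0537, rel=2e-3)
        assert res.S0 + res.diffusion == pytest.approx(res.K_G, rel=1e-12)

    def test_small_cells_surface_equals_bulk(self, env):
        """As ESD shrinks the boundary-layer term vanishes and the bulk
        concentration approaches the membrane concentration."""
        fractions = [
            half_saturation_growth(OrganismConfig(ESD=esd), env).diffusion
            / half_saturation_growth(OrganismConfig(ESD=esd), env).K_G
            for esd in (5.0, 1.0, 0.2)
        ]
        assert fractions[0] > fractions[1] > fractions[2]
        assert fractions[2] < 0.02

    def test_motion_lowers_kg(self, env):
        still = half_saturation_growth(
            OrganismConfig(ESD=20.0, carbon_model="Cprot"), env
        )
        swim = half_saturation_growth(
            OrganismConfig(ESD=20.0, carbon_model="Cprot", motion="swim"), env
        )
        assert swim.K_G < still.K_G

    def test_vacuolation_lowers_kg_at_large_size(self, env):
        diat = half_saturation_growth(
            OrganismConfig(ESD=60.0, carbon_model="Cdiat"), env
        )
        fixed = half_saturation_growth(
            OrganismConfig(ESD=60.0, carbon_model="C150"), env
        )
        assert diat.K_G < fixed.K_G

    def test_flat_tmax_raises_kg(self, env):
        eq5 = half_saturation_growth(OrganismConfig(ESD=10.0), env)
        flat = half_saturation_growth(
            OrganismConfig(ESD=10.0, tmax_mode="flat"), env
        )
        assert flat.K_G > eq5.K_G

    def test_gmax_over_kg_invariant_under_gmax(self, env):
        """G_max/K_G varies by <10% as G_max spans 0.2-1.4 /d."""
        ratios = []
        for gmax in np.linspace(0.2, 1.4, 7):
            cfg = OrganismConfig(
                ESD=10.0, quota=QuotaParams(G_max=gmax)
            )
            ratios.append(gmax / half_saturation_growth(cfg, env).K_G)
        spread = (max(ratios) - min(ratios)) / np.mean(ratios)
        assert spread < 0.10


class TestKineticCurve:
    def test_monotone_and_passes_through_kg(self, c150_10um, env):
        kc = kinetic_curve(c150_10um, env)
        assert np.all(np.diff(kc.S_inf) > 0)
        kg = half_saturation_growth(c150_10um, env).K_G
        # interpolate the curve at G_max/2
        s_at_half = np.interp(0.693 / 2, kc.G, kc.S_inf)
        assert s_at_half == pytest.approx(kg, rel=1e-6)

    def test_flat_mode_curve_lies_above_eq5(self, env):
        g_grid = np.linspace(0.05, 0.65, 40)
        eq5 = kinetic_curve(OrganismConfig(ESD=10.0), env, g_grid)
        flat = kinetic_curve(
            OrganismConfig(ESD=10.0, tmax_mode="flat"), env, g_grid
        )
        assert np.all(flat.S_inf > eq5.S_inf)

    def test_nonmotile_curve_lies_above_motile(self, env):
        g_grid = np.linspace(0.05, 0.65, 40)
        still = kinetic_curve(
            OrganismConfig(ESD=20.0, carbon_model="Cprot"), env, g_grid
        )
        swim = kinetic_curve(
            OrganismConfig(ESD=20.0, carbon_model="Cprot", motion="swim"),
            env, g_grid,
        )
        assert np.all(still.S_inf > swim.S_inf)

    def test_saturated_sweep_is_truncated(self, env, caplog):
        cfg = OrganismConfig(ESD=10.0, tmax_mode="flat")
        grid = np.linspace(0.0, cfg.quota.G_max, 10)  # includes G_max
        with caplog.at_level("WARNING"):
            kc = kinetic_curve(cfg, env, grid)
        assert len(kc.states) == 9
        assert "truncated" in caplog.text


class TestEsdScan:
    def test_kg_strictly_increasing_in_size(self, env):
        for model, motion in [("C150", "none"), ("Cprot", "swim"),
                              ("Cdiat", "sink")]:
            scan = esd_scan(
                OrganismConfig(ESD=10.0, carbon_model=model, motion=motion),
                env,
            )
            kg = scan[scan.feasible]["K_G"].to_numpy()
            assert np.all(np.diff(kg) > 0)

    def test_motile_kg_below_nonmotile_everywhere(self, env):
        still = esd_scan(OrganismConfig(ESD=10, carbon_model="Cprot"), env)
        swim = esd_scan(
            OrganismConfig(ESD=10, carbon_model="Cprot", motion="swim"), env
        )
        assert np.all(swim["K_G"].to_numpy() < still["K_G"].to_numpy())

    def test_infeasible_sizes_recorded_not_raised(self, env):
        cfg = OrganismConfig(
            ESD=5.0, carbon_model="C150", quota=QuotaParams(G_max=1.4)
        )
        scan = esd_scan(cfg, env, np.array([5.0, 10.0, 60.0, 80.0]))
        assert not scan.iloc[-1]["feasible"]
        assert scan.iloc[0]["feasible"]


class TestPowerFit:
    def test_exact_power_law_recovered(self):
        x = np.linspace(2, 50, 20)
        fit = power_fit(np.column_stack([x, 3.0 * x**-1.2]))
        assert fit.params["a"] == pytest.approx(3.0, rel=1e-10)
        assert fit.params["b"] == pytest.approx(-1.2, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_rejected(self):
        x = np.linspace(1, 10, 10)
        with pytest.raises(NutrikinError):
            power_fit(np.column_stack([x, x - 5.0]))

    def test_c150_scan_exponent(self, env):
        fit = power_fit(esd_scan(OrganismConfig(ESD=10.0), env))
        assert fit.params["b"] == pytest.approx(-1.645, abs=0.15)


class TestRht2Fit:
    def test_self_consistency_on_exact_hyperbola(self):
        s = np.geomspace(0.01, 10, 50)
        data = np.column_stack([s, 0.9 * s / (s + 0.3)])
        fit = fit_rht2(data)
        assert fit.params["Vmax"] == pytest.approx(0.9, rel=1e-6)
        assert fit.params["K"] == pytest.approx(0.3, rel=1e-6)

    def test_fixed_max_never_beats_free_fit(self, c150_10um, env):
        kc = kinetic_curve(c150_10um, env)
        free = fit_rht2(kc)
        fixed = fit_rht2(kc, fix_max=0.693)
        assert fixed.r_squared <= free.r_squared
        assert fixed.params["Vmax"] == 0.693

    def test_emergent_curve_misfit(self, env):
        """High R^2 yet systematic overestimation of growth at K_G: the
        emergent curve is steeper than any rectangular hyperbola."""
        cfg = OrganismConfig(ESD=20.0, carbon_model="Cprot", motion="swim")
        kc = kinetic_curve(cfg, env)
        kg = half_saturation_growth(cfg, env).K_G
        fit = fit_rht2(kc)
        assert fit.r_squared > 0.98
        predicted_at_kg = fit.predict(np.array([kg]))[0]
        assert predicted_at_kg > 0.693 / 2


class TestKtSensitivity:
    def test_unit_factor_is_identity(self, c150_10um, env):
        df = kt_sensitivity(c150_10um, env, factors=[1.0])
        assert df["ratio"].iloc[0] == pytest.approx(1.0, rel=1e-12)

    def test_halving_and_doubling(self, c150_10um, env):
        """Halving K_T lowers K_G to ~75%; doubling raises it to ~150%."""
        df = kt_sensitivity(c150_10um, env, factors=[0.5, 2.0])
        assert df["ratio"].iloc[0] == pytest.approx(0.75, abs=0.05)
        assert df["ratio"].iloc[1] == pytest.approx(1.50, abs=0.10)

    def test_surface_component_scales_linearly(self, c150_10um, env):
        base = half_saturation_growth(c150_10um, env)
        tp = replace(c150_10um.transporter, K_T=0.5)
        halved = half_saturation_growth(
            replace(c150_10um, transporter=tp), env
        )
        assert halved.S0 == pytest.approx(base.S0 / 2, rel=1e-12)
        assert halved.diffusion == pytest.approx(base.diffusion, rel=1e-12)


class TestFeasibilitySurface:
    def test_diatoms_need_less_density_than_protists(self, env):
        # above the few-μm crossover of the two biovolume regressions
        esd = np.logspace(np.log10(5), np.log10(80), 10)
        gmax = np.linspace(0.2, 1.4, 5)
        df = trd_feasibility_surface(["Cprot", "Cdiat"], esd, gmax)
        merged = df.pivot_table(
            index=["ESD", "G_max"], columns="carbon_model", values="TRD_Gmax"
        )
        assert np.all(merged["Cdiat"] < merged["Cprot"])

    def test_trd_gmax_vanishes_with_gmax(self, env):
        df = trd_feasibility_surface(["C150"], [10.0], [1e-9])
        assert df["TRD_Gmax"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_large_fast_protists_flagged_infeasible(self, env):
        df = trd_feasibility_surface(["C150"], [80.0], [1.4])
        assert not df["feasible"].iloc[0]


class TestEmpiricalPipeline:
    def test_tabulated_tmax_through_full_pipeline(self, env):
        """A measured-shape Tmax table drives the emergent curve: the
        hyperbolic fit is statistically excellent yet its half-saturation
        is biased away from the true K_G."""
        tab = gen_tmax_table(seed=11)
        cfg = OrganismConfig(
            ESD=10.0, tmax_mode="empirical",
            tmax_curve=empirical_tmax_curve(tab.table()),
        )
        g_grid = np.linspace(0.0, 0.693, 120, endpoint=False)
        kc = kinetic_curve(cfg, env, g_grid)
        fit = fit_rht2(kc)
        kg = half_saturation_growth(cfg, env).K_G
        assert fit.r_squared > 0.95
        assert abs(fit.params["K"] - kg) / kg > 0.02
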