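"""Condition scans: maintenance sensitivity, formaldehyde split, the H2
phase plane with switch/threshold detection, the substrate panel and the
uptake-response regression."""

from dataclasses import replace

import numpy as np
import pytest

from redoxflux.conditions import (build_condition, find_min_h2_uptake,
                                  find_switch_fraction, load_condition,
                                  phase_plane_h2, save_condition,
                                  scan_formaldehyde_split, scan_maintenance,
                                  simulate_substrate_panel, uptake_response_fit)
from redoxflux.conditions import _ols
from redoxflux.curation import MaintenanceSpec
from redoxflux.fba import SolverSettings, solve_fba
from redoxflux.model import ModelError


def non_increasing(seq, tol=1e-8):
    vals = [v for v in seq if v is not None]
    return all(a >= b - tol for a, b in zip(vals[:-1], vals[1:]))


class TestBuildCondition:
    @pytest.mark.parametrize("substrate,uptake", [
        ("CH4", 3.5), ("propane", 3.5 / 3), ("isopropanol", 3.5 / 3), ("acetone", 3.5 / 3),
    ])
    def test_carbon_normalized_uptake(self, substrate, uptake):
        cond = build_condition(substrate, 3.5)
        assert cond.uptake_bounds[cond.substrate_exchange] == pytest.approx(uptake)

    def test_propane_uptake_prints_as_1_16(self):
        cond = build_condition("propane", 3.5)
        assert round(cond.uptake_bounds[cond.substrate_exchange], 2) == 1.17  # 3.5/3 = 1.1667

    def test_zero_uptake_allowed(self):
        cond = build_condition("acetone", 0.0)
        assert cond.uptake_bounds[cond.substrate_exchange] == 0.0

    def test_autotrophic_defaults(self):
        cond = build_condition("H2+CO2")
        assert cond.uptake_bounds["EX_h2_e"] == 13.2
        assert cond.uptake_bounds["EX_co2_e"] == 1000.0
        assert cond.ratio_constraints[0].fraction == 0.76
        assert cond.reversible_overrides["NADH16pp"] == (-1000.0, 1000.0)

    def test_ch4_attaches_formaldehyde_split(self):
        cond = build_condition("CH4")
        rc = cond.ratio_constraints[0]
        assert rc.focal_reaction == "FALDHpp" and rc.fraction == 0.2

    def test_unknown_substrate_rejected(self):
        with pytest.raises(ModelError):
            build_condition("glucose")

    def test_yaml_round_trip(self, tmp_path, maintenance):
        cond = build_condition("H2+CO2", maintenance=maintenance)
        path = tmp_path / "cond.yaml"
        save_condition(cond, path)
        back = load_condition(path)
        assert back.uptake_bounds == cond.uptake_bounds
        assert back.ratio_constraints == cond.ratio_constraints
        assert back.reversible_overrides == cond.reversible_overrides
        assert back.maintenance.ngam == cond.maintenance.ngam


class TestMaintenanceScan:
    def test_mu_non_increasing_in_ngam(self, mini_model, ch4_condition):
        grid = list(np.linspace(0.0, 15.0, 21))
        result = scan_maintenance(mini_model, ch4_condition, "ngam", grid)
        assert non_increasing(result.mu)
        assert all(m is not None for m in result.mu)  # feasible over this range

    def test_infeasible_above_finite_ngam(self, mini_model, ch4_condition):
        grid = list(np.linspace(0.0, 60.0, 13))
        result = scan_maintenance(mini_model, ch4_condition, "ngam", grid)
        assert result.mu[0] is not None
        assert result.mu[-1] is None  # ATP supply from 3.5 CH4 cannot cover it
        # once infeasible, stays infeasible
        first_bad = next(i for i, m in enumerate(result.mu) if m is None)
        assert all(m is None for m in result.mu[first_bad:])

    def test_gam_scan_has_insensitive_segment(self, mini_model, ch4_condition):
        grid = list(np.linspace(0.0, 40.0, 9))
        result = scan_maintenance(mini_model, ch4_condition, "gam", grid)
        assert non_increasing(result.mu)
        # growth is redox- not ATP-limited at low GAM: flat initial segment
        assert result.mu[0] == pytest.approx(result.mu[2], rel=1e-6)

    def test_per_point_agreement_with_direct_solve(self, mini_model, ch4_condition):
        grid = [0.0, 5.0, 10.0]
        result = scan_maintenance(mini_model, ch4_condition, "ngam", grid)
        for value, mu in zip(grid, result.mu):
            cond = replace(ch4_condition,
                           maintenance=ch4_condition.maintenance.replace(ngam=value))
            assert mu == pytest.approx(solve_fba(mini_model, cond).objective_value, abs=1e-9)

    def test_segment_slopes_with_breakpoints(self, mini_model, ch4_condition):
        grid = list(np.linspace(0.0, 12.0, 13))
        result = scan_maintenance(mini_model, ch4_condition, "ngam", grid,
                                  breakpoints=[6.0])
        assert len(result.segment_slopes) == 2
        (seg1, slope1), (seg2, slope2) = result.segment_slopes
        assert slope2 <= slope1 + 1e-12  # decay steepens after the plateau

    def test_bad_grid_rejected(self, mini_model, ch4_condition):
        with pytest.raises(ModelError):
            scan_maintenance(mini_model, ch4_condition, "ngam", [3.0, 1.0])
        with pytest.raises(ModelError):
            scan_maintenance(mini_model, ch4_condition, "atp", [0.0, 1.0])


class TestFormaldehydeSplit:
    def test_mu_non_increasing_in_alpha(self, mini_model, ch4_condition):
        grid = list(np.linspace(0.0, 1.0, 21))
        result = scan_formaldehyde_split(mini_model, ch4_condition, grid)
        assert non_increasing(result.mu)
        assert result.mu[-1] < result.mu[0]  # the constraint really bites

    def test_alpha_zero_recovers_thf_only_optimum(self, mini_model, ch4_condition):
        result = scan_formaldehyde_split(mini_model, ch4_condition, [0.0])
        cond = ch4_condition.with_ratio(ch4_condition.ratio_constraints[0].__class__(
            "FALDHpp", ("FALDHpp", "THFOX"), 0.0))
        assert result.mu[0] == pytest.approx(
            solve_fba(mini_model, cond).objective_value, abs=1e-9)

    def test_empty_denominator_rejected(self, mini_model, ch4_condition):
        with pytest.raises(ModelError):
            scan_formaldehyde_split(mini_model, ch4_condition, [0.2], denominator=())


@pytest.fixture(scope="module")
def plane(mini_model, maintenance):
    return phase_plane_h2(mini_model, h2_grid=[8.0, 13.2],
                          f_grid=np.linspace(0.0, 1.0, 6),
                          maintenance=maintenance)


class TestPhasePlane:
    def test_surfaces_share_shape(self, plane):
        assert plane.mu.shape == plane.complex_i_flux.shape == \
               plane.atp_synthase_flux.shape == (2, 6)

    def test_mu_non_increasing_in_f(self, plane):
        for row in plane.mu:
            vals = row[~np.isnan(row)]
            assert non_increasing(list(vals))

    def test_complex_i_forward_at_f_zero(self, plane):
        assert np.all(plane.complex_i_flux[:, 0] >= -1e-8)

    def test_atp_synthase_lower_at_f_one(self, plane):
        # reverse electron flow diverts proton motive force from ATP production
        assert plane.atp_synthase_flux[1, -1] < plane.atp_synthase_flux[1, 0]


class TestSwitchFraction:
    def test_switch_exists_in_open_interval(self, mini_model, maintenance):
        f_star = find_switch_fraction(mini_model, 13.2, maintenance)
        assert f_star is not None
        assert 0.0 < f_star < 1.0

    def test_bisection_matches_grid_scan(self, mini_model, maintenance):
        f_star = find_switch_fraction(mini_model, 13.2, maintenance, resolution=1e-3)
        settings = SolverSettings(parsimonious=True)
        grid = np.arange(max(0.0, f_star - 0.01), min(1.0, f_star + 0.01), 1e-3)
        signs = []
        for f in grid:
            cond = build_condition("H2+CO2", maintenance=maintenance, hyd_fraction=float(f))
            sol = solve_fba(mini_model, cond, settings)
            signs.append(sol.fluxes["NADH16pp"])
        crossings = [f for f, a, b in zip(grid[:-1], signs[:-1], signs[1:]) if a > 0 >= b]
        assert crossings and abs(crossings[0] - f_star) <= 2e-3

    def test_no_cytosolic_hydrogenase_means_no_switch(self, mini_model, maintenance):
        # with the NAD-coupled hydrogenase blocked, the split constraint
        # leaves growth infeasible below f=1 and complex I always reverse
        blocked = mini_model.copy()
        rxn = blocked.reaction("NAD_H2")
        rxn.lower_bound = rxn.upper_bound = 0.0
        assert find_switch_fraction(blocked, 13.2, maintenance) is None


class TestMinH2Uptake:
    def test_threshold_zero_without_maintenance(self, mini_model):
        free = MaintenanceSpec(gam=0.0, ngam=0.0)
        thr = find_min_h2_uptake(mini_model, f=1.0, maintenance=free)
        assert thr == pytest.approx(0.0, abs=1e-3)

    def test_threshold_positive_with_ngam(self, mini_model, maintenance):
        thr = find_min_h2_uptake(mini_model, f=1.0, maintenance=maintenance)
        assert thr > 0.5

    def test_bisection_matches_grid_scan(self, mini_model, maintenance):
        thr = find_min_h2_uptake(mini_model, f=1.0, maintenance=maintenance,
                                 resolution=1e-3)
        for h2, should_grow in ((thr - 5e-3, False), (thr + 5e-3, True)):
            cond = build_condition("H2+CO2", maintenance=maintenance,
                                   h2_uptake=h2, hyd_fraction=1.0)
            sol = solve_fba(mini_model, cond)
            grows = sol.optimal and sol.objective_value > 1e-6
            assert grows is should_grow, h2


class TestResponseFit:
    def test_noiseless_line_recovered_exactly(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = _ols(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_ols_matches_normal_equations(self, mini_model, maintenance):
        fit = uptake_response_fit(mini_model, ch4_grid=np.linspace(1.0, 6.0, 8),
                                  maintenance=maintenance)
        x = np.array(fit.ch4_grid)
        y = np.array(fit.o2_uptake)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.o2.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.o2.slope == pytest.approx(beta[1], abs=1e-8)
        assert fit.o2.slope > 1.0  # more than one O2 per CH4: monooxygenase + respiration

    def test_too_few_points_rejected(self, mini_model, maintenance):
        with pytest.raises(ModelError):
            uptake_response_fit(mini_model, ch4_grid=[2.0, 3.0], maintenance=maintenance)


@pytest.fixture(scope="module")
def panel(mini_model, maintenance):
    return simulate_substrate_panel(mini_model, maintenance=maintenance)


class TestSubstratePanel:
    def test_isopropanol_outgrows_acetone(self, panel):
        assert panel.loc["isopropanol", "mu"] > panel.loc["acetone", "mu"]

    def test_oxidase_flux_higher_on_isopropanol(self, panel):
        # the extra redox pair from the alcohol dehydrogenase step feeds
        # the cytochrome oxidase
        assert panel.loc["isopropanol", "cyo_flux"] > panel.loc["acetone", "cyo_flux"]

    def test_all_substrates_grow(self, panel):
        assert (panel["status"] == "optimal").all()
        assert (panel["mu"] > 0).all()

    def test_zero_uptake_zero_maintenance_zero_growth(self, mini_model):
        frame = simulate_substrate_panel(
            mini_model, carbon_uptake=0.0,
            maintenance=MaintenanceSpec(gam=0.0, ngam=0.0))
        assert (frame["status"] == "optimal").all()
        assert frame["mu"].abs().max() == pytest.approx(0.0, abs=1e-9)
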