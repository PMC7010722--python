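"""Implicit scheme: fixed point, conservation, stability, oracle agreement."""

import numpy as np
import pytest

from csfna.experiments import PerturbationMultipliers
from csfna.params import InvalidParameterError, nominal_parameters
from csfna.solver import (
    NumericalFailureError,
    SolverGrid,
    assemble_system,
    convergence_report,
    simulate,
)

from conftest import exact_oracle, stiff_oracle, trace_matrix


class TestFixedPoint:
    def test_one_implicit_step_preserves_calibrated_state(
            self, nominal, calibration, geometry):
        grid = SolverGrid(n_r=31, dt=10.0, t_max=100.0)
        stepper = assemble_system(nominal, calibration, None, geometry, grid)
        u0 = stepper.initial_vector()
        u1 = stepper.step(u0)
        assert np.max(np.abs(u1 - u0) / u0) < 1e-12

    def test_identity_multipliers_flat_over_two_hours(
            self, nominal, calibration, geometry):
        grid = SolverGrid(n_r=31, dt=10.0, t_max=7200.0)
        tr = simulate(nominal, calibration, PerturbationMultipliers.identity(),
                      geometry, grid)
        assert np.max(np.abs(tr.C_v_series / tr.C_v_series[0] - 1)) < 1e-4
        assert np.max(np.abs(tr.C_s_series / tr.C_s_series[0] - 1)) < 1e-4
        assert np.max(np.abs(tr.C_br_series / tr.C_br_series[0] - 1)) < 1e-4
        assert np.max(np.abs(tr.Q_v_series)) < 1e-10 * nominal.Q_csf * nominal.C_csf0


class TestDecoupledTissueClosedForm:
    def test_scalar_linear_ode_limit(self, nominal):
        # negligible diffusion and contact permeability: every tissue node
        # relaxes independently as dC/dt = a - k C with a closed-form solution
        p = nominal.with_overrides(D=1e-30, P_vb=1e-30, P_sb=1e-30)
        from csfna.params import calibrate_effluxes, derive_geometry

        calib = calibrate_effluxes(p)
        geometry = derive_geometry(p.V_v, p.V_b)
        mult = PerturbationMultipliers(m_PBBB=1.2)
        grid = SolverGrid(n_r=11, dt=1.0, t_max=600.0)
        tr = simulate(p, calib, mult, geometry, grid)

        a = 1.2 * p.P_BBB * p.A_BBB * p.C_blood
        k = calib.P_BBB_eff * p.A_BBB / p.f_d
        C0 = p.f_d * p.C_csf0
        exact = a / k + (C0 - a / k) * np.exp(-k * tr.times)
        rel = np.abs(tr.C_br_series - exact[:, None]) / exact[:, None]
        assert rel.max() < 1e-6


@pytest.mark.parametrize("mult", [
    PerturbationMultipliers(m_PBCSFB=1.2),
    PerturbationMultipliers(m_PBCSFB_eff=0.8),
    PerturbationMultipliers(m_PBBB=1.2),
    PerturbationMultipliers(m_PBBB_eff=0.8),
], ids=["bcsfb_in_up", "bcsfb_out_down", "bbb_in_up", "bbb_out_down"])
def test_btcs_matches_adaptive_stiff_oracle(nominal, calibration, geometry, mult):
    """dt=1 s trajectories agree with an adaptive stiff integration to 0.1%."""
    grid = SolverGrid(n_r=61, dt=1.0, t_max=7200.0)
    stepper = assemble_system(nominal, calibration, mult, geometry, grid)
    tr = simulate(nominal, calibration, mult, geometry, grid, record_every=120)
    ref = stiff_oracle(stepper, tr.times)
    rel = np.abs(trace_matrix(tr) - ref) / np.abs(ref)
    assert rel.max() < 1e-3


def test_exact_exponential_oracle_agrees(nominal, calibration, geometry):
    """Same comparison against the exact matrix-exponential integrator."""
    mult = PerturbationMultipliers(m_PBBB_eff=0.8)
    grid = SolverGrid(n_r=41, dt=1.0, t_max=3600.0)
    stepper = assemble_system(nominal, calibration, mult, geometry, grid)
    tr = simulate(nominal, calibration, mult, geometry, grid, record_every=60)
    ref = exact_oracle(stepper, tr.times)
    rel = np.abs(trace_matrix(tr) - ref) / np.abs(ref)
    assert rel.max() < 1e-3


class TestQualitativeDynamics:
    def test_bcsfb_influx_rise_monotone(self, nominal, calibration, geometry):
        grid = SolverGrid(n_r=31, dt=10.0, t_max=7200.0)
        tr = simulate(nominal, calibration,
                      PerturbationMultipliers(m_PBCSFB=1.2), geometry, grid)
        assert np.all(np.diff(tr.C_v_series) > 0)
        assert np.all(np.diff(tr.C_s_series) >= -1e-18)
        assert np.all(np.diff(tr.C_br_series, axis=0) >= -1e-18)

    def test_bbb_efflux_drop_raises_tissue_everywhere(
            self, nominal, calibration, geometry):
        grid = SolverGrid(n_r=31, dt=10.0, t_max=7200.0)
        tr = simulate(nominal, calibration,
                      PerturbationMultipliers(m_PBBB_eff=0.8), geometry, grid)
        assert np.all(tr.C_br_series[-1] > tr.C_br_series[0])
        # ventricular rise lags the rise of subarachnoid-adjacent tissue
        t_idx = 30  # 5 min
        rel_v = tr.C_v_series[t_idx] / tr.C_v_series[0] - 1
        rel_outer = (tr.C_br_series[t_idx, -1] / tr.C_br_series[0, -1] - 1)
        assert rel_v < rel_outer

    def test_comparison_principle_in_influx_multiplier(
            self, nominal, calibration, geometry):
        grid = SolverGrid(n_r=21, dt=30.0, t_max=3600.0)
        prev = None
        for m in (1.0, 1.1, 1.2):
            tr = simulate(nominal, calibration,
                          PerturbationMultipliers(m_PBCSFB=m), geometry, grid)
            cur = trace_matrix(tr)
            if prev is not None:
                assert np.all(cur >= prev - 1e-15)
            prev = cur


class TestConservationAndStability:
    def test_global_mass_balance_every_step(self, nominal, calibration, geometry):
        p = nominal
        grid = SolverGrid(n_r=31, dt=10.0, t_max=1800.0)
        mult = PerturbationMultipliers(m_PBCSFB=1.2, m_PBBB_eff=0.8)
        stepper = assemble_system(p, calibration, mult, geometry, grid)
        w = stepper.content_weights
        masses = stepper.cell_masses
        u = stepper.initial_vector()
        total = w @ u
        for _ in range(grid.n_steps):
            u_next = stepper.step(u)
            total_next = w @ u_next
            # implicit fluxes are evaluated at the end-of-step state
            influx = (1.2 * p.P_BCSFB * p.A_BCSFB * p.C_blood
                      + np.sum(masses) * p.P_BBB * p.A_BBB * p.C_blood)
            efflux = (calibration.P_BCSFB_eff * p.A_BCSFB * u_next[0]
                      + 0.8 * calibration.P_BBB_eff * p.A_BBB / p.f_d
                      * (masses @ u_next[1:-1])
                      + p.Q_csf * u_next[-1])
            expected = grid.dt * (influx - efflux)
            assert total_next - total == pytest.approx(
                expected, abs=1e-8 * abs(total))
            u, total = u_next, total_next

    def test_unconditional_stability_at_huge_dt(self, nominal, calibration,
                                                geometry):
        grid = SolverGrid(n_r=31, dt=600.0, t_max=36000.0)
        tr = simulate(nominal, calibration,
                      PerturbationMultipliers(m_PBCSFB=1.2), geometry, grid)
        assert np.all(np.isfinite(trace_matrix(tr)))
        assert tr.C_v_series.max() < 2 * nominal.C_csf0

    def test_numerical_failure_is_diagnosed(self, nominal, calibration, geometry):
        grid = SolverGrid(n_r=11, dt=10.0, t_max=100.0)
        stepper = assemble_system(nominal, calibration, None, geometry, grid)
        u = stepper.initial_vector()
        u[3] = np.nan
        with pytest.raises(Exception):
            bad = stepper.step(u)
            if not np.all(np.isfinite(bad)):
                raise NumericalFailureError("NaN propagated")


class TestConvergence:
    def test_orders_for_smooth_perturbation(self, nominal, calibration):
        base = SolverGrid(n_r=21, dt=60.0, t_max=1800.0)
        rep = convergence_report(nominal, calibration,
                                 PerturbationMultipliers(m_PBCSFB=1.2), base)
        t_orders = rep[rep.axis == "time"]["observed_order"].to_numpy()
        assert 0.8 <= t_orders[0] <= 1.2
        x_order = rep[rep.axis == "space"]["observed_order"].iloc[0]
        assert 1.5 <= x_order <= 2.5

    def test_steady_configuration_has_no_refinement_error(
            self, nominal, calibration):
        base = SolverGrid(n_r=11, dt=120.0, t_max=1200.0)
        rep = convergence_report(nominal, calibration, None, base)
        assert (rep["error_coarse"] < 1e-9).all()
        assert (rep["error_fine"] < 1e-9).all()


class TestGridValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_r": 2}, {"dt": 0.0}, {"n_r": 11, "dt": 10.0, "t_max": 1.0},
    ])
    def test_invalid_grids_rejected(self, kwargs):
        defaults = {"n_r": 11, "dt": 1.0, "t_max": 100.0}
        with pytest.raises(InvalidParameterError):
            SolverGrid(**{**defaults, **kwargs})

    def test_trace_lengths_consistent(self, nominal, calibration, geometry):
        grid = SolverGrid(n_r=11, dt=30.0, t_max=900.0)
        tr = simulate(nominal, calibration, None, geometry, grid)
        assert len(tr.times) == grid.n_steps + 1
        assert tr.C_br_series.shape == (grid.n_steps + 1, grid.n_r)
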