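import numpy as np
import pytest

from csfna.params import (
    PhysiologicalParameterSet,
    calibrate_effluxes,
    derive_geometry,
    nominal_parameters,
)


@pytest.fixture(scope="session")
def nominal():
    return nominal_parameters()


@pytest.fixture(scope="session")
def geometry(nominal):
    return derive_geometry(nominal.V_v, nominal.V_b)


@pytest.fixture(scope="session")
def calibration(nominal):
    return calibrate_effluxes(nominal)


def stiff_oracle(stepper, t_eval):
    """Adaptive stiff method-of-lines reference on the same semi-discrete system."""
    from scipy.integrate import solve_ivp

    sol = solve_ivp(lambda t, u: stepper.M @ u + stepper.b,
                    (t_eval[0], t_eval[-1]), stepper.initial_vector(),
                    method="BDF", jac=stepper.M, rtol=1e-6, atol=1e-11,
                    t_eval=t_eval)
    assert sol.success
    return sol.y  # shape (n_state, len(t_eval))


def exact_oracle(stepper, t_eval):
    """Exact exponential-integrator solution of the semi-discrete system."""
    from scipy.linalg import expm

    u_star = np.linalg.solve(stepper.M, -stepper.b)
    dts = np.diff(t_eval)
    assert np.allclose(dts, dts[0])
    E = expm(stepper.M * dts[0])
    u = stepper.initial_vector()
    out = [u]
    for _ in dts:
        u = u_star + E @ (u - u_star)
        out.append(u)
    return np.array(out).T


def trace_matrix(trace):
    """Stack a trace in solver state ordering, shape (n_state, T)."""
    return np.concatenate([trace.C_v_series[None, :], trace.C_br_series.T,
                           trace.C_s_series[None, :]])
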