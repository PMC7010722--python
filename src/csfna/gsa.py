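"""Variance-based (Sobol) global sensitivity analysis of the sodium model.

The 18-dimensional input space couples inter-subject physiological
variability with migraine-like pathophysiological disturbances:

* 12 independent physiological parameters, uniform within +/-25% of nominal;
* the blood and initial CSF sodium concentrations, uniform within +/-5%;
* 4 pathophysiological multipliers on the barrier permeabilities, uniform
  in [0.5, 1.5], applied to each sampled subject's OWN (re)calibrated
  permeabilities at t=0.

Every sampled subject is recalibrated to its own steady state before the
multipliers hit, so with identity multipliers all outputs vanish: the
analysis isolates the pathophysiology. Because each percent-change output is
a deviation from the subject's own baseline and can take either sign, the
variance decomposition is applied to the ABSOLUTE percent change; the
magnitude of the disturbance, not its direction, is the quantity whose
variance the indices apportion.

First-order indices use the Saltelli (2010) estimator, total-effect indices
the Jansen (1999) estimator; 95% confidence intervals come from a bootstrap
over the base sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .params import (
    InvalidParameterError,
    PhysiologicalParameterSet,
    calibrate_effluxes,
    derive_geometry,
    nominal_parameters,
)
from .solver import SolverGrid, assemble_system

__all__ = [
    "INPUT_NAMES",
    "SamplingDesign",
    "SobolResult",
    "sample_inputs",
    "evaluate_model",
    "evaluate_design",
    "sobol_indices",
    "sobol_indices_from_blocks",
    "screen_noninfluential",
    "sensitivity_landscape",
    "flux_ratio_survey",
    "GSA_GRID",
]

#: canonical input ordering: 12 physiological, 2 concentrations, 4 multipliers
INPUT_NAMES = (
    "P_BCSFB", "A_BCSFB", "V_s", "V_v", "V_b", "P_BBB", "A_BBB", "f_d",
    "D", "Q_csf", "lam", "rho",
    "C_blood", "C_csf0",
    "m_PBCSFB", "m_PBBB", "m_PBCSFB_eff", "m_PBBB_eff",
)
MULTIPLIER_NAMES = INPUT_NAMES[14:]

#: default solver resolution for sensitivity sweeps (coarser than the
#: experiment default; convergence error is far below the effects ranked)
GSA_GRID = SolverGrid(n_r=31, dt=10.0, t_max=7200.0)


@dataclass(frozen=True)
class SamplingDesign:
    """Saltelli cross-sampling design over the 18 uniform inputs."""

    n_base: int
    seed: int
    conc_halfwidth: float = 0.05
    phys_halfwidth: float = 0.25
    patho_halfwidth: float = 0.50
    input_names: tuple = INPUT_NAMES

    def __post_init__(self) -> None:
        if self.n_base < 2:
            raise InvalidParameterError("n_base must be >= 2")
        for hw in (self.conc_halfwidth, self.phys_halfwidth, self.patho_halfwidth):
            if not 0.0 <= hw < 1.0:
                raise InvalidParameterError("halfwidths must lie in [0, 1)")
        if len(self.input_names) != 18:
            raise InvalidParameterError("input_names must have exactly 18 entries")

    @property
    def k(self) -> int:
        return len(self.input_names)

    @property
    def n_evaluations(self) -> int:
        return self.n_base * (self.k + 2)

    def bounds(self, nominal: Optional[PhysiologicalParameterSet] = None):
        """(lower, upper) arrays in input order."""
        p = nominal if nominal is not None else nominal_parameters()
        lo, hi = [], []
        for i, name in enumerate(self.input_names):
            if name in MULTIPLIER_NAMES:
                center, hw = 1.0, self.patho_halfwidth
            elif name in ("C_blood", "C_csf0"):
                center, hw = getattr(p, name), self.conc_halfwidth
            else:
                center, hw = getattr(p, name), self.phys_halfwidth
            lo.append(center * (1.0 - hw))
            hi.append(center * (1.0 + hw))
        return np.asarray(lo), np.asarray(hi)


def sample_inputs(design: SamplingDesign,
                  nominal: Optional[PhysiologicalParameterSet] = None
                  ) -> np.ndarray:
    """Saltelli evaluation matrix, shape (n_base*(k+2), k).

    Row blocks are [A; B; AB_1; ...; AB_k] where AB_i equals A with column i
    replaced from B. Base points come from a scrambled Sobol' sequence in 2k
    dimensions (A from the first k columns, B from the last k), so identical
    seeds give bit-identical matrices.
    """
    k, N = design.k, design.n_base
    sob = qmc.Sobol(d=2 * k, scramble=True, seed=design.seed)
    base = sob.random(N)
    lo, hi = design.bounds(nominal)
    A = lo + (hi - lo) * base[:, :k]
    B = lo + (hi - lo) * base[:, k:]
    blocks = [A, B]
    for i in range(k):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        blocks.append(ABi)
    return np.vstack(blocks)


def _build_subject(x: np.ndarray, base: PhysiologicalParameterSet
                   ) -> PhysiologicalParameterSet:
    phys = dict(zip(INPUT_NAMES[:14], x[:14]))
    return PhysiologicalParameterSet(P_vb=base.P_vb, P_sb=base.P_sb, **phys)


class _FastRun:
    """Per-subject propagator with running reductions for the functionals."""

    def __init__(self, x: np.ndarray, base: PhysiologicalParameterSet,
                 grid: SolverGrid):
        from .experiments import PerturbationMultipliers

        p = _build_subject(x, base)
        calib = calibrate_effluxes(p, strict=False)
        self.negative_efflux = calib.P_BCSFB_eff < 0.0
        mult = PerturbationMultipliers(*x[14:18])
        geometry = derive_geometry(p.V_v, p.V_b)
        stepper = assemble_system(p, calib, mult, geometry, grid)
        self.P, self.c = stepper.propagator()  # deviation-form step
        self.u0 = stepper.initial_vector()
        self.p = p
        self.dt = grid.dt
        # trapezoid weights for the radial integral of 4 pi r^2 C_br
        r = stepper.r
        h = r[1] - r[0]
        w = np.full_like(r, h)
        w[0] = w[-1] = 0.5 * h
        self.w_brain = w * 4.0 * np.pi * r ** 2
        # baseline under the same quadrature, so a steady run is exactly zero
        self.brain_base = self.w_brain @ self.u0[1:-1]


def _row_outputs(x: np.ndarray, base: PhysiologicalParameterSet,
                 grid: SolverGrid, horizon_steps: np.ndarray) -> tuple:
    """Signed (3, H) outputs for one input vector; also negative-efflux flag."""
    run = _FastRun(x, base, grid)
    u0 = run.u0
    delta = np.zeros_like(u0)
    P, c, dt = run.P, run.c, run.dt
    C0 = run.p.C_csf0
    cv_prev, cs_prev = u0[0], u0[-1]
    I_v = I_s = 0.0
    out = np.empty((3, len(horizon_steps)))
    h_iter = 0
    n_steps = int(horizon_steps[-1])
    for k in range(1, n_steps + 1):
        delta = P @ delta + c
        cv, cs = u0[0] + delta[0], u0[-1] + delta[-1]
        I_v += 0.5 * dt * (cv_prev + cv)
        I_s += 0.5 * dt * (cs_prev + cs)
        cv_prev, cs_prev = cv, cs
        while h_iter < len(horizon_steps) and k == horizon_steps[h_iter]:
            T = k * dt
            out[0, h_iter] = (I_v / T - C0) / C0
            out[1, h_iter] = (I_s / T - C0) / C0
            brain = run.w_brain @ (u0[1:-1] + delta[1:-1])
            out[2, h_iter] = brain / run.brain_base - 1.0
            h_iter += 1
    if not np.all(np.isfinite(delta)):
        raise RuntimeError("non-finite state in sensitivity sweep")
    return out, run.negative_efflux


def evaluate_model(x: Sequence[float],
                   horizons: Sequence[float] = (7200.0,),
                   grid: Optional[SolverGrid] = None,
                   base: Optional[PhysiologicalParameterSet] = None
                   ) -> np.ndarray:
    """Signed percent-change outputs (3, n_horizons) for one input vector.

    Rows: ventricular time-average, subarachnoid time-average, brain total
    endpoint. The subject is recalibrated to its own steady state before the
    four multipliers (entries 14..17 of ``x``) are applied.
    """
    grid = grid or GSA_GRID
    base = base or nominal_parameters()
    x = np.asarray(x, dtype=float)
    steps = _horizon_steps(horizons, grid)
    out, _ = _row_outputs(x, base, grid, steps)
    return out


def _horizon_steps(horizons: Sequence[float], grid: SolverGrid) -> np.ndarray:
    steps = np.asarray([int(round(t / grid.dt)) for t in sorted(horizons)])
    if np.any(steps < 1):
        raise InvalidParameterError("every horizon must be at least one time step")
    if len(set(steps)) != len(steps):
        raise InvalidParameterError("horizons collide on the time grid")
    return steps


def evaluate_design(X: np.ndarray,
                    horizons: Sequence[float],
                    grid: Optional[SolverGrid] = None,
                    base: Optional[PhysiologicalParameterSet] = None,
                    progress: bool = False) -> tuple:
    """Run the simulator for every design row.

    Returns ``(Y, info)``: ``Y`` has shape (n_rows, 3, n_horizons) with
    SIGNED percent changes (horizons in ascending order), ``info`` counts
    subjects whose implied BCSFB efflux came out negative (their signed
    calibration is kept; see the package docs).
    """
    grid = grid or GSA_GRID
    base = base or nominal_parameters()
    steps = _horizon_steps(horizons, grid)
    Y = np.empty((X.shape[0], 3, len(steps)))
    n_neg = 0
    for i, x in enumerate(X):
        Y[i], neg = _row_outputs(x, base, grid, steps)
        n_neg += bool(neg)
        if progress and (i + 1) % 1000 == 0:
            print(f"  evaluated {i + 1}/{X.shape[0]} samples", flush=True)
    return Y, {"n_rows": int(X.shape[0]), "n_negative_bcsfb_eff": int(n_neg)}


@dataclass
class SobolResult:
    """First-order and total-effect indices with bootstrap 95% intervals."""

    input_names: tuple
    S1: np.ndarray
    ST: np.ndarray
    S1_ci: np.ndarray  # shape (2, k): lower, upper
    ST_ci: np.ndarray
    n_base: int
    seed: int
    estimator: str = "saltelli2010/jansen"
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "input": list(self.input_names),
            "S1": self.S1, "S1_ci_low": self.S1_ci[0], "S1_ci_high": self.S1_ci[1],
            "ST": self.ST, "ST_ci_low": self.ST_ci[0], "ST_ci_high": self.ST_ci[1],
        })


def _split_saltelli(Y: np.ndarray, n_base: int, k: int):
    if Y.ndim != 1 or len(Y) != n_base * (k + 2):
        raise InvalidParameterError(
            f"output vector length {len(Y)} does not match n_base*(k+2)")
    fA = Y[:n_base]
    fB = Y[n_base:2 * n_base]
    fAB = Y[2 * n_base:].reshape(k, n_base)
    return fA, fB, fAB


def sobol_indices(Y: np.ndarray, design: SamplingDesign,
                  n_boot: int = 1000, boot_seed: int = 0) -> SobolResult:
    """Estimate S1 (Saltelli 2010) and ST (Jansen) from Saltelli-ordered outputs.

    A zero-variance output yields a flagged all-NaN result rather than an
    exception (``result.degenerate``).
    """
    return sobol_indices_from_blocks(Y, design.n_base, design.input_names,
                                     n_boot=n_boot, boot_seed=boot_seed,
                                     seed=design.seed)


def sobol_indices_from_blocks(Y: np.ndarray, n_base: int,
                              input_names: Sequence[str],
                              n_boot: int = 1000, boot_seed: int = 0,
                              seed: int = 0) -> SobolResult:
    """Estimator core for any Saltelli-ordered output vector (k inputs)."""
    input_names = tuple(input_names)
    k, N = len(input_names), n_base
    fA, fB, fAB = _split_saltelli(np.asarray(Y, dtype=float), N, k)
    scale = np.max(np.abs(np.concatenate([fA, fB]))) or 1.0
    V = np.var(np.concatenate([fA, fB]), ddof=1)
    # degenerate if variance is rounding-level relative to the output scale,
    # or absolutely negligible for a dimensionless percent-change output
    if V <= max((1e-10 * scale) ** 2, 1e-24):
        nan = np.full(k, np.nan)
        return SobolResult(input_names, nan.copy(), nan.copy(),
                           np.full((2, k), np.nan), np.full((2, k), np.nan),
                           N, seed, degenerate=True)

    S1 = np.array([np.mean(fB * (fAB[i] - fA)) for i in range(k)]) / V
    ST = np.array([0.5 * np.mean((fA - fAB[i]) ** 2) for i in range(k)]) / V

    rng = np.random.default_rng(boot_seed)
    S1_b = np.empty((n_boot, k))
    ST_b = np.empty((n_boot, k))
    chunk = 256
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, N, size=(m, N))
        a, b = fA[idx], fB[idx]
        Vb = np.var(np.concatenate([a, b], axis=1), axis=1, ddof=1)
        Vb[Vb == 0.0] = np.nan
        for i in range(k):
            ab = fAB[i][idx]
            S1_b[done:done + m, i] = np.mean(b * (ab - a), axis=1) / Vb
            ST_b[done:done + m, i] = 0.5 * np.mean((a - ab) ** 2, axis=1) / Vb
        done += m
    S1_ci = np.nanpercentile(S1_b, [2.5, 97.5], axis=0)
    ST_ci = np.nanpercentile(ST_b, [2.5, 97.5], axis=0)
    return SobolResult(input_names, S1, ST, S1_ci, ST_ci, N, seed)


def screen_noninfluential(result: SobolResult, threshold: float = 0.01,
                          conservative: bool = False) -> dict:
    """Partition inputs by the ST < threshold rule.

    ``conservative=True`` only flags an input when the UPPER bootstrap bound
    of its total effect is below the threshold.
    """
    values = result.ST_ci[1] if conservative else result.ST
    non_influential = [name for name, v in zip(result.input_names, values)
                       if np.isfinite(v) and v < threshold]
    influential = [n for n in result.input_names if n not in non_influential]
    return {"influential": influential, "non_influential": non_influential}


OUTPUT_LABELS = ("ventricular", "subarachnoid", "brain")
DEFAULT_HORIZONS = (60.0, 300.0, 600.0, 1800.0, 3600.0, 7200.0, 10800.0)


def sensitivity_landscape(design: SamplingDesign,
                     horizons: Sequence[float] = DEFAULT_HORIZONS,
                     grid: Optional[SolverGrid] = None,
                     n_boot: int = 1000,
                     progress: bool = False) -> tuple:
    """Total-effect landscape across outputs and horizons.

    Runs one simulation per design row to the longest horizon, evaluates all
    three functionals at every horizon, and applies the Sobol estimators to
    the absolute percent change. Returns ``(table, info)`` where ``table``
    is long-format (output, horizon_s, input, S1, ST, ci_low, ci_high).
    """
    grid = grid or GSA_GRID
    horizons = sorted(horizons)
    if grid.t_max < horizons[-1]:
        grid = SolverGrid(grid.n_r, grid.dt, horizons[-1])
    X = sample_inputs(design)
    Y, info = evaluate_design(X, horizons, grid, progress=progress)
    rows = []
    results = {}
    for oi, label in enumerate(OUTPUT_LABELS):
        for hi, T in enumerate(horizons):
            res = sobol_indices(np.abs(Y[:, oi, hi]), design,
                                n_boot=n_boot, boot_seed=design.seed + 1)
            results[(label, T)] = res
            for j, name in enumerate(design.input_names):
                rows.append({
                    "output": label, "horizon_s": T, "input": name,
                    "S1": res.S1[j], "ST": res.ST[j],
                    "ci_low": res.ST_ci[0, j], "ci_high": res.ST_ci[1, j],
                })
    table = pd.DataFrame(rows)
    info = dict(info, n_base=design.n_base, seed=design.seed,
                dt=grid.dt, n_r=grid.n_r)
    return table, {"info": info, "results": results}


def flux_ratio_survey(n_samples: int, seed: int,
                      t_max: float = 7200.0,
                      grid: Optional[SolverGrid] = None,
                      base: Optional[PhysiologicalParameterSet] = None
                      ) -> np.ndarray:
    """q_v/q_s for plain uniform random subjects+disturbances; one per sample.

    Each draw is a full 18-dimensional input vector (same ranges as the
    Sobol design); q_v and q_s are the time-averaged absolute per-area
    boundary fluxes over [0, t_max].
    """
    grid = grid or SolverGrid(n_r=GSA_GRID.n_r, dt=GSA_GRID.dt, t_max=t_max)
    base = base or nominal_parameters()
    design = SamplingDesign(n_base=max(n_samples, 2), seed=seed)
    lo, hi = design.bounds(base)
    rng = np.random.default_rng(seed)
    X = lo + (hi - lo) * rng.uniform(size=(n_samples, design.k))
    n_steps = int(round(t_max / grid.dt))
    ratios = np.empty(n_samples)
    for i, x in enumerate(X):
        run = _FastRun(x, base, grid)
        u0, P, c, dt = run.u0, run.P, run.c, run.dt
        delta = np.zeros_like(u0)
        f_d, lam = run.p.f_d, run.p.lam
        pv, ps = run.p.P_vb * lam, run.p.P_sb * lam
        dv_prev = ds_prev = 0.0  # equilibrated start: zero boundary deviation
        Iv = Is = 0.0
        for _ in range(n_steps):
            delta = P @ delta + c
            u = u0 + delta
            dv = abs(pv * (u[0] - u[1] / f_d))
            ds = abs(ps * (u[-1] - u[-2] / f_d))
            Iv += 0.5 * dt * (dv_prev + dv)
            Is += 0.5 * dt * (ds_prev + ds)
            dv_prev, ds_prev = dv, ds
        ratios[i] = Iv / Is if Is > 0 else np.nan
    return ratios
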