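"""Perturbation experiments, scalar output functionals and interface fluxes.

A migraine-like disturbance is represented by four dimensionless multipliers
applied at t=0 to the (calibrated) barrier permeabilities and held constant.
Three scalar functionals summarize a run: the percent change of the
time-averaged ventricular or subarachnoid CSF sodium over [0, t_max], and the
percent change of volume-integrated brain tissue sodium at t = t_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    EffluxCalibration,
    Geometry,
    InvalidParameterError,
    PhysiologicalParameterSet,
    calibrate_effluxes,
    derive_geometry,
)
from .solver import SimulationTrace, SolverGrid, simulate

__all__ = [
    "PerturbationMultipliers",
    "OutputFunctional",
    "OUTPUT_KINDS",
    "percent_change",
    "interface_fluxes",
    "absolute_flux_ratio",
    "run_local_sensitivity_suite",
    "CANONICAL_EXPERIMENTS",
]

OUTPUT_KINDS = ("ventricular_timeavg", "subarachnoid_timeavg", "brain_total_endpoint")


@dataclass(frozen=True)
class PerturbationMultipliers:
    """Scale factors on the four pathophysiological permeabilities."""

    m_PBCSFB: float = 1.0
    m_PBBB: float = 1.0
    m_PBCSFB_eff: float = 1.0
    m_PBBB_eff: float = 1.0

    def __post_init__(self) -> None:
        for name in ("m_PBCSFB", "m_PBBB", "m_PBCSFB_eff", "m_PBBB_eff"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be positive, got {v!r}")

    @classmethod
    def identity(cls) -> "PerturbationMultipliers":
        return cls()


@dataclass(frozen=True)
class OutputFunctional:
    """Which scalar summary to evaluate, and over what horizon (s)."""

    kind: str
    t_max: float

    def __post_init__(self) -> None:
        if self.kind not in OUTPUT_KINDS:
            raise InvalidParameterError(
                f"kind must be one of {OUTPUT_KINDS}, got {self.kind!r}")
        if not self.t_max > 0:
            raise InvalidParameterError("t_max must be positive")


def _horizon_index(times: np.ndarray, t_max: float) -> int:
    if t_max > times[-1] * (1 + 1e-9):
        raise InvalidParameterError(
            f"horizon {t_max:g} s exceeds trace end {times[-1]:g} s")
    return int(np.searchsorted(times, t_max * (1 - 1e-9)))


def percent_change(trace: SimulationTrace, f: OutputFunctional,
                   geometry: Geometry, p: PhysiologicalParameterSet) -> float:
    """Signed fractional change of the requested output over [0, f.t_max].

    * ``ventricular_timeavg``: ((1/T) integral of C_v dt - C_v(0)) / C_v(0)
    * ``subarachnoid_timeavg``: the same with C_s
    * ``brain_total_endpoint``: fractional change of the radial integral of
      C_br(t_max, r) * 4 pi r^2 against C_br(0) * V_b (trapezoid on the
      solver grid; the density cancels between numerator and denominator)
    """
    k = _horizon_index(trace.times, f.t_max)
    t = trace.times[: k + 1]
    if f.kind == "ventricular_timeavg":
        series = trace.C_v_series
    elif f.kind == "subarachnoid_timeavg":
        series = trace.C_s_series
    else:
        shell = 4.0 * np.pi * trace.r ** 2
        total = np.trapezoid(trace.C_br_series[k] * shell, trace.r)
        # baseline C_br(0) * V_b evaluated under the same quadrature so the
        # O(h^2) volume error cancels and a steady run reports exactly zero
        base = np.trapezoid(trace.C_br_series[0] * shell, trace.r)
        return float(total / base - 1.0)
    avg = np.trapezoid(series[: k + 1], t) / t[-1]
    return float((avg - series[0]) / series[0])


def interface_fluxes(trace: SimulationTrace, p: PhysiologicalParameterSet,
                     geometry: Geometry, per_area: bool = False):
    """Signed exchange rates Q_v(t), Q_s(t); positive = CSF -> tissue.

    ``per_area=True`` divides out the contact areas (mol cm^-2 s^-1),
    the form the average-absolute-flux ratio is defined in.
    """
    dev_v = trace.C_v_series - trace.C_br_series[:, 0] / p.f_d
    dev_s = trace.C_s_series - trace.C_br_series[:, -1] / p.f_d
    Q_v = p.P_vb * p.lam * dev_v
    Q_s = p.P_sb * p.lam * dev_s
    if not per_area:
        Q_v = Q_v * geometry.A_v
        Q_s = Q_s * geometry.A_s
    return Q_v, Q_s


def absolute_flux_ratio(trace: SimulationTrace, p: PhysiologicalParameterSet,
                        t_max: float) -> float:
    """q_v / q_s: ratio of time-averaged absolute per-area boundary fluxes.

    q_v = (1/T) integral |P_vb lam (C_v - C_br(t, r_i)/f_d)| dt and q_s
    analogously at r_o. Raises on an identically-zero q_s (exact steady
    state), where the ratio is undefined.
    """
    k = _horizon_index(trace.times, t_max)
    t = trace.times[: k + 1]
    dev_v = np.abs(trace.C_v_series[: k + 1]
                   - trace.C_br_series[: k + 1, 0] / p.f_d)
    dev_s = np.abs(trace.C_s_series[: k + 1]
                   - trace.C_br_series[: k + 1, -1] / p.f_d)
    q_v = np.trapezoid(p.P_vb * p.lam * dev_v, t) / t[-1]
    q_s = np.trapezoid(p.P_sb * p.lam * dev_s, t) / t[-1]
    if q_s == 0.0:
        raise ZeroDivisionError("q_s vanishes (exact steady state); ratio undefined")
    return float(q_v / q_s)


#: the four canonical single-parameter perturbations (name -> multipliers)
CANONICAL_EXPERIMENTS = {
    "P_BCSFB_x1.2": PerturbationMultipliers(m_PBCSFB=1.2),
    "P_BCSFB_eff_x0.8": PerturbationMultipliers(m_PBCSFB_eff=0.8),
    "P_BBB_x1.2": PerturbationMultipliers(m_PBBB=1.2),
    "P_BBB_eff_x0.8": PerturbationMultipliers(m_PBBB_eff=0.8),
}


def run_local_sensitivity_suite(p: PhysiologicalParameterSet,
                                grid: SolverGrid,
                                include_control: bool = True):
    """Run the four canonical +/-20% experiments (plus an identity control).

    Returns ``(traces, summary)``: a dict name -> SimulationTrace and a
    DataFrame of the three output functionals per experiment at t_max.
    """
    calib = calibrate_effluxes(p)
    geometry = derive_geometry(p.V_v, p.V_b)
    experiments = dict(CANONICAL_EXPERIMENTS)
    if include_control:
        experiments = {"control": PerturbationMultipliers.identity(), **experiments}

    traces = {}
    rows = []
    for name, mult in experiments.items():
        tr = simulate(p, calib, mult, geometry, grid)
        traces[name] = tr
        row = {"experiment": name, "t_max_s": grid.t_max}
        for kind in OUTPUT_KINDS:
            row[kind] = percent_change(
                tr, OutputFunctional(kind, grid.t_max), geometry, p)
        rows.append(row)
    return traces, pd.DataFrame(rows)
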