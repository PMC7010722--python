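"""Physiological parameters, spherical geometry and steady-state calibration.

The brain is modelled as three concentric spheres: an inner sphere of
ventricular CSF (volume ``V_v``), a spherical shell of brain tissue
(volume ``V_b``) and an outer shell of subarachnoid CSF (volume ``V_s``).
Blood is an infinite reservoir at fixed sodium concentration ``C_blood``.
Sodium crosses the blood-CSF barrier (BCSFB, choroid plexus) and the
blood-brain barrier (BBB) with lumped influx/efflux permeability
coefficients; the two efflux coefficients are not measured quantities but
are *calibrated* so that the nominal physiology is a steady state.

Internal units are cm, s, g, mol/cm^3 (fluids) and mol/g (tissue).
Concentrations are exposed to users in mM; 1 mM = 1e-6 mol/cm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "MM_TO_MOL_PER_CM3",
    "InvalidParameterError",
    "CalibrationInfeasibleError",
    "PhysiologicalParameterSet",
    "Geometry",
    "EffluxCalibration",
    "State",
    "derive_geometry",
    "calibrate_effluxes",
    "isf_concentration",
    "efflux_rate_constant",
    "initial_state",
    "nominal_parameters",
    "load_parameter_file",
    "PARAMETER_UNITS",
]

#: conversion factor from mM to the internal mol/cm^3 concentration unit
MM_TO_MOL_PER_CM3 = 1e-6

#: expected unit string for every fixture / config symbol
PARAMETER_UNITS = {
    "P_BCSFB": "cm/s",
    "A_BCSFB": "cm^2",
    "V_s": "cm^3",
    "V_v": "cm^3",
    "V_b": "cm^3",
    "P_BBB": "cm/s",
    "A_BBB": "cm^2/g",
    "f_d": "cm^3/g",
    "D": "cm^2/s",
    "Q_csf": "cm^3/s",
    "lam": "dimensionless",
    "rho": "g/cm^3",
    "P_vb": "cm/s",
    "P_sb": "cm/s",
    "C_blood": "mM",
    "C_csf0": "mM",
}


class InvalidParameterError(ValueError):
    """A physiological parameter violates its physical constraints."""


class CalibrationInfeasibleError(ValueError):
    """The steady-state calibration would require a negative efflux."""


@dataclass(frozen=True)
class PhysiologicalParameterSet:
    """One 'rat': the independent physiological inputs of the model.

    Concentrations (``C_blood``, ``C_csf0``) are stored internally in
    mol/cm^3. ``C_csf0`` is the shared initial CSF sodium concentration,
    C_v(0) = C_s(0); the equilibrium calibration requires them equal.
    """

    P_BCSFB: float  # BCSFB influx permeability, cm/s
    A_BCSFB: float  # BCSFB surface area, cm^2
    V_s: float      # subarachnoid volume, cm^3
    V_v: float      # ventricular volume, cm^3
    V_b: float      # brain tissue volume, cm^3
    P_BBB: float    # BBB influx permeability, cm/s
    A_BBB: float    # BBB area per brain mass, cm^2/g
    f_d: float      # sodium distribution factor, cm^3/g
    D: float        # sodium diffusivity in ISF, cm^2/s
    Q_csf: float    # bulk CSF flow, cm^3/s
    lam: float      # ISF volume fraction, dimensionless
    rho: float      # brain density, g/cm^3
    P_vb: float     # ventricle-tissue contact permeability, cm/s
    P_sb: float     # subarachnoid-tissue contact permeability, cm/s
    C_blood: float  # blood sodium, mol/cm^3
    C_csf0: float   # initial CSF sodium, mol/cm^3

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise InvalidParameterError(
                    f"parameter {f.name} must be a finite positive number, got {v!r}"
                )
        if not self.lam <= 1.0:
            raise InvalidParameterError(f"lam must lie in (0, 1], got {self.lam}")
        if not self.f_d <= 1.5:
            raise InvalidParameterError(f"f_d must lie in (0, 1.5], got {self.f_d}")

    def check_scale_separation(self, ratio: float = 1e6) -> None:
        """Verify that the tissue-CSF contact permeabilities dwarf the barriers.

        P_vb and P_sb encode 'no rate-limiting diffusion' at the contact
        surfaces; the model's instant-equilibrium reading of Eqs for the
        boundary exchange is only valid when they exceed every barrier
        permeability by orders of magnitude.
        """
        barrier = max(self.P_BCSFB, self.P_BBB)
        if min(self.P_vb, self.P_sb) < ratio * barrier:
            raise InvalidParameterError(
                "P_vb and P_sb must exceed the barrier permeabilities by a "
                f"factor of at least {ratio:g} (got P_vb={self.P_vb:g}, "
                f"P_sb={self.P_sb:g} vs max barrier {barrier:g})"
            )

    def with_overrides(self, **kwargs: float) -> "PhysiologicalParameterSet":
        return replace(self, **kwargs)

    @classmethod
    def from_mM(cls, *, C_blood_mM: float, C_csf0_mM: float, **kwargs: float
                ) -> "PhysiologicalParameterSet":
        return cls(C_blood=C_blood_mM * MM_TO_MOL_PER_CM3,
                   C_csf0=C_csf0_mM * MM_TO_MOL_PER_CM3, **kwargs)


@dataclass(frozen=True)
class Geometry:
    """Concentric-sphere geometry derived from the compartment volumes."""

    r_i: float  # inner (ventricle-tissue) radius, cm
    r_o: float  # outer (tissue-subarachnoid) radius, cm
    A_v: float  # ventricle-tissue contact area, cm^2
    A_s: float  # subarachnoid-tissue contact area, cm^2


@dataclass(frozen=True)
class EffluxCalibration:
    """Dependent efflux permeabilities implied by the t=0 steady state."""

    P_BCSFB_eff: float  # CSF -> blood, cm/s
    P_BBB_eff: float    # tissue -> blood, cm/s


@dataclass
class State:
    """Instantaneous model state: two CSF scalars plus the radial profile."""

    C_v: float            # mol/cm^3
    C_s: float            # mol/cm^3
    C_br: np.ndarray      # mol/g, one entry per radial node

    def __post_init__(self) -> None:
        self.C_br = np.asarray(self.C_br, dtype=float)
        if self.C_v < 0 or self.C_s < 0 or np.any(self.C_br < 0):
            raise InvalidParameterError("state concentrations must be non-negative")


def derive_geometry(V_v: float, V_b: float) -> Geometry:
    """Radii and contact areas of the concentric-sphere brain.

    The ventricle occupies the inner sphere (volume ``V_v``) and the tissue
    the shell between ``r_i`` and ``r_o`` (volume ``V_b``), so
    ``r = (3V / 4 pi)^(1/3)`` at each interface and the contact areas are
    the corresponding sphere surfaces.
    """
    if not (math.isfinite(V_v) and V_v > 0):
        raise InvalidParameterError(f"V_v must be positive, got {V_v!r}")
    if not (math.isfinite(V_b) and V_b >= 0):
        raise InvalidParameterError(f"V_b must be non-negative, got {V_b!r}")
    r_i = (3.0 * V_v / (4.0 * math.pi)) ** (1.0 / 3.0)
    r_o = (3.0 * (V_v + V_b) / (4.0 * math.pi)) ** (1.0 / 3.0)
    return Geometry(r_i=r_i, r_o=r_o,
                    A_v=4.0 * math.pi * r_i ** 2,
                    A_s=4.0 * math.pi * r_o ** 2)


def calibrate_effluxes(p: PhysiologicalParameterSet, *, strict: bool = True
                       ) -> EffluxCalibration:
    """Solve for the two efflux permeabilities from the t=0 steady state.

    At t=0 the CSF and tissue are equilibrated (C_v = C_s = C_csf0 and
    C_br = f_d * C_csf0), so there is no tissue-CSF exchange and no
    diffusion. Zeroing the ventricular balance gives

        P_BCSFB_eff = (P_BCSFB*A_BCSFB*C_blood - Q_csf*C_csf0) / (A_BCSFB*C_csf0)

    and zeroing the tissue balance gives

        P_BBB_eff = P_BBB * C_blood / C_csf0.

    With ``strict=True`` (default) a negative implied BCSFB efflux raises
    :class:`CalibrationInfeasibleError`; ``strict=False`` returns the signed
    value, which still makes the initial state an exact stationary point
    (the total ventricular loss coefficient P'A + Q = P*A*C_blood/C_csf0
    remains positive, so the system stays stable).
    """
    influx = p.P_BCSFB * p.A_BCSFB * p.C_blood     # mol/s into ventricle
    drainage = p.Q_csf * p.C_csf0                  # mol/s out via bulk flow
    if strict and influx <= drainage:
        raise CalibrationInfeasibleError(
            "steady-state calibration requires P_BCSFB*A_BCSFB*C_blood > "
            f"Q_csf*C_csf0, but {influx:.6g} <= {drainage:.6g} mol/s"
        )
    return EffluxCalibration(
        P_BCSFB_eff=(influx - drainage) / (p.A_BCSFB * p.C_csf0),
        P_BBB_eff=p.P_BBB * p.C_blood / p.C_csf0,
    )


def isf_concentration(C_br_value, f_d: float):
    """ISF sodium concentration (mol/cm^3) from tissue content (mol/g)."""
    if not f_d > 0:
        raise InvalidParameterError(f"f_d must be positive, got {f_d!r}")
    return np.asarray(C_br_value) / f_d if np.ndim(C_br_value) else C_br_value / f_d


def efflux_rate_constant(calib: EffluxCalibration, A_BBB: float, f_d: float) -> float:
    """First-order rate constant (1/s) for tissue -> blood sodium loss.

    This is the coefficient of C_br in the tissue balance's efflux term,
    P_BBB_eff * A_BBB / f_d. Division by f_d is the dimensionally
    consistent form (cm/s * cm^2/g / (cm^3/g) = 1/s).
    """
    if not (A_BBB > 0 and f_d > 0):
        raise InvalidParameterError("A_BBB and f_d must be positive")
    return calib.P_BBB_eff * A_BBB / f_d


def initial_state(p: PhysiologicalParameterSet, grid_size: int) -> State:
    """The equilibrated t=0 state on a radial grid of ``grid_size`` nodes."""
    if grid_size < 3:
        raise InvalidParameterError(f"grid_size must be >= 3, got {grid_size}")
    return State(C_v=p.C_csf0, C_s=p.C_csf0,
                 C_br=np.full(grid_size, p.f_d * p.C_csf0))


def _parse_entries(raw: dict) -> dict:
    values = {}
    for name, entry in raw.items():
        if name not in PARAMETER_UNITS:
            raise InvalidParameterError(f"unknown parameter symbol {name!r}")
        if not (isinstance(entry, dict) and set(entry) == {"value", "unit"}):
            raise InvalidParameterError(
                f"parameter {name!r} must be a mapping with 'value' and 'unit'"
            )
        expected = PARAMETER_UNITS[name]
        if entry["unit"] != expected:
            raise InvalidParameterError(
                f"parameter {name!r} has unit {entry['unit']!r}, expected {expected!r}"
            )
        v = float(entry["value"])
        if name in ("C_blood", "C_csf0"):
            v *= MM_TO_MOL_PER_CM3
        values[name] = v
    return values


def load_parameter_file(path_or_stream) -> PhysiologicalParameterSet:
    """Load a structured-text (YAML) parameter file; see data/nominal_rat.yaml."""
    if hasattr(path_or_stream, "read"):
        raw = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            raw = yaml.safe_load(fh)
    values = _parse_entries(raw or {})
    missing = set(PARAMETER_UNITS) - set(values)
    if missing:
        raise InvalidParameterError(f"missing parameters: {sorted(missing)}")
    p = PhysiologicalParameterSet(**values)
    p.check_scale_separation()
    return p


def nominal_parameters(**overrides: float) -> PhysiologicalParameterSet:
    """The shipped nominal adult-rat parameter set, optionally overridden.

    Overrides are given in internal units (mol/cm^3 for concentrations).
    """
    ref = resources.files("csfna.data").joinpath("nominal_rat.yaml")
    with ref.open() as fh:
        p = load_parameter_file(fh)
    return p.with_overrides(**overrides) if overrides else p
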