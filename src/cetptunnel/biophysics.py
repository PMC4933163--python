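"""Young-Laplace driving force and radiolabel-rate conversions.

A lipoprotein particle is a curved phospholipid monolayer with surface
tension α and radius R, so its core sits at an excess internal pressure
P = 2α/R.  HDL (smaller R) is at higher pressure than LDL; the pressure
difference pushed over the tunnel cross-section is the physiological
driving force on a cholesteryl ester inside the tunnel, expressed here
in the simulation unit kcal/mol/Å.

The experimental counterpart converts radiolabeled transfer rates
(specific activity per mass of transfer protein, or bulk plasma flux) to
CE molecules per second per CETP molecule and its reciprocal, the
per-molecule transfer time.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import constants

__all__ = [
    "LipoproteinShell",
    "TunnelCrossSection",
    "SpecificActivity",
    "PlasmaFlux",
    "KCAL_MOL_A_IN_NEWTONS",
    "laplace_pressure",
    "pressure_difference",
    "driving_force",
    "rate_from_specific_activity",
    "rate_from_plasma_flux",
    "per_molecule_time",
]

#: 1 kcal/mol/Å expressed in newtons: 4184 J / N_A / 1e-10 m ≈ 6.948e-11 N.
KCAL_MOL_A_IN_NEWTONS = 4184.0 / (constants.N_A * 1e-10)

_SECONDS_PER_HOUR = 3600.0


@dataclass
class LipoproteinShell:
    """Surface tension (N/m) and radius (Å) of a lipoprotein particle."""

    surface_tension: float
    radius: float

    def __post_init__(self) -> None:
        if self.surface_tension <= 0:
            raise ValueError("surface tension must be positive")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class TunnelCrossSection:
    """Circular tunnel cross-section of the given diameter (Å)."""

    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")

    @property
    def area_m2(self) -> float:
        return math.pi * (self.diameter / 2.0 * 1e-10) ** 2


@dataclass
class SpecificActivity:
    """Radiolabel transfer rate per mass of transfer protein.

    ``activity``: nmol CE / h / µg CETP; ``cetp_mass``: CETP molar mass, Da.
    """

    activity: float
    cetp_mass: float

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValueError("activity must be non-negative")
        if self.cetp_mass <= 0:
            raise ValueError("CETP molar mass must be positive")


@dataclass
class PlasmaFlux:
    """Bulk plasma CE transfer flux with the CETP pool it runs through.

    ``flux``: µg CE / h / ml plasma; ``cetp_concentration``: µg CETP / ml;
    ``ce_mass`` and ``cetp_mass``: molar masses, Da.
    """

    flux: float
    cetp_concentration: float
    ce_mass: float
    cetp_mass: float

    def __post_init__(self) -> None:
        if self.flux < 0:
            raise ValueError("flux must be non-negative")
        if self.cetp_concentration <= 0:
            raise ValueError("CETP concentration must be positive")
        if self.ce_mass <= 0 or self.cetp_mass <= 0:
            raise ValueError("molar masses must be positive")


def laplace_pressure(shell: LipoproteinShell) -> float:
    """Internal excess pressure P = 2α/R of a curved monolayer (Pa)."""
    return 2.0 * shell.surface_tension / (shell.radius * 1e-10)


def pressure_difference(hdl: LipoproteinShell, ldl: LipoproteinShell) -> float:
    """Laplace pressure of the first shell minus the second (Pa).

    Positive when the first particle is the smaller (higher-pressure)
    one; the sign is preserved for the caller to interpret.
    """
    return laplace_pressure(hdl) - laplace_pressure(ldl)


def driving_force(dP: float, cross: TunnelCrossSection) -> float:
    """Force pushed over the tunnel cross-section (kcal/mol/Å).

    ``dP × π(d/2)²`` in newtons, converted with 1 kcal/mol/Å ≈
    6.948e-11 N.
    """
    return dP * cross.area_m2 / KCAL_MOL_A_IN_NEWTONS


def rate_from_specific_activity(m: SpecificActivity) -> float:
    """CE molecules transferred per second per CETP molecule.

    (activity in mol CE/s/µg) ÷ (mol CETP/µg): the molar masses cancel
    the mass units, leaving a per-molecule turnover rate.
    """
    mol_ce_per_s_per_ug = m.activity * 1e-9 / _SECONDS_PER_HOUR
    mol_cetp_per_ug = 1e-6 / m.cetp_mass
    return mol_ce_per_s_per_ug / mol_cetp_per_ug


def rate_from_plasma_flux(m: PlasmaFlux) -> float:
    """CE molecules per second per CETP molecule from a bulk plasma flux."""
    mol_ce_per_s_per_ml = m.flux * 1e-6 / m.ce_mass / _SECONDS_PER_HOUR
    mol_cetp_per_ml = m.cetp_concentration * 1e-6 / m.cetp_mass
    return mol_ce_per_s_per_ml / mol_cetp_per_ml


def per_molecule_time(rate: float) -> float:
    """Seconds per transferred molecule: the reciprocal turnover time."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return 1.0 / rate
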