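"""Equilibrium (Nernst) potentials for ion gradients across Golgi membranes.

Two conventions are exposed deliberately:

``gradient_potential``
    A valence-free *chemical-gradient* potential, ``slope * log10(c_lumen /
    c_cytosol)``.  This is the operational convention used throughout the
    driving-force decomposition: the pumped H+ gradient of one pH unit gives
    +61.5 mV at 37 °C, a 107/140 mM K+ gradient gives -7 mV, and the chloride
    residual of -54 mV corresponds to a ~0.5 mM luminal Cl- equilibrium
    concentration against 4 mM cytosolic Cl-.

``nernst_potential_signed``
    The textbook form with the valence in the denominator,
    ``slope / z * log10(c_lumen / c_cytosol)``.  For anions (z = -1) the two
    conventions differ by sign.

The decomposition assumes zero trans-membrane voltage (counter-ion
conductance non-limiting), so the three chemical terms must close to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "PhysicalConstants",
    "MembraneConditions",
    "IonSpecies",
    "DrivingForceDecomposition",
    "nernst_slope",
    "gradient_potential",
    "nernst_potential_signed",
    "equilibrium_luminal_conc",
    "decompose_proton_motive",
]

#: CODATA 2018 molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314462618
#: CODATA 2018 Faraday constant, C mol^-1.
FARADAY = 96485.33212


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants used by the potential calculations."""

    gas_constant: float = GAS_CONSTANT
    faraday: float = FARADAY

    def __post_init__(self) -> None:
        if self.gas_constant <= 0 or self.faraday <= 0:
            raise ValueError("physical constants must be strictly positive")


@dataclass(frozen=True)
class MembraneConditions:
    """Temperature and the trans-membrane pH pair.

    Parameters
    ----------
    temperature
        Absolute temperature in kelvin.  Defaults to 310.15 K (37 °C), the
        only temperature at which the log-slope is 61.5 mV per decade.
    ph_lumen, ph_cytosol
        Luminal (organelle) and cytosolic pH.
    """

    temperature: float = 310.15
    ph_lumen: float = 6.0
    ph_cytosol: float = 7.0
    constants: PhysicalConstants = PhysicalConstants()

    def __post_init__(self) -> None:
        if not 250.0 < self.temperature < 350.0:
            raise ValueError(
                f"temperature {self.temperature} K outside plausible range (250, 350)"
            )
        for name in ("ph_lumen", "ph_cytosol"):
            value = getattr(self, name)
            if not 0.0 < value < 14.0:
                raise ValueError(f"{name}={value} outside (0, 14)")


@dataclass(frozen=True)
class IonSpecies:
    """An ion with its valence and concentrations on both membrane faces.

    Concentrations are millimolar; ``conc_lumen`` is the Golgi-luminal and
    ``conc_cytosol`` the cytosolic concentration.
    """

    name: str
    valence: int
    conc_cytosol: float
    conc_lumen: float

    def __post_init__(self) -> None:
        if self.valence == 0:
            raise ValueError("valence must be non-zero")
        if self.conc_cytosol <= 0 or self.conc_lumen <= 0:
            raise ValueError("concentrations must be strictly positive")


@dataclass(frozen=True)
class DrivingForceDecomposition:
    """Closure of the pumped-proton chemical potential by counter-ion terms.

    All potentials are millivolts; ``chloride_lumen_equilibrium`` is the
    luminal Cl- concentration (mM) at which the chloride gradient would
    exactly carry the residual term.
    """

    slope_mV_per_decade: float
    proton_term: float
    potassium_term: float
    chloride_residual: float
    chloride_lumen_equilibrium: float

    def as_dict(self) -> dict:
        return {
            "slope_mV_per_decade": self.slope_mV_per_decade,
            "proton_term_mV": self.proton_term,
            "potassium_term_mV": self.potassium_term,
            "chloride_residual_mV": self.chloride_residual,
            "chloride_lumen_equilibrium_mM": self.chloride_lumen_equilibrium,
        }


def nernst_slope(conditions: MembraneConditions | None = None) -> float:
    """Return the Nernst log-slope ln(10)*R*T/F in mV per decade.

    61.5 mV at 310.15 K, 59.2 mV at 298.15 K.
    """
    cond = conditions or MembraneConditions()
    c = cond.constants
    return math.log(10.0) * c.gas_constant * cond.temperature / c.faraday * 1000.0


def gradient_potential(
    conc_lumen: float,
    conc_cytosol: float,
    conditions: MembraneConditions | None = None,
) -> float:
    """Valence-free chemical-gradient potential in mV.

    ``slope * log10(conc_lumen / conc_cytosol)``; positive when the lumen
    holds the higher concentration.
    """
    if conc_lumen <= 0 or conc_cytosol <= 0:
        raise ValueError("concentrations must be strictly positive")
    return nernst_slope(conditions) * math.log10(conc_lumen / conc_cytosol)


def nernst_potential_signed(
    species: IonSpecies, conditions: MembraneConditions | None = None
) -> float:
    """Textbook valence-signed equilibrium potential in mV.

    ``slope / z * log10(conc_lumen / conc_cytosol)``.  Coincides with
    :func:`gradient_potential` for z = +1 and flips sign for z = -1.
    """
    return gradient_potential(species.conc_lumen, species.conc_cytosol, conditions) / (
        species.valence
    )


def equilibrium_luminal_conc(
    conc_cytosol: float,
    target_potential: float,
    conditions: MembraneConditions | None = None,
) -> float:
    """Luminal concentration (mM) whose gradient potential equals the target.

    Algebraic inverse of :func:`gradient_potential` in its first argument.
    """
    if conc_cytosol <= 0:
        raise ValueError("conc_cytosol must be strictly positive")
    return conc_cytosol * 10.0 ** (target_potential / nernst_slope(conditions))


def decompose_proton_motive(
    potassium: IonSpecies,
    cl_cytosol: float,
    conditions: MembraneConditions | None = None,
) -> DrivingForceDecomposition:
    """Decompose the pumped H+ chemical potential into counter-ion terms.

    The proton term is the gradient potential of H+ across the membrane
    (positive for an acidified lumen); the potassium term is the gradient
    potential of K+; chloride is assigned the residual so the three terms
    close to zero, and the luminal Cl- concentration at which its gradient
    matches that residual is reported.

    Requires an acidified lumen (``ph_lumen < ph_cytosol``).
    """
    cond = conditions or MembraneConditions()
    if cond.ph_lumen >= cond.ph_cytosol:
        raise ValueError(
            "decomposition requires an acidified lumen (ph_lumen < ph_cytosol)"
        )
    slope = nernst_slope(cond)
    # [H+] ratio lumen/cytosol = 10^(ph_cytosol - ph_lumen)
    proton = slope * (cond.ph_cytosol - cond.ph_lumen)
    k_term = gradient_potential(potassium.conc_lumen, potassium.conc_cytosol, cond)
    cl_residual = -proton - k_term
    cl_lumen = equilibrium_luminal_conc(cl_cytosol, cl_residual, cond)
    return DrivingForceDecomposition(
        slope_mV_per_decade=slope,
        proton_term=proton,
        potassium_term=k_term,
        chloride_residual=cl_residual,
        chloride_lumen_equilibrium=cl_lumen,
    )
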