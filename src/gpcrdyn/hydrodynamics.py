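"""Rotational correlation time of a protein-detergent complex.

A detergent-solubilized membrane protein tumbles together with its micelle.
Given the weight-averaged molar mass of the complex (e.g. from SEC-MALS),
the mass-fraction-weighted partial specific volume of its components, a
hydration-layer thickness and the solvent viscosity, the isotropic
rotational correlation time follows from the Stokes-Einstein-Debye relation
for a sphere,

    tau_c = 4 pi eta_S r_H^3 / (3 k T),    r_H = r_NH + r_W,

where r_NH is the anhydrous radius of the sphere holding the complex's
molecular volume M vbar / N_A and r_W the hydration shell thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .relaxation import K_BOLTZMANN, N_AVOGADRO

#: (name, partial specific volume ml/g, mass fraction) of a micelle component.
Component = tuple


@dataclass(frozen=True)
class MicelleModel:
    """Composition and solvent parameters of a protein-detergent complex.

    mass is the weight-averaged molar mass in kDa; components are
    (name, vbar ml/g, mass fraction) triples whose fractions sum to 1;
    hydration_thickness in Angstrom; viscosity in cP; temperature in K.
    """

    mass: float
    components: Sequence[Component]
    hydration_thickness: float = 3.2
    viscosity: float = 0.840
    temperature: float = 304.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be > 0 kDa")
        if self.viscosity <= 0 or self.temperature <= 0:
            raise ValueError("viscosity and temperature must be > 0")
        if self.hydration_thickness < 0:
            raise ValueError("hydration thickness must be >= 0")
        for name, vbar, frac in self.components:
            if vbar <= 0:
                raise ValueError(f"component {name!r}: vbar must be > 0")
            if frac < 0:
                raise ValueError(f"component {name!r}: fraction must be >= 0")
        total = sum(frac for _, _, frac in self.components)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mass fractions must sum to 1, got {total}")

    def tau_c(self) -> float:
        """Full pipeline mass -> vbar -> r_NH -> tau_c, in ns."""
        vbar = complex_specific_volume(self.components)
        r_nh = anhydrous_radius(self.mass, vbar)
        return stokes_einstein_tauc(r_nh, self.hydration_thickness,
                                    self.viscosity, self.temperature)


def complex_specific_volume(components: Sequence[Component]) -> float:
    """Mass-fraction-weighted mean partial specific volume, ml/g."""
    total = sum(frac for _, _, frac in components)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"mass fractions must sum to 1, got {total}")
    return sum(vbar * frac for _, vbar, frac in components)


def anhydrous_radius(mass_kda: float, vbar_ml_g: float) -> float:
    """Radius (Angstrom) of the sphere of volume M vbar / N_A.

    mass in kDa, vbar in ml/g.
    """
    if mass_kda <= 0 or vbar_ml_g <= 0:
        raise ValueError("mass and vbar must be > 0")
    # M vbar / N_A in cm^3, then to Angstrom^3 (1 cm^3 = 1e24 A^3)
    volume_a3 = mass_kda * 1e3 * vbar_ml_g / N_AVOGADRO * 1e24
    return (3.0 * volume_a3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def stokes_einstein_tauc(r_nh: float, r_w: float, eta_s: float, temperature: float
                         ) -> float:
    """Stokes-Einstein-Debye tau_c in ns for a hydrated sphere.

    r_nh, r_w in Angstrom, eta_s in cP, temperature in K.
    """
    if r_nh <= 0 or r_w < 0 or eta_s <= 0 or temperature <= 0:
        raise ValueError("radii, viscosity and temperature must be positive")
    r_h = (r_nh + r_w) * 1e-10          # m
    eta_si = eta_s * 1e-3               # Pa s
    tau_s = 4.0 * math.pi * eta_si * r_h ** 3 / (
        3.0 * K_BOLTZMANN * temperature)
    return tau_s * 1e9
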