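"""Substance properties: water medium state and diffusion coefficients.

The dissolution model needs, for every substance and temperature, a
diffusion coefficient ``D`` in water.  ``D`` is estimated from molecular
structure with the modified Stokes--Einstein relation

    D = k_B * T / (n_f * 6 * pi * eta * R_vdW)

where ``R_vdW`` is the sphere-equivalent van der Waals radius of the
molecule, ``eta`` the dynamic viscosity of water at the working
temperature, and ``n_f`` a dimensionless numerical factor of the modified
equation (1.0 recovers the classical Stokes--Einstein limit).

``R_vdW`` is computed from the elemental composition via an atomic
increment scheme (Zhao--Abraham--Zissimos): the molecular van der Waals
volume in cubic angstroms is the sum of atomic contributions minus
5.92 per bond, 14.7 per aromatic ring and 3.8 per non-aromatic ring; the
volume is then mapped to the radius of the equivalent sphere.  An explicit
radius on the substance overrides the computed value.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "BOLTZMANN_CONSTANT",
    "SUPPORTED_ELEMENTS",
    "DiffusionSpec",
    "MediumState",
    "Substance",
    "diffusion_coefficient",
    "load_registry",
    "parse_formula",
    "vdw_radius_from_composition",
    "water_properties",
]

#: CODATA exact value, J/K.  Not configurable.
BOLTZMANN_CONSTANT = 1.380649e-23

# Atomic van der Waals volume contributions, cubic angstrom
# (Zhao, Abraham & Zissimos 2003 increment scheme).
_ATOM_VOLUME_A3 = {
    "C": 20.58,
    "H": 7.24,
    "N": 15.60,
    "O": 14.71,
    "S": 24.43,
    "P": 24.43,
    "F": 13.31,
    "Cl": 22.45,
    "Br": 26.52,
    "I": 32.52,
}
_BOND_CORRECTION_A3 = 5.92
_AROMATIC_RING_CORRECTION_A3 = 14.7
_NONAROMATIC_RING_CORRECTION_A3 = 3.8

SUPPORTED_ELEMENTS = frozenset(_ATOM_VOLUME_A3)

# Vogel (VFT) viscosity correlation for liquid water,
# eta [Pa s] = A * exp(B / (T - C)); good to ~0.3% over 0-100 degC.
_VOGEL_A = 2.939e-5
_VOGEL_B = 507.88
_VOGEL_C = 149.3

# Kell (1975) density polynomial for air-free water at 1 atm, t in degC.
_KELL_NUM = (999.83952, 16.945176, -7.9870401e-3, -46.170461e-6,
             105.56302e-9, -280.54253e-12)
_KELL_DEN = 16.879850e-3


@dataclass(frozen=True)
class MediumState:
    """Thermophysical state of the dissolution medium (SI units)."""

    temperature: float  # K
    dynamic_viscosity: float  # Pa s
    density: float  # kg/m^3

    def __post_init__(self) -> None:
        if not 273.15 < self.temperature < 373.15:
            raise ValueError(
                f"temperature {self.temperature} K outside liquid-water range"
            )
        if self.dynamic_viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        """nu = eta / rho, m^2/s."""
        return self.dynamic_viscosity / self.density


@dataclass(frozen=True)
class DiffusionSpec:
    """Parameters of the modified Stokes--Einstein relation.

    ``numerical_factor`` (n_f) is the dimensionless modification factor;
    1.0 recovers the classical relation.  The Boltzmann constant is fixed.
    """

    numerical_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.numerical_factor <= 0:
            raise ValueError("numerical_factor must be positive")

    @property
    def boltzmann_constant(self) -> float:
        return BOLTZMANN_CONSTANT


@dataclass
class Substance:
    """A pure drug substance.

    Parameters
    ----------
    name
        Identifier used in measurement tables.
    composition
        Element -> atom count map (e.g. ``{"C": 7, "H": 8, "N": 4, "O": 2}``).
    bonds, aromatic_rings, nonaromatic_rings
        Connectivity counts for the van der Waals volume increments.
    vdw_radius_nm
        Explicit sphere-equivalent van der Waals radius in nm; overrides
        the value computed from ``composition``.
    solubilities
        Measured saturation solubility c_s, keyed by temperature in degC,
        values in kg/m^3.
    solubilities_fit
        Solubilities back-fitted from dissolution data (populated by
        :func:`dissoflow.dissolution.fit_solubility`).
    """

    name: str
    composition: dict[str, int] | None = None
    bonds: int = 0
    aromatic_rings: int = 0
    nonaromatic_rings: int = 0
    vdw_radius_nm: float | None = None
    solubilities: dict[float, float] = field(default_factory=dict)
    solubilities_fit: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.composition is None and self.vdw_radius_nm is None:
            raise ValueError(
                f"substance {self.name!r}: need composition or vdw_radius_nm"
            )
        if self.composition is not None:
            bad = set(self.composition) - SUPPORTED_ELEMENTS
            if bad:
                raise ValueError(
                    f"substance {self.name!r}: unsupported elements {sorted(bad)}; "
                    f"supported: {sorted(SUPPORTED_ELEMENTS)}"
                )
            if any(n < 1 for n in self.composition.values()):
                raise ValueError("composition counts must be >= 1")
        if self.vdw_radius_nm is not None and self.vdw_radius_nm <= 0:
            raise ValueError("vdw_radius_nm must be positive")
        for cs in self.solubilities.values():
            if cs <= 0:
                raise ValueError("solubilities must be positive")

    def radius_nm(self) -> float:
        """Resolve the van der Waals radius (explicit override wins)."""
        if self.vdw_radius_nm is not None:
            return self.vdw_radius_nm
        return vdw_radius_from_composition(
            self.composition, self.bonds,
            self.aromatic_rings, self.nonaromatic_rings,
        )

    def solubility_at(self, temperature_C: float) -> float:
        """Measured c_s at a temperature (kg/m^3); exact-key lookup."""
        for t, cs in self.solubilities.items():
            if abs(t - temperature_C) < 1e-9:
                return cs
        raise KeyError(
            f"substance {self.name!r} has no measured solubility at "
            f"{temperature_C} degC (available: {sorted(self.solubilities)})"
        )


def water_properties(temperature_C: float) -> MediumState:
    """Thermophysical properties of pure water at ``temperature_C``.

    Viscosity from a three-parameter Vogel correlation and density from the
    Kell polynomial; both reproduce standard reference-table values to
    within 0.5% over 20-60 degC.
    """
    if not 0.0 < temperature_C < 100.0:
        raise ValueError(
            f"temperature {temperature_C} degC outside (0, 100) liquid range"
        )
    T = temperature_C + 273.15
    eta = _VOGEL_A * math.exp(_VOGEL_B / (T - _VOGEL_C))
    t = temperature_C
    num = sum(c * t**i for i, c in enumerate(_KELL_NUM))
    rho = num / (1.0 + _KELL_DEN * t)
    return MediumState(temperature=T, dynamic_viscosity=eta, density=rho)


def vdw_radius_from_composition(
    composition: dict[str, int],
    bond_count: int,
    aromatic_rings: int = 0,
    nonaromatic_rings: int = 0,
) -> float:
    """Sphere-equivalent van der Waals radius in nm from atom counts.

    V_vdW [A^3] = sum(atomic contributions) - 5.92*bonds
                  - 14.7*aromatic rings - 3.8*non-aromatic rings,
    then r = (3 V / 4 pi)^(1/3).
    """
    if bond_count < 0 or aromatic_rings < 0 or nonaromatic_rings < 0:
        raise ValueError("bond and ring counts must be >= 0")
    bad = set(composition) - SUPPORTED_ELEMENTS
    if bad:
        raise ValueError(
            f"unsupported elements {sorted(bad)}; "
            f"supported: {sorted(SUPPORTED_ELEMENTS)}"
        )
    volume_A3 = sum(_ATOM_VOLUME_A3[el] * n for el, n in composition.items())
    volume_A3 -= _BOND_CORRECTION_A3 * bond_count
    volume_A3 -= _AROMATIC_RING_CORRECTION_A3 * aromatic_rings
    volume_A3 -= _NONAROMATIC_RING_CORRECTION_A3 * nonaromatic_rings
    if volume_A3 <= 0:
        raise ValueError("increment scheme gave non-positive molecular volume")
    radius_A = (3.0 * volume_A3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return radius_A * 0.1  # A -> nm


def diffusion_coefficient(
    substance: Substance,
    medium: MediumState,
    spec: DiffusionSpec = DiffusionSpec(),
) -> float:
    """Modified Stokes--Einstein diffusion coefficient, m^2/s."""
    radius_m = substance.radius_nm() * 1e-9
    if radius_m <= 0:
        raise ValueError("van der Waals radius must be positive")
    eta = medium.dynamic_viscosity
    return (
        spec.boltzmann_constant * medium.temperature
        / (spec.numerical_factor * 6.0 * math.pi * eta * radius_m)
    )


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string (e.g. ``C7H8N4O2``) to a count map."""
    composition: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {pos}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        composition[element] = composition.get(element, 0) + (
            int(count) if count else 1
        )
    if pos != len(formula) or not composition:
        raise ValueError(f"cannot parse formula {formula!r}")
    return composition


def load_registry(path: str | Path) -> dict[str, Substance]:
    """Load a substance registry from JSON.

    Expected shape::

        {"substances": [
            {"name": ..., "formula": "C7H8N4O2", "bonds": 21,
             "aromatic_rings": 2, "nonaromatic_rings": 0,
             "vdw_radius_nm": null,
             "solubilities": {"25": 7.5, "37": 12.4}},
            ...
        ]}
    """
    with open(path) as fh:
        raw = json.load(fh)
    registry: dict[str, Substance] = {}
    for entry in raw["substances"]:
        composition = (
            parse_formula(entry["formula"]) if entry.get("formula") else None
        )
        registry[entry["name"]] = Substance(
            name=entry["name"],
            composition=composition,
            bonds=int(entry.get("bonds", 0)),
            aromatic_rings=int(entry.get("aromatic_rings", 0)),
            nonaromatic_rings=int(entry.get("nonaromatic_rings", 0)),
            vdw_radius_nm=entry.get("vdw_radius_nm"),
            solubilities={
                float(t): float(cs)
                for t, cs in entry.get("solubilities", {}).items()
            },
        )
    return registry
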