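"""Solvent/cellulose composition arithmetic.

Concentrations are reported as mol % water of the *solvent*,

    mol % water = 100 * n_water / (n_water + n_TBPCl),

with one TBPCl counted per ion pair, and as wt % dissolved cellulose,

    wt % dissolved = 100 * m_dissolved / (m_dissolved + m_water + m_TBPCl).

The weight-percent denominator is the total mass of dissolved cellulose plus
solvent; a product of the two solvent masses would be dimensionally
inconsistent, so the sum form is used (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SpeciesAtomModel",
    "MassModel",
    "CompositionSpec",
    "mol_percent_water",
    "mol_percent_tbpcl",
    "wt_percent_dissolved",
    "count_atoms",
    "dissolved_mass",
]

#: anhydroglucose (C6H10O5) residue mass, amu
GLYCAN_MASS = 162.14
#: tetrabutylphosphonium chloride ion-pair mass, amu (P(C4H9)4+ + Cl-)
TBPCL_MASS = 294.89
#: water molecular mass, amu
WATER_MASS = 18.015


@dataclass(frozen=True)
class SpeciesAtomModel:
    """Atoms per molecule for each species; cellulose strands follow the
    21*g + 3 all-atom count for g glycans plus terminal OH caps."""

    atoms_per_TBP: int = 53  # P + 16 C + 36 H
    atoms_per_Cl: int = 1
    atoms_per_water: int = 3

    def atoms_per_strand(self, n_glycans: int) -> int:
        return 21 * n_glycans + 3


@dataclass(frozen=True)
class MassModel:
    glycan_mass: float = GLYCAN_MASS
    tbpcl_mass: float = TBPCL_MASS
    water_mass: float = WATER_MASS


@dataclass
class CompositionSpec:
    """Solvent composition: TBPCl ion pairs and water molecules, optionally
    around a cellulose bundle (n_strands, n_glycans_per_strand)."""

    n_tbpcl: int
    n_water: int
    bundle: tuple[int, int] | None = None

    def __post_init__(self):
        if self.n_tbpcl < 0 or self.n_water < 0:
            raise ValueError("molecule counts must be non-negative")


def mol_percent_water(n_water: int, n_tbpcl: int) -> float:
    """Solvent water concentration in mol %, counting TBPCl as ion pairs."""
    if n_water + n_tbpcl <= 0:
        raise ValueError("mol %% water undefined: no solvent molecules")
    return 100.0 * n_water / (n_water + n_tbpcl)


def mol_percent_tbpcl(n_water: int, n_tbpcl: int) -> float:
    if n_water + n_tbpcl <= 0:
        raise ValueError("mol %% TBPCl undefined: no solvent molecules")
    return 100.0 * n_tbpcl / (n_water + n_tbpcl)


def wt_percent_dissolved(m_dissolved: float, m_water: float, m_tbpcl: float) -> float:
    """Weight percent of dissolved cellulose in the solution (masses in amu
    or any consistent unit)."""
    total = m_dissolved + m_water + m_tbpcl
    if total <= 0:
        raise ValueError("wt %% dissolved undefined: total mass is zero")
    return 100.0 * m_dissolved / total


def count_atoms(
    comp: CompositionSpec, model: SpeciesAtomModel = SpeciesAtomModel()
) -> dict[str, int]:
    """Cellulose / solvent / total atom counts for a composition."""
    cellulose = 0
    if comp.bundle is not None:
        n_strands, g = comp.bundle
        cellulose = n_strands * model.atoms_per_strand(g)
    solvent = (
        comp.n_tbpcl * (model.atoms_per_TBP + model.atoms_per_Cl)
        + comp.n_water * model.atoms_per_water
    )
    return {
        "cellulose_atoms": cellulose,
        "solvent_atoms": solvent,
        "total_atoms": cellulose + solvent,
    }


def dissolved_mass(n_dissolved_glycans: int,
                   mass_model: MassModel = MassModel()) -> float:
    """Mass (amu) of a number of dissolved anhydroglucose residues."""
    if n_dissolved_glycans < 0:
        raise ValueError("glycan count must be non-negative")
    return n_dissolved_glycans * mass_model.glycan_mass
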