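"""Core domain model: atoms, topologies, frames, trajectories.

Unit conventions used throughout the package:

* coordinates and distances in angstroms (Å)
* time in picoseconds (ps)
* masses in atomic mass units (amu)
* charges in elementary charge units (e)
* energies in kcal/mol
* angles in degrees

Simulation boxes are orthorhombic; periodic distances use the orthorhombic
minimum-image convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ELEMENT_MASSES",
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "ClassificationError",
    "TopologyError",
    "element_from_name",
    "mass_of_element",
    "minimum_image_displacement",
    "minimum_image_distance",
]

ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "Cl": 35.453,
}


class TopologyError(ValueError):
    """Raised when a topology is internally inconsistent."""


class ClassificationError(ValueError):
    """Raised when an atom or residue cannot be assigned to a known species."""


def element_from_name(name: str) -> str:
    """Infer the chemical element from an atom name.

    The naming scheme distinguishes chloride (``Cl``) before falling back on
    the leading letter: cellulose atoms are C1..C6, O1..O6, H1..H62 and the
    hydroxyl hydrogens HO1/HO2/HO3/HO4/HO6; water is Ow/Hw; the phosphonium
    cation uses P, CT, HP and HC2/HC3/HC4.
    """
    if name.startswith("Cl") or name.upper() == "CL":
        return "Cl"
    lead = name[0].upper()
    if lead in ("C", "O", "H", "P", "N"):
        return lead
    raise ClassificationError(f"cannot infer element from atom name {name!r}")


def mass_of_element(element: str) -> float:
    try:
        return ELEMENT_MASSES[element]
    except KeyError:
        raise ClassificationError(f"no mass tabulated for element {element!r}")


@dataclass
class AtomRecord:
    """One atom: 1-based serial id, name, element, mass and optional charge."""

    atom_id: int
    name: str
    element: str
    mass: float
    charge: Optional[float] = None

    def __post_init__(self):
        if self.atom_id < 1:
            raise TopologyError(f"atom_id must be >= 1, got {self.atom_id}")
        if self.mass <= 0:
            raise TopologyError(f"mass must be positive, got {self.mass}")


@dataclass
class Topology:
    """Atoms grouped into cellulose strands (strand -> glycan -> atom indices)
    and solvent molecules (``(species, atom indices)`` with species one of
    ``"TBP"``, ``"Cl"``, ``"water"``).

    All atom indices held by ``strands``/``solvent_molecules``/``bonds`` are
    0-based positions into ``atoms``; glycans are numbered 1..g in a linear
    order, the same direction for every strand.
    """

    atoms: list[AtomRecord]
    strands: list[list[list[int]]] = field(default_factory=list)
    solvent_molecules: list[tuple[str, list[int]]] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise TopologyError("atom_id values must be unique within a topology")
        self.validate_membership()

    # -- derived arrays -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_strands(self) -> int:
        return len(self.strands)

    @property
    def n_glycans_per_strand(self) -> int:
        return len(self.strands[0]) if self.strands else 0

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms], dtype=object)

    def charges(self) -> np.ndarray:
        q = [a.charge for a in self.atoms]
        if any(v is None for v in q):
            missing = [a.atom_id for a in self.atoms if a.charge is None]
            raise TopologyError(f"atoms without charges: {missing[:5]} ...")
        return np.array(q, dtype=float)

    def atom_strand(self) -> np.ndarray:
        """Per-atom strand index, -1 for solvent."""
        out = np.full(self.n_atoms, -1, dtype=int)
        for s, strand in enumerate(self.strands):
            for glycan in strand:
                out[glycan] = s
        return out

    def atom_glycan(self) -> np.ndarray:
        """Per-atom 1-based glycan number within its strand, 0 for solvent."""
        out = np.zeros(self.n_atoms, dtype=int)
        for strand in self.strands:
            for j, glycan in enumerate(strand, start=1):
                out[glycan] = j
        return out

    def atom_solvent_molecule(self) -> np.ndarray:
        """Per-atom solvent molecule index, -1 for cellulose."""
        out = np.full(self.n_atoms, -1, dtype=int)
        for m, (_, idx) in enumerate(self.solvent_molecules):
            out[idx] = m
        return out

    def atom_species(self) -> np.ndarray:
        """Per-atom species tag: 'cellulose', 'TBP', 'Cl' or 'water'."""
        out = np.full(self.n_atoms, "cellulose", dtype=object)
        for species, idx in self.solvent_molecules:
            out[idx] = species
        return out

    def strand_atoms(self, strand: int) -> np.ndarray:
        return np.concatenate([np.asarray(g, dtype=int) for g in self.strands[strand]])

    def bonded_hydrogens(self) -> dict[int, list[int]]:
        """Map heavy-atom index -> covalently bonded hydrogen indices."""
        out: dict[int, list[int]] = {}
        for i, j in self.bonds:
            for a, b in ((i, j), (j, i)):
                if self.atoms[b].element == "H" and self.atoms[a].element != "H":
                    out.setdefault(a, []).append(b)
        return out

    # -- validation -----------------------------------------------------

    def validate_membership(self) -> None:
        """Every atom belongs to exactly one strand-glycan or one solvent
        molecule; per-strand atom count is 21*g + 3."""
        owner = np.zeros(self.n_atoms, dtype=int)
        for strand in self.strands:
            for glycan in strand:
                owner[glycan] += 1
        for _, idx in self.solvent_molecules:
            owner[idx] += 1
        if np.any(owner != 1):
            bad = np.nonzero(owner != 1)[0]
            raise TopologyError(
                f"{bad.size} atoms not assigned to exactly one strand-glycan or "
                f"solvent molecule (first: atom index {bad[0]})"
            )
        for s, strand in enumerate(self.strands):
            g = len(strand)
            n = sum(len(gl) for gl in strand)
            if n != 21 * g + 3:
                raise TopologyError(
                    f"strand {s} has {n} atoms for {g} glycans; expected {21 * g + 3}"
                )


@dataclass
class Frame:
    """A time-stamped periodic-box coordinate set (box edges in Å)."""

    time: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if np.any(self.box <= 0):
            raise ValueError(f"box edges must be positive, got {self.box}")


@dataclass
class Trajectory:
    """A time-ordered frame sequence over one topology; dt is the nominal
    sampling interval in ps."""

    topology: Topology
    frames: list[Frame]
    dt: float

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        times = self.times()
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        for k, f in enumerate(self.frames):
            if f.coords.shape[0] != self.topology.n_atoms:
                raise ValueError(
                    f"frame {k}: {f.coords.shape[0]} coordinates for "
                    f"{self.topology.n_atoms} topology atoms"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)


# -- periodic geometry ---------------------------------------------------


def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, box: Sequence[float]
) -> np.ndarray:
    """Minimum-image displacement vector(s) b - a in an orthorhombic box."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError(f"box edges must be positive, got {box}")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.round(d / box)


def minimum_image_distance(a, b, box) -> float | np.ndarray:
    """Euclidean distance under the orthorhombic minimum-image convention.

    Accepts single 3-vectors or broadcastable arrays of 3-vectors; symmetric
    in its first two arguments.
    """
    d = minimum_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)
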