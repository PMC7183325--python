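"""Readers and writers for the standard text formats.

Supported formats
-----------------
* PDB for topology + coordinates (single model) and multi-model trajectories,
  via biotite.  CRYST1 carries the orthorhombic box.
* XYZ frames, with ``time=<ps> box=<Lx>,<Ly>,<Lz>`` metadata on the comment
  line (metadata written by this package; plain XYZ is accepted when ``dt``
  and ``box`` are supplied).
* LAMMPS text dumps in the ``ITEM: TIMESTEP`` / ``ITEM: ATOMS id type x y z``
  dialect; frame times are timestep * fs_per_step / 1000 ps.

Topology conventions in PDB files (documented, deterministic):

* cellulose glycans are ``BGC`` residues numbered 1..g within each strand;
  a residue-number restart marks the start of a new strand,
* solvent residues are ``TBP`` (53 atoms, canonical atom order), ``CL``
  (one atom) and ``HOH`` (Ow, Hw, Hw),
* covalent bonds are reconstructed from these residue templates by atom
  name (cellulose, water) or canonical atom order (TBP).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import (
    AtomRecord,
    ClassificationError,
    Frame,
    Topology,
    Trajectory,
    element_from_name,
    mass_of_element,
)

__all__ = [
    "FormatError",
    "read_topology",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "TBP_ATOM_NAMES",
    "WATER_ATOM_NAMES",
]


class FormatError(ValueError):
    """Raised when an input file does not parse under the named standard."""


# -- residue templates ---------------------------------------------------

#: canonical TBP atom order: tetrahedral P followed by four butyl arms,
#: each CT,HP,HP / CT,HC2,HC2 / CT,HC3,HC3 / CT,HC4,HC4,HC4.
TBP_ATOM_NAMES: list[str] = ["P"] + [
    name
    for _ in range(4)
    for name in (
        "CT", "HP", "HP",
        "CT", "HC2", "HC2",
        "CT", "HC3", "HC3",
        "CT", "HC4", "HC4", "HC4",
    )
]

#: positional bonds for the canonical TBP atom order
TBP_BOND_TEMPLATE: list[tuple[int, int]] = []
for arm in range(4):
    base = 1 + 13 * arm
    carbons = [base, base + 3, base + 6, base + 9]
    TBP_BOND_TEMPLATE.append((0, carbons[0]))
    for k in range(3):
        TBP_BOND_TEMPLATE.append((carbons[k], carbons[k + 1]))
    TBP_BOND_TEMPLATE += [(carbons[0], base + 1), (carbons[0], base + 2)]
    TBP_BOND_TEMPLATE += [(carbons[1], base + 4), (carbons[1], base + 5)]
    TBP_BOND_TEMPLATE += [(carbons[2], base + 7), (carbons[2], base + 8)]
    TBP_BOND_TEMPLATE += [(carbons[3], base + 10), (carbons[3], base + 11),
                          (carbons[3], base + 12)]

WATER_ATOM_NAMES = ["Ow", "Hw", "Hw"]

#: within-glycan bonds by atom name (β-D-glucopyranose residue)
GLYCAN_BOND_NAMES: list[tuple[str, str]] = [
    ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"), ("C5", "O5"),
    ("O5", "C1"),
    ("C2", "O2"), ("O2", "HO2"),
    ("C3", "O3"), ("O3", "HO3"),
    ("C4", "O4"),
    ("C5", "C6"), ("C6", "O6"), ("O6", "HO6"),
    ("C1", "H1"), ("C2", "H2"), ("C3", "H3"), ("C4", "H4"), ("C5", "H5"),
    ("C6", "H61"), ("C6", "H62"),
    # terminal caps, present on the first / last glycan only
    ("O4", "HO4"), ("C1", "O1"), ("O1", "HO1"),
]

CELLULOSE_RESNAMES = {"BGC", "GLC"}
WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SPC"}


def _glycan_bonds(name_to_idx: dict[str, list[int]]) -> list[tuple[int, int]]:
    bonds = []
    for a, b in GLYCAN_BOND_NAMES:
        if a in name_to_idx and b in name_to_idx:
            for i, j in zip(name_to_idx[a], name_to_idx[b]):
                bonds.append((i, j))
    return bonds


def build_residue_bonds(
    strands: list[list[list[int]]],
    solvent_molecules: list[tuple[str, list[int]]],
    names: Sequence[str],
) -> list[tuple[int, int]]:
    """Reconstruct covalent bonds from the residue templates."""
    bonds: list[tuple[int, int]] = []
    for strand in strands:
        prev_c1 = None
        for glycan in strand:
            lut: dict[str, list[int]] = {}
            for i in glycan:
                lut.setdefault(names[i], []).append(i)
            bonds += _glycan_bonds(lut)
            if prev_c1 is not None and "O4" in lut:
                bonds.append((prev_c1, lut["O4"][0]))
            prev_c1 = lut["C1"][0] if "C1" in lut else None
    for species, idx in solvent_molecules:
        if species == "water":
            bonds += [(idx[0], idx[1]), (idx[0], idx[2])]
        elif species == "TBP":
            bonds += [(idx[i], idx[j]) for i, j in TBP_BOND_TEMPLATE]
    return bonds


# -- PDB -----------------------------------------------------------------


def _atoms_from_names(names: Sequence[str]) -> list[AtomRecord]:
    out = []
    for k, name in enumerate(names):
        el = element_from_name(name)
        out.append(AtomRecord(atom_id=k + 1, name=name, element=el,
                              mass=mass_of_element(el)))
    return out


def _topology_from_residues(
    residues: list[tuple[str, int, list[int]]], names: Sequence[str]
) -> Topology:
    """Assemble a Topology from (res_name, res_id, atom indices) runs."""
    strands: list[list[list[int]]] = []
    solvent: list[tuple[str, list[int]]] = []
    prev_was_glycan = False
    prev_resid = 0
    for res_name, res_id, idx in residues:
        if res_name in CELLULOSE_RESNAMES:
            if not prev_was_glycan or res_id <= prev_resid:
                strands.append([])
            strands[-1].append(idx)
            prev_was_glycan, prev_resid = True, res_id
            continue
        prev_was_glycan = False
        if res_name == "TBP":
            solvent.append(("TBP", idx))
        elif res_name in ("CL", "CLA") or (len(idx) == 1 and names[idx[0]].startswith("Cl")):
            solvent.append(("Cl", idx))
        elif res_name in WATER_RESNAMES:
            solvent.append(("water", idx))
        else:
            raise ClassificationError(
                f"unknown residue name {res_name!r} (residue {res_id})"
            )
    bonds = build_residue_bonds(strands, solvent, names)
    return Topology(atoms=_atoms_from_names(names), strands=strands,
                    solvent_molecules=solvent, bonds=bonds)


def _residue_runs(atoms: struc.AtomArray) -> list[tuple[str, int, list[int]]]:
    runs: list[tuple[str, int, list[int]]] = []
    key = None
    for i in range(atoms.array_length()):
        k = (atoms.chain_id[i], atoms.res_id[i], atoms.res_name[i])
        if k != key:
            runs.append((atoms.res_name[i], int(atoms.res_id[i]), []))
            key = k
        runs[-1][2].append(i)
    return runs


def _read_pdb(path: str):
    try:
        pdbf = PDBFile.read(path)
        stack = pdbf.get_structure()
    except Exception as exc:  # biotite reports the offending line
        raise FormatError(f"cannot parse PDB file {path!r}: {exc}") from exc
    return stack


def _box_from(arr, default=None) -> np.ndarray:
    if getattr(arr, "box", None) is not None:
        box3 = np.asarray(arr.box)
        return np.diag(box3) if box3.ndim == 2 else np.diag(box3[0])
    if default is not None:
        return np.asarray(default, dtype=float)
    return np.array([1e6, 1e6, 1e6])  # effectively non-periodic


def read_structure(path: str, box=None) -> tuple[Topology, Frame]:
    """Read a single-model PDB into a Topology and its coordinate Frame."""
    stack = _read_pdb(path)
    atoms = stack[0]
    names = list(atoms.atom_name)
    topology = _topology_from_residues(_residue_runs(atoms), names)
    frame = Frame(time=0.0, box=_box_from(atoms, box), coords=atoms.coord)
    return topology, frame


def read_topology(path: str, format: str = "pdb", box=None) -> Topology:
    """Read a topology from a PDB file, inferring strand/glycan/solvent
    assignment from residue names and numbering (see module docstring)."""
    if format != "pdb":
        raise FormatError(f"unsupported topology format {format!r}")
    return read_structure(path, box=box)[0]


def _to_atom_array(topology: Topology, coords: np.ndarray) -> struc.AtomArray:
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    chain = np.empty(n, dtype="U4")
    res_id = np.zeros(n, dtype=int)
    res_name = np.empty(n, dtype="U5")
    chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for s, strand in enumerate(topology.strands):
        for j, glycan in enumerate(strand, start=1):
            for i in glycan:
                chain[i] = chains[s % len(chains)]
                res_id[i] = j
                res_name[i] = "BGC"
    resctr = 0
    for species, idx in topology.solvent_molecules:
        resctr += 1
        rn = {"TBP": "TBP", "Cl": "CL", "water": "HOH"}[species]
        for i in idx:
            chain[i] = "X"
            res_id[i] = (resctr - 1) % 9999 + 1
            res_name[i] = rn
    arr.chain_id = chain
    arr.res_id = res_id
    arr.res_name = res_name
    arr.atom_name = np.array([a.name for a in topology.atoms], dtype="U6")
    arr.element = np.array([a.element for a in topology.atoms], dtype="U2")
    arr.hetero = np.full(n, True)
    return arr


def write_structure(path: str, topology: Topology, frame: Frame) -> None:
    """Write a Topology + Frame as a single-model PDB with CRYST1 box."""
    arr = _to_atom_array(topology, frame.coords)
    arr.box = np.diag(frame.box).astype(np.float32)
    pdbf = PDBFile()
    pdbf.set_structure(arr)
    pdbf.write(path)


# -- trajectories --------------------------------------------------------


def _parse_xyz(path: str, topology: Topology, dt, box):
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos, k = 0, 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError:
            raise FormatError(f"{path}: expected atom count at line {pos + 1}")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        t, b = None, None
        for tok in comment.split():
            if tok.startswith("time="):
                t = float(tok[5:])
            elif tok.startswith("box="):
                b = np.array([float(x) for x in tok[4:].split(",")])
        if n != topology.n_atoms:
            raise FormatError(
                f"{path}: frame {k + 1} has {n} atoms, topology has "
                f"{topology.n_atoms}"
            )
        body = lines[pos + 2: pos + 2 + n]
        if len(body) < n:
            raise FormatError(f"{path}: truncated frame {k + 1}")
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in body]
        )
        if t is None:
            if dt is None:
                raise FormatError(
                    f"{path}: no time metadata and no dt supplied"
                )
            t = k * dt
        if b is None:
            if box is None:
                raise FormatError(
                    f"{path}: no box metadata and no box supplied"
                )
            b = np.asarray(box, dtype=float)
        frames.append(Frame(time=t, box=b, coords=coords))
        pos += 2 + n
        k += 1
    return frames


def _parse_lammps_dump(path: str, topology: Topology, fs_per_step: float):
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos, k = 0, 0
    while pos < len(lines):
        if not lines[pos].startswith("ITEM: TIMESTEP"):
            raise FormatError(
                f"{path}: expected 'ITEM: TIMESTEP' at line {pos + 1}"
            )
        step = int(lines[pos + 1])
        if not lines[pos + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise FormatError(
                f"{path}: expected 'ITEM: NUMBER OF ATOMS' at line {pos + 3}"
            )
        n = int(lines[pos + 3])
        if n != topology.n_atoms:
            raise FormatError(
                f"{path}: frame {k + 1} has {n} atoms, topology has "
                f"{topology.n_atoms}"
            )
        if not lines[pos + 4].startswith("ITEM: BOX BOUNDS"):
            raise FormatError(
                f"{path}: expected 'ITEM: BOX BOUNDS' at line {pos + 5}"
            )
        bounds = [tuple(float(v) for v in lines[pos + 5 + i].split()[:2])
                  for i in range(3)]
        box = np.array([hi - lo for lo, hi in bounds])
        header = lines[pos + 8]
        if not header.startswith("ITEM: ATOMS"):
            raise FormatError(
                f"{path}: expected 'ITEM: ATOMS' at line {pos + 9}"
            )
        cols = header.split()[2:]
        try:
            ci, cx = cols.index("id"), cols.index("x")
        except ValueError:
            raise FormatError(f"{path}: dump must provide id and x y z columns")
        body = lines[pos + 9: pos + 9 + n]
        if len(body) < n:
            raise FormatError(f"{path}: truncated frame {k + 1}")
        coords = np.empty((n, 3))
        for ln in body:
            parts = ln.split()
            coords[int(parts[ci]) - 1] = [float(parts[cx + d]) for d in range(3)]
        frames.append(
            Frame(time=step * fs_per_step / 1000.0, box=box, coords=coords)
        )
        pos += 9 + n
        k += 1
    return frames


def read_trajectory(
    path: str,
    format: str,
    topology: Topology,
    dt: Optional[float] = None,
    fs_per_step: float = 2.0,
    box=None,
) -> Trajectory:
    """Read a trajectory; times are taken from the file when present, else
    synthesized from ``dt`` (ps).  LAMMPS dump timesteps are converted with
    ``fs_per_step`` (default 2 fs, the conventional MD integration step)."""
    if format == "xyz":
        frames = _parse_xyz(path, topology, dt, box)
    elif format == "lammps-dump":
        frames = _parse_lammps_dump(path, topology, fs_per_step)
    elif format == "pdb-multi-model":
        stack = _read_pdb(path)
        if stack.array_length() != topology.n_atoms:
            raise FormatError(
                f"{path}: model has {stack.array_length()} atoms, topology "
                f"has {topology.n_atoms}"
            )
        if dt is None:
            raise FormatError("pdb-multi-model requires dt to synthesize times")
        b = _box_from(stack, box)
        frames = [Frame(time=m * dt, box=b, coords=stack.coord[m])
                  for m in range(stack.stack_depth())]
    else:
        raise FormatError(f"unsupported trajectory format {format!r}")
    times = np.array([f.time for f in frames])
    if times.size > 1 and np.any(np.diff(times) <= 0):
        bad = int(np.nonzero(np.diff(times) <= 0)[0][0]) + 1
        raise FormatError(f"{path}: non-monotone frame times at frame {bad + 1}")
    if dt is None:
        dt = float(times[1] - times[0]) if times.size > 1 else 1.0
    return Trajectory(topology=topology, frames=frames, dt=dt)


def write_trajectory(path: str, trajectory: Trajectory, format: str = "xyz") -> None:
    """Write a trajectory as XYZ (with time/box metadata), LAMMPS dump, or a
    multi-model PDB."""
    topo = trajectory.topology
    if format == "xyz":
        names = [a.name for a in topo.atoms]
        with open(path, "w") as fh:
            for f in trajectory.frames:
                bx = ",".join(f"{v:.6f}" for v in f.box)
                fh.write(f"{topo.n_atoms}\n")
                fh.write(f"time={f.time:.6f} box={bx}\n")
                for name, (x, y, z) in zip(names, f.coords):
                    fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")
    elif format == "lammps-dump":
        with open(path, "w") as fh:
            for f in trajectory.frames:
                step = int(round(f.time * 1000 / 2.0))  # 2 fs steps
                fh.write("ITEM: TIMESTEP\n%d\n" % step)
                fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % topo.n_atoms)
                fh.write("ITEM: BOX BOUNDS pp pp pp\n")
                for e in f.box:
                    fh.write(f"0.0 {e:.6f}\n")
                fh.write("ITEM: ATOMS id type x y z\n")
                for i, (x, y, z) in enumerate(f.coords):
                    fh.write(f"{i + 1} 1 {x:.6f} {y:.6f} {z:.6f}\n")
    elif format == "pdb-multi-model":
        arrays = []
        for f in trajectory.frames:
            arr = _to_atom_array(topo, f.coords)
            arr.box = np.diag(f.box).astype(np.float32)
            arrays.append(arr)
        stack = struc.stack(arrays)
        pdbf = PDBFile()
        pdbf.set_structure(stack)
        pdbf.write(path)
    else:
        raise FormatError(f"unsupported trajectory format {format!r}")
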