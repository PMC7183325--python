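"""Group-group pairwise nonbonded energy decomposition.

Energies are the truncated sum over unexcluded minimum-image pairs within a
cutoff (default 20 Å) of

    E(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6] + C q1 q2 / r,

with Lorentz-Berthelot mixing (eps_ij = sqrt(eps_i eps_j), sigma_ij =
(sigma_i + sigma_j)/2) and the Coulomb constant C = 332.0636 kcal Å /
(mol e²).  Interactions between atoms one, two or three bonds apart (1-2,
1-3, 1-4) are excluded; 1-5 and further pairs are retained, including
within the peeling strand itself.  Plain truncation, no long-range or
switching corrections — the decomposition compares groups within one
convention rather than absolute energies.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._neighbors import cross_pairs_within, pairs_within
from .core import Frame, Topology, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "ForceFieldParams",
    "load_forcefield",
    "build_exclusions",
    "pair_energy",
    "decompose_strand_energy",
    "energy_trace",
]

#: kcal Å / (mol e^2)
COULOMB_CONSTANT = 332.0636


class MissingParameterError(KeyError):
    pass


@dataclass
class ForceFieldParams:
    """Per-atom-name nonbonded parameters: charge (e), LJ epsilon (kcal/mol)
    and sigma (Å)."""

    by_name: dict[str, tuple[float, float, float]]

    def arrays(self, topology: Topology) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        q = np.empty(topology.n_atoms)
        eps = np.empty(topology.n_atoms)
        sig = np.empty(topology.n_atoms)
        for i, a in enumerate(topology.atoms):
            try:
                q[i], eps[i], sig[i] = self.by_name[a.name]
            except KeyError:
                raise MissingParameterError(
                    f"no force-field parameters for atom {a.name!r} (id {a.atom_id})"
                )
        if np.any(eps < 0) or np.any(sig <= 0):
            raise ValueError("epsilon must be >= 0 and sigma > 0")
        return q, eps, sig


def load_forcefield(path: str) -> ForceFieldParams:
    """Plain-text schema: one ``name charge epsilon sigma`` line per atom
    name; '#' starts a comment."""
    table = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{ln}: expected 'name charge epsilon sigma'"
                )
            table[parts[0]] = (float(parts[1]), float(parts[2]), float(parts[3]))
    return ForceFieldParams(by_name=table)


def default_forcefield() -> ForceFieldParams:
    """Toy nonbonded parameters for every atom name the builder emits.

    Charges are chosen so each glycan and each water is neutral and each
    TBP carries +1 / Cl -1; magnitudes are plausible but not a fitted force
    field — the decomposition machinery, not the absolute energies, is the
    point of synthetic runs.
    """
    table: dict[str, tuple[float, float, float]] = {}
    for c in ("C1", "C2", "C3", "C4", "C5", "C6"):
        table[c] = (0.20, 0.109, 3.40)
    for o in ("O2", "O3", "O6", "O1"):
        table[o] = (-0.60, 0.170, 3.00)
    for o in ("O4", "O5"):
        table[o] = (-0.45, 0.170, 3.00)
    for h in ("H1", "H2", "H3", "H4", "H5", "H61", "H62"):
        table[h] = (0.0214, 0.0157, 2.50)
    for h in ("HO1", "HO2", "HO3", "HO4", "HO6"):
        table[h] = (0.45, 0.0, 1.00)
    table["P"] = (0.80, 0.20, 3.74)
    table["CT"] = (0.0, 0.109, 3.50)
    table["HP"] = (0.025, 0.0157, 2.50)
    for h in ("HC2", "HC3", "HC4"):
        table[h] = (0.0, 0.0157, 2.50)
    table["Cl"] = (-1.0, 0.100, 4.40)
    table["Ow"] = (-0.834, 0.152, 3.15)
    table["Hw"] = (0.417, 0.0, 1.00)
    return ForceFieldParams(by_name=table)


def write_forcefield(path: str, params: ForceFieldParams) -> None:
    with open(path, "w") as fh:
        fh.write("# atom_name charge(e) epsilon(kcal/mol) sigma(A)\n")
        for name, (q, e, s) in params.by_name.items():
            fh.write(f"{name} {q} {e} {s}\n")


def build_exclusions(topology: Topology) -> list[set[int]]:
    """Per-atom excluded partners: all atoms one, two or three bonds away
    (1-2, 1-3, 1-4), via breadth-first search over the bond graph."""
    adj: list[list[int]] = [[] for _ in range(topology.n_atoms)]
    for i, j in topology.bonds:
        adj[i].append(j)
        adj[j].append(i)
    excl: list[set[int]] = [set() for _ in range(topology.n_atoms)]
    for start in range(topology.n_atoms):
        dist = {start: 0}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            if dist[u] == 3:
                continue
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        excl[start] = {v for v, k in dist.items() if 0 < k <= 3}
    return excl


def _exclusion_keys(exclusions: list[set[int]], n: int) -> np.ndarray:
    keys = [
        i * n + j
        for i, partners in enumerate(exclusions)
        for j in partners
        if i < j
    ]
    return np.asarray(sorted(keys), dtype=np.int64)


def pair_energy(
    frame: Frame,
    params: ForceFieldParams,
    topology: Topology,
    group_a: Sequence[int],
    group_b: Sequence[int],
    exclusions: Optional[list[set[int]]] = None,
    cutoff: float = 20.0,
) -> dict[str, float]:
    """LJ + Coulomb energy between two atom groups (kcal/mol).

    Groups must be disjoint unless identical; the identical-group self mode
    sums each unexcluded pair once.
    """
    a = np.asarray(sorted(group_a), dtype=int)
    b = np.asarray(sorted(group_b), dtype=int)
    q, eps, sig = params.arrays(topology)
    same = a.size == b.size and np.array_equal(a, b)
    if not same and np.intersect1d(a, b).size:
        raise ValueError("groups must be disjoint unless identical")
    if not same and b.size and (a.size == 0 or (b.size and b[0] < a[0])):
        a, b = b, a  # canonical order: pair_energy(A, B) == pair_energy(B, A) exactly
    if same:
        ii, jj, d = pairs_within(frame.coords[a], frame.box, cutoff)
        gi, gj = a[ii], a[jj]
    else:
        ii, jj, d = cross_pairs_within(
            frame.coords[a], frame.coords[b], frame.box, cutoff
        )
        gi, gj = a[ii], b[jj]
    if exclusions is not None and len(gi):
        n = topology.n_atoms
        keys = np.minimum(gi, gj).astype(np.int64) * n + np.maximum(gi, gj)
        keep = ~np.isin(keys, _exclusion_keys(exclusions, n))
        gi, gj, d = gi[keep], gj[keep], d[keep]
    if np.any(d <= 0):
        k = int(np.nonzero(d <= 0)[0][0])
        raise ValueError(f"coincident atoms {gi[k]} and {gj[k]}")
    qq = COULOMB_CONSTANT * q[gi] * q[gj] / d
    sr6 = (0.5 * (sig[gi] + sig[gj]) / d) ** 6
    lj = 4.0 * np.sqrt(eps[gi] * eps[gj]) * (sr6 * sr6 - sr6)
    lj_sum = float(lj.sum())
    qq_sum = float(qq.sum())
    return {"lj": lj_sum, "coulomb": qq_sum, "total": lj_sum + qq_sum}


GROUPS = ["Cl", "TBP", "water", "bundle_minus_strand", "intra_strand_1-5+"]


def decompose_strand_energy(
    frame: Frame,
    params: ForceFieldParams,
    topology: Topology,
    strand: int,
    exclusions: Optional[list[set[int]]] = None,
    cutoff: float = 20.0,
) -> dict[str, dict[str, float]]:
    """Pairwise energies of the peeling strand against each solvent species,
    the rest of the bundle, and its own retained 1-5+ internal pairs."""
    if not 0 <= strand < topology.n_strands:
        raise ValueError(f"no strand {strand}")
    if exclusions is None:
        exclusions = build_exclusions(topology)
    strand_atoms = topology.strand_atoms(strand)
    species = topology.atom_species()
    strand_of = topology.atom_strand()
    out = {}
    for sp in ("Cl", "TBP", "water"):
        idx = np.nonzero(species == sp)[0]
        if idx.size == 0:
            out[sp] = {"lj": 0.0, "coulomb": 0.0, "total": 0.0}
        else:
            out[sp] = pair_energy(
                frame, params, topology, strand_atoms, idx, exclusions, cutoff
            )
    other = np.nonzero((strand_of >= 0) & (strand_of != strand))[0]
    if other.size:
        out["bundle_minus_strand"] = pair_energy(
            frame, params, topology, strand_atoms, other, exclusions, cutoff
        )
    else:
        out["bundle_minus_strand"] = {"lj": 0.0, "coulomb": 0.0, "total": 0.0}
    out["intra_strand_1-5+"] = pair_energy(
        frame, params, topology, strand_atoms, strand_atoms, exclusions, cutoff
    )
    return out


def energy_trace(
    trajectory: Trajectory,
    params: ForceFieldParams,
    strand: int,
    cutoff: float = 20.0,
    rolling: Optional[tuple[int, int]] = None,
) -> pd.DataFrame:
    """Per-frame group energies vs the peeling strand; optionally smoothed
    with (window, stride) through the rolling-average transform."""
    from .conformation import rolling_average

    exclusions = build_exclusions(trajectory.topology)
    rows = []
    for frame in trajectory.frames:
        dec = decompose_strand_energy(
            frame, params, trajectory.topology, strand, exclusions, cutoff
        )
        row = {"time_ps": frame.time}
        for grp, terms in dec.items():
            for key, val in terms.items():
                row[f"{grp}_{key}"] = val
        rows.append(row)
    table = pd.DataFrame(rows)
    if rolling is not None:
        window, stride = rolling
        idx = None
        out = {}
        for col in table.columns:
            idx, vals = rolling_average(table[col].to_numpy(), window, stride)
            out[col] = vals
        table = pd.DataFrame(out, index=idx)
    return table
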