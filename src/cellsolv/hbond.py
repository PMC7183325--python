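"""Geometric hydrogen-bond detection, classification and census statistics.

A bond A⋯H-D (acceptor ⋯ hydrogen - donor, with H covalently bonded to D)
is accepted when, under the minimum-image convention,

* d(H⋯A) <= 2.45 Å,
* the angle at the donor between D->H and D->A is <= 30 degrees, and
* d(D⋯A) <= 3.5 Å,

the standard geometric criterion for this solvent family.  The angle vertex
sits at the donor by default ("hydrogen-donor-acceptor"); a vertex-at-
hydrogen convention (deviation from D-H⋯A linearity) is available via
``angle_vertex="hydrogen"`` since both conventions are in circulation.

Classification partitions bonds into primary intra-strand (O5⋯HO3-O3 and
O6⋯HO2-O2 within one strand — the pairs present in the experimental Iβ
crystal), other intra-strand, inter-strand, solvent-strand by species, and
solvent-solvent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._neighbors import cross_pairs_within
from .core import Frame, Topology, TopologyError, Trajectory, minimum_image_displacement
from .synthetic import StrandClassMap

__all__ = [
    "HBondCriteria",
    "HBond",
    "detect_hbonds",
    "classify_hbonds",
    "per_glycan_class_average",
    "solvent_proximity_count",
    "pocket_census",
]

#: primary intra-strand pairs as (acceptor name, donor name)
PRIMARY_PAIRS = {("O5", "O3"), ("O6", "O2")}

BOND_CLASSES = [
    "intra_primary", "intra_other", "inter_strand",
    "Cl_strand", "TBP_strand", "water_strand", "solvent_solvent",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric admission thresholds (Å, degrees)."""

    d_ha_max: float = 2.45
    angle_max: float = 30.0
    d_da_max: float = 3.5

    def __post_init__(self):
        if min(self.d_ha_max, self.angle_max, self.d_da_max) <= 0:
            raise ValueError("criteria must be positive")
        if self.d_da_max < self.d_ha_max:
            raise ValueError("d_da_max must be >= d_ha_max")


@dataclass
class HBond:
    """One detected bond; donor/hydrogen/acceptor are 0-based atom indices
    into the topology."""

    frame_index: int
    donor: int
    hydrogen: int
    acceptor: int
    bond_class: Optional[str] = None


def _donor_hydrogen_pairs(
    topology: Topology,
    donor_names: Optional[set[str]],
    include_ch: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """(hydrogen index, donor index) arrays for all eligible donors."""
    bonded_h = topology.bonded_hydrogens()
    hs, ds = [], []
    for d, hlist in bonded_h.items():
        el = topology.atoms[d].element
        if el == "C" and not include_ch:
            continue
        if el not in ("O", "C", "N"):
            continue
        if donor_names is not None and topology.atoms[d].name not in donor_names:
            continue
        for h in hlist:
            hs.append(h)
            ds.append(d)
    return np.asarray(hs, dtype=int), np.asarray(ds, dtype=int)


def _acceptor_indices(
    topology: Topology, acceptor_names: Optional[set[str]]
) -> np.ndarray:
    out = [
        i
        for i, a in enumerate(topology.atoms)
        if a.element in ("O", "Cl", "N")
        and (acceptor_names is None or a.name in acceptor_names)
    ]
    return np.asarray(out, dtype=int)


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
    donors: Optional[set[str]] = None,
    acceptors: Optional[set[str]] = None,
    include_ch_donors: bool = False,
    angle_vertex: str = "donor",
    frame_index: int = 0,
) -> list[HBond]:
    """Detect all hydrogen bonds in one frame.

    ``donors`` / ``acceptors`` restrict by atom name (None = all O-H — plus
    C-H when ``include_ch_donors`` — donors; all O and Cl acceptors).  One
    hydrogen may bond several acceptors simultaneously; no exclusivity is
    imposed.  Output is ordered by (donor, acceptor, hydrogen) index.
    """
    hs, ds = _donor_hydrogen_pairs(topology, donors, include_ch_donors)
    if donors is not None and len(hs) == 0:
        raise TopologyError("no eligible donor has a covalently bonded hydrogen")
    acc = _acceptor_indices(topology, acceptors)
    if len(hs) == 0 or len(acc) == 0:
        return []
    ih, ia, _ = cross_pairs_within(
        frame.coords[hs], frame.coords[acc], frame.box, criteria.d_ha_max
    )
    bonds = []
    for k in range(len(ih)):
        h, d, a = hs[ih[k]], ds[ih[k]], acc[ia[k]]
        if a == d or a == h:
            continue
        v_da = minimum_image_displacement(frame.coords[d], frame.coords[a], frame.box)
        d_da = np.linalg.norm(v_da)
        if d_da > criteria.d_da_max:
            continue
        v_dh = minimum_image_displacement(frame.coords[d], frame.coords[h], frame.box)
        if angle_vertex == "donor":
            cosang = v_dh @ v_da / (np.linalg.norm(v_dh) * d_da)
        elif angle_vertex == "hydrogen":
            v_hd = -v_dh
            v_ha = minimum_image_displacement(
                frame.coords[h], frame.coords[a], frame.box
            )
            # deviation from D-H...A linearity
            cosang = -(v_hd @ v_ha) / (np.linalg.norm(v_hd) * np.linalg.norm(v_ha))
        else:
            raise ValueError(f"unknown angle vertex {angle_vertex!r}")
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if ang <= criteria.angle_max:
            bonds.append(HBond(frame_index, int(d), int(h), int(a)))
    bonds.sort(key=lambda b: (b.donor, b.acceptor, b.hydrogen))
    return bonds


def classify_hbonds(
    bonds: Sequence[HBond], topology: Topology
) -> list[HBond]:
    """Assign each bond exactly one class label (in place; returns bonds)."""
    strand_of = topology.atom_strand()
    species = topology.atom_species()
    names = topology.names()
    for b in bonds:
        sd, sa = strand_of[b.donor], strand_of[b.acceptor]
        if sd >= 0 and sa >= 0:
            if sd == sa:
                pair = (names[b.acceptor], names[b.donor])
                b.bond_class = "intra_primary" if pair in PRIMARY_PAIRS else "intra_other"
            else:
                b.bond_class = "inter_strand"
        elif sd < 0 and sa < 0:
            b.bond_class = "solvent_solvent"
        else:
            solvent_atom = b.donor if sd < 0 else b.acceptor
            b.bond_class = f"{species[solvent_atom]}_strand"
    return bonds


def per_glycan_class_average(
    bonds_per_frame: Sequence[Sequence[HBond]],
    times_ps: Sequence[float],
    topology: Topology,
    class_map: StrandClassMap,
    window_ns: tuple[float, float],
) -> pd.DataFrame:
    """Average bonds per glycan by strand class over a time window.

    Primary intra-strand bonds are normalized by g-1 glycans per strand (the
    last glycan has no junction partner); inter-strand and solvent classes
    by g.  Inter-strand bonds count once for each participating strand.
    Returns a strand-class x bond-class table.
    """
    t0, t1 = (1000.0 * window_ns[0], 1000.0 * window_ns[1])
    sel = [k for k, t in enumerate(times_ps) if t0 <= t <= t1]
    if not sel:
        raise ValueError(
            f"window {window_ns} ns contains no frames "
            f"(trajectory spans {min(times_ps) / 1e3}-{max(times_ps) / 1e3} ns)"
        )
    g = topology.n_glycans_per_strand
    strand_of = topology.atom_strand()
    cols = ["intra_primary", "inter_strand", "Cl_strand", "TBP_strand", "water_strand"]
    counts = np.zeros((topology.n_strands, len(cols)))
    for k in sel:
        for b in bonds_per_frame[k]:
            if b.bond_class is None:
                raise ValueError("bonds must be classified first")
            if b.bond_class == "intra_primary":
                counts[strand_of[b.donor], 0] += 1
            elif b.bond_class == "inter_strand":
                counts[strand_of[b.donor], 1] += 1
                counts[strand_of[b.acceptor], 1] += 1
            elif b.bond_class in ("Cl_strand", "TBP_strand", "water_strand"):
                s = strand_of[b.donor] if strand_of[b.donor] >= 0 else strand_of[b.acceptor]
                counts[s, cols.index(b.bond_class)] += 1
    counts /= len(sel)
    norm = np.array([g - 1, g, g, g, g], dtype=float)
    per_glycan = counts / norm
    classes = sorted(set(class_map.classes.values()))
    rows = {}
    for cls in classes:
        idx = class_map.strands_of(cls)
        rows[cls] = per_glycan[idx].mean(axis=0)
    return pd.DataFrame(rows, index=cols).T


def solvent_proximity_count(
    frame: Frame,
    topology: Topology,
    target: Sequence[int],
    cutoff: float = 3.5,
    species: str = "water",
) -> int:
    """Count solvent molecules of a species with any atom within ``cutoff``
    of any target atom (minimum image)."""
    target = np.asarray(target, dtype=int)
    if target.size == 0:
        raise ValueError("target atom set is empty")
    box = frame.box
    tree = cKDTree(np.mod(frame.coords[target], box), boxsize=box)
    count = 0
    for sp, idx in topology.solvent_molecules:
        if sp != species:
            continue
        near = tree.query_ball_point(
            np.mod(frame.coords[idx], box), cutoff, return_length=True
        )
        if np.sum(near) > 0:
            count += 1
    return count


def pocket_census(
    trajectory: Trajectory,
    strand_a: int,
    strand_b: int,
    cutoff: float = 3.5,
    window_ns: Optional[tuple[float, float]] = None,
) -> tuple[pd.DataFrame, str]:
    """Per-frame count of TBP and water molecules in the pocket between two
    strands, and the cation:water exchange ratio.

    A molecule is in the pocket when it has atoms within ``cutoff`` of BOTH
    strands.  The ratio is the time-averaged n_TBP : n_water, rounded to one
    decimal and reduced to the smallest integer ratio ("-" when empty).
    """
    if strand_a == strand_b:
        raise ValueError("pocket strands must be distinct")
    topo = trajectory.topology
    ia = topo.strand_atoms(strand_a)
    ib = topo.strand_atoms(strand_b)
    rows = []
    for k, frame in enumerate(trajectory.frames):
        if window_ns is not None:
            t_ns = frame.time / 1000.0
            if not (window_ns[0] <= t_ns <= window_ns[1]):
                continue
        box = frame.box
        tree_a = cKDTree(np.mod(frame.coords[ia], box), boxsize=box)
        tree_b = cKDTree(np.mod(frame.coords[ib], box), boxsize=box)
        n = {"TBP": 0, "water": 0}
        for sp, idx in topo.solvent_molecules:
            if sp not in n:
                continue
            pts = np.mod(frame.coords[idx], box)
            if (
                np.sum(tree_a.query_ball_point(pts, cutoff, return_length=True)) > 0
                and np.sum(tree_b.query_ball_point(pts, cutoff, return_length=True)) > 0
            ):
                n[sp] += 1
        rows.append({"time_ps": frame.time, "n_TBP": n["TBP"], "n_water": n["water"]})
    table = pd.DataFrame(rows)
    if len(table) == 0:
        return table, "-"
    a = round(float(table["n_TBP"].mean()), 1)
    b = round(float(table["n_water"].mean()), 1)
    if a == 0 and b == 0:
        return table, "-"
    ai, bi = int(round(a * 10)), int(round(b * 10))
    g = np.gcd(ai, bi) if min(ai, bi) > 0 else max(ai, bi)
    return table, f"{ai // g}:{bi // g}"
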