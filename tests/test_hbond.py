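"""Hydrogen-bond detection against geometry examples and a brute-force oracle."""

import numpy as np
import pytest

from cellsolv.core import AtomRecord, Frame, Topology, Trajectory, minimum_image_distance
from cellsolv.hbond import (
    HBondCriteria,
    classify_hbonds,
    detect_hbonds,
    per_glycan_class_average,
    pocket_census,
    solvent_proximity_count,
)
from cellsolv.synthetic import classify_strands


def water_box(n_waters, box, rng):
    """Random rigid waters; returns (topology, frame)."""
    atoms, solvent, coords, bonds = [], [], [], []
    for m in range(n_waters):
        base = 3 * m
        atoms += [
            AtomRecord(base + 1, "Ow", "O", 15.999),
            AtomRecord(base + 2, "Hw", "H", 1.008),
            AtomRecord(base + 3, "Hw", "H", 1.008),
        ]
        solvent.append(("water", [base, base + 1, base + 2]))
        bonds += [(base, base + 1), (base, base + 2)]
        pos = rng.uniform(0, 1, 3) * box
        # random orientation
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        v = rng.normal(size=3)
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        coords += [pos, pos + 0.96 * u, pos + 0.96 * (-0.25 * u + 0.97 * v)]
    topo = Topology(atoms=atoms, strands=[], solvent_molecules=solvent, bonds=bonds)
    return topo, Frame(0.0, box, np.array(coords))


def oracle_detect(frame, topology, criteria):
    """Independent all-pairs O(N^2) detector (no neighbor lists)."""
    found = set()
    donors = topology.bonded_hydrogens()
    box = frame.box
    for d, hlist in donors.items():
        if topology.atoms[d].element != "O":
            continue
        for h in hlist:
            for a, rec in enumerate(topology.atoms):
                if rec.element not in ("O", "Cl") or a in (d, h):
                    continue
                if minimum_image_distance(frame.coords[h], frame.coords[a], box) > criteria.d_ha_max:
                    continue
                d_da = minimum_image_distance(frame.coords[d], frame.coords[a], box)
                if d_da > criteria.d_da_max:
                    continue
                from cellsolv.core import minimum_image_displacement
                v1 = minimum_image_displacement(frame.coords[d], frame.coords[h], box)
                v2 = minimum_image_displacement(frame.coords[d], frame.coords[a], box)
                ang = np.degrees(
                    np.arccos(np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))
                )
                if ang <= criteria.angle_max:
                    found.add((d, h, a))
    return found


def simple_pair(d_ha=1.8, angle_deg=0.0, d_dh=0.97):
    """O-H donor plus one acceptor O at controlled geometry."""
    atoms = [
        AtomRecord(1, "Ow", "O", 15.999),
        AtomRecord(2, "Hw", "H", 1.008),
        AtomRecord(3, "Hw", "H", 1.008),
        AtomRecord(4, "Ow", "O", 15.999),
        AtomRecord(5, "Hw", "H", 1.008),
        AtomRecord(6, "Hw", "H", 1.008),
    ]
    topo = Topology(
        atoms=atoms,
        solvent_molecules=[("water", [0, 1, 2]), ("water", [3, 4, 5])],
        bonds=[(0, 1), (0, 2), (3, 4), (3, 5)],
    )
    # donor at origin, H along +x; acceptor at angle from the D->H direction
    theta = np.radians(angle_deg)
    r_da = d_dh + d_ha  # collinear beyond H when angle=0
    acc = np.array([r_da * np.cos(theta), r_da * np.sin(theta), 0.0])
    coords = np.array(
        [
            [0, 0, 0], [d_dh, 0, 0], [-0.3, 0.9, 0],
            acc, acc + [0.6, 0.8, 0], acc + [0.6, -0.8, 0],
        ]
    )
    return topo, Frame(0.0, [50, 50, 50], coords)


class TestCriteriaGeometry:
    def test_ideal_linear_bond(self):
        topo, frame = simple_pair(d_ha=1.8, angle_deg=0.0)
        bonds = detect_hbonds(frame, topo)
        assert [(b.donor, b.hydrogen, b.acceptor) for b in bonds] == [(0, 1, 3)]

    def test_ha_distance_cut(self):
        topo, frame = simple_pair(d_ha=2.50, angle_deg=0.0)
        assert detect_hbonds(frame, topo) == []
        topo, frame = simple_pair(d_ha=2.44, angle_deg=0.0)
        assert len(detect_hbonds(frame, topo)) == 1

    def test_angle_cut(self):
        topo, frame = simple_pair(d_ha=1.3, angle_deg=31.0)
        assert detect_hbonds(frame, topo) == []
        topo, frame = simple_pair(d_ha=1.3, angle_deg=29.0)
        assert len(detect_hbonds(frame, topo)) == 1

    def test_da_distance_bound_consistency(self):
        """Grid search over admissible geometries (d_HA <= 2.45 Å, donor
        angle <= 30°, d_DH = 1.0 Å): the D-A distance never exceeds 3.5 Å —
        the three thresholds are mutually consistent."""
        d_dh = 1.0
        worst = 0.0
        for theta in np.linspace(0, np.radians(30.0), 200):
            for d_ha in np.linspace(0.0, 2.45, 200):
                # law of cosines: furthest acceptor at donor angle theta
                disc = d_ha**2 - (d_dh * np.sin(theta)) ** 2
                if disc < 0:
                    continue
                r_da = d_dh * np.cos(theta) + np.sqrt(disc)
                worst = max(worst, r_da)
        assert worst <= 3.5
        # the extreme geometry is the collinear one: d_DH + d_HA = 3.45 Å
        assert worst == pytest.approx(1.0 + 2.45, abs=1e-6)

    def test_detector_matches_brute_force_oracle(self, rng):
        """Cell-list detection is identical to the all-pairs oracle on
        randomized boxes (including periodic wrap)."""
        criteria = HBondCriteria()
        for trial in range(30):
            n = int(rng.integers(5, 60))
            box = np.array([12.0, 14.0, 11.0])
            topo, frame = water_box(n, box, rng)
            got = {
                (b.donor, b.hydrogen, b.acceptor)
                for b in detect_hbonds(frame, topo, criteria)
            }
            assert got == oracle_detect(frame, topo, criteria)


class TestClassification:
    def test_primary_and_other_intra(self, bundle_2x2):
        topo, frame = bundle_2x2
        bonds = classify_hbonds(detect_hbonds(frame, topo), topo)
        names = topo.names()
        for b in bonds:
            assert b.bond_class is not None  # partition: every bond labeled
            if b.bond_class == "intra_primary":
                assert (names[b.acceptor], names[b.donor]) in {("O5", "O3"), ("O6", "O2")}

    def test_chloride_strand_bond(self, bundle_2x2):
        topo, frame = bundle_2x2
        from cellsolv.core import AtomRecord, Topology
        names = [a.name for a in topo.atoms] + ["Cl"]
        atoms = list(topo.atoms) + [AtomRecord(topo.n_atoms + 1, "Cl", "Cl", 35.453)]
        merged = Topology(
            atoms=atoms,
            strands=topo.strands,
            solvent_molecules=[("Cl", [topo.n_atoms])],
            bonds=topo.bonds,
        )
        # place Cl 1.9 A beyond a hydroxyl hydrogen, along the O-H axis
        ho2 = next(i for i, n in enumerate(names[:-1]) if n == "HO2")
        o2 = next(i for i, j in merged.bonds if j == ho2)
        u = frame.coords[ho2] - frame.coords[o2]
        u /= np.linalg.norm(u)
        cl_xyz = frame.coords[ho2] + 1.9 * u
        mframe = Frame(0.0, frame.box, np.vstack([frame.coords, cl_xyz]))
        bonds = classify_hbonds(detect_hbonds(mframe, merged), merged)
        cl_bonds = [b for b in bonds if b.bond_class == "Cl_strand"]
        assert any(
            merged.atoms[b.acceptor].name == "Cl" and merged.atoms[b.donor].name == "O2"
            for b in cl_bonds
        )

    def test_class_partition_sums(self, bundle_2x2):
        topo, frame = bundle_2x2
        bonds = classify_hbonds(detect_hbonds(frame, topo), topo)
        from collections import Counter
        counts = Counter(b.bond_class for b in bonds)
        assert sum(counts.values()) == len(bonds)


class TestPerGlycanAverage:
    def test_ideal_bundle_two_per_glycan(self, bundle_18x12):
        """Static ideal bundle: primary intra-strand bonds per glycan is
        exactly 2.0 for every strand class (the 'perfect' crystal value),
        on the 11-glycan basis for 12-glycan strands."""
        topo, frame = bundle_18x12
        bonds = classify_hbonds(detect_hbonds(frame, topo), topo)
        from cellsolv.synthetic import default_layout
        cmap = classify_strands(topo, default_layout(18))
        table = per_glycan_class_average([bonds], [0.0], topo, cmap, (0.0, 0.001))
        assert np.allclose(table["intra_primary"].to_numpy(), 2.0)
        assert topo.n_glycans_per_strand - 1 == 11

    def test_empty_window_raises(self, bundle_2x2):
        topo, frame = bundle_2x2
        with pytest.raises(ValueError, match="window"):
            per_glycan_class_average(
                [[]], [0.0], topo,
                classify_strands(4, [(0, 0), (0, 1), (1, 0), (1, 1)]),
                (5.0, 6.0),
            )

    def test_no_bonds_gives_zero_table(self, bundle_2x2):
        topo, _ = bundle_2x2
        cmap = classify_strands(4, [(0, 0), (0, 1), (1, 0), (1, 1)])
        table = per_glycan_class_average([[]], [0.0], topo, cmap, (0.0, 0.1))
        assert float(table.to_numpy().sum()) == 0.0


class TestProximity:
    def test_cutoff_boundary(self, rng):
        box = np.array([30.0, 30.0, 30.0])
        topo, frame = water_box(2, box, rng)
        target = np.array([[5.0, 5.0, 5.0]])
        for dist, expected in ((3.4, 1), (3.6, 0)):
            coords = frame.coords.copy()
            coords[0] = target[0] + [dist, 0, 0]
            # hydrogens point away from the target so only the oxygen's
            # distance decides the count
            coords[1] = coords[0] + [0.96, 0, 0]
            coords[2] = coords[0] + [0.24, 0.93, 0]
            coords[3:] = 20.0
            f = Frame(0.0, box, coords)
            tframe = Frame(0.0, box, np.vstack([coords, target]))
            from cellsolv.core import AtomRecord, Topology
            atoms = list(topo.atoms) + [AtomRecord(7, "C1", "C", 12.011)]
            merged = Topology(
                atoms=atoms,
                strands=[],
                solvent_molecules=topo.solvent_molecules + [("Cl", [6])],
                bonds=topo.bonds,
            )
            n = solvent_proximity_count(tframe, merged, [6], cutoff=3.5, species="water")
            assert n == expected

    def test_matches_brute_force(self, rng):
        box = np.array([15.0, 15.0, 15.0])
        for _ in range(20):
            topo, frame = water_box(25, box, rng)
            target = [0, 1, 2]  # first water is the target set
            got = solvent_proximity_count(frame, topo, target, 3.5, "water")
            expected = 0
            for sp, idx in topo.solvent_molecules:
                if idx == target:
                    near = True  # the target water trivially touches itself
                else:
                    near = any(
                        minimum_image_distance(frame.coords[i], frame.coords[t], box) <= 3.5
                        for i in idx
                        for t in target
                    )
                if near:
                    expected += 1
            assert got == expected


class TestPocketCensus:
    def make_pocket_system(self, n_tbp, n_water):
        """Plant molecules exactly between two 2-glycan strands."""
        from cellsolv.synthetic import BundleSpec, build_ibeta_bundle, TBP_TEMPLATE
        from cellsolv.io import TBP_ATOM_NAMES
        from cellsolv.core import AtomRecord, Topology
        topo, frame = build_ibeta_bundle(BundleSpec(2, 2, layout=[(0, 0), (0, 1)]))
        mid = frame.coords[topo.strand_atoms(0)].mean(axis=0) * 0.5 + \
            frame.coords[topo.strand_atoms(1)].mean(axis=0) * 0.5
        names = [a.name for a in topo.atoms]
        solvent, coords = [], [frame.coords]
        idx = topo.n_atoms
        for m in range(n_tbp):
            solvent.append(("TBP", list(range(idx, idx + 53))))
            coords.append(TBP_TEMPLATE * 0.45 + mid + [0, 0, 2.5 * m])
            names += list(TBP_ATOM_NAMES)
            idx += 53
        for m in range(n_water):
            solvent.append(("water", [idx, idx + 1, idx + 2]))
            base = mid + [0.0, 0.5, -2.0 - 1.5 * m]
            coords.append(np.array([base, base + [0.96, 0, 0], base + [-0.24, 0.93, 0]]))
            names += ["Ow", "Hw", "Hw"]
            idx += 3
        atoms = [AtomRecord(k + 1, n, "O" if n.startswith("O") else n[0], 15.0)
                 for k, n in enumerate(names)]
        merged = Topology(atoms=atoms, strands=topo.strands,
                          solvent_molecules=solvent, bonds=[])
        mframe = Frame(0.0, frame.box, np.vstack(coords))
        return Trajectory(topology=merged, frames=[mframe], dt=10.0)

    def test_three_to_one(self):
        traj = self.make_pocket_system(3, 1)
        table, ratio = pocket_census(traj, 0, 1, cutoff=6.0)
        assert ratio == "3:1"
        assert table.iloc[0]["n_TBP"] == 3 and table.iloc[0]["n_water"] == 1

    def test_one_to_two(self):
        traj = self.make_pocket_system(1, 2)
        _, ratio = pocket_census(traj, 0, 1, cutoff=6.0)
        assert ratio == "1:2"

    def test_empty_pocket(self):
        traj = self.make_pocket_system(0, 0)
        table, ratio = pocket_census(traj, 0, 1, cutoff=3.5)
        assert ratio == "-"
        assert table.iloc[0]["n_TBP"] == 0 and table.iloc[0]["n_water"] == 0

    def test_identical_strands_rejected(self):
        traj = self.make_pocket_system(0, 0)
        with pytest.raises(ValueError):
            pocket_census(traj, 1, 1)
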