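"""End-to-end orchestration: build, solvate, peel, analyze, report.

A run is described by a ``RunConfig`` (YAML on disk).  ``run_pipeline``
executes the stages in order, writes CSV tables plus a JSON summary with
per-stage provenance (package version, config hash), and is deterministic
given the seeds.  ``make_demo`` fabricates a complete miniature study: an
18-strand bundle in a down-scaled 63.1 mol %-water solvent box, a planted
peeling strand, a pure-bundle control for threshold calibration, and a
ready-to-run config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, composition, conformation, dissolution, energy, hbond, io, lifetime, synthetic

logger = logging.getLogger("cellsolv")

__all__ = ["RunConfig", "run_pipeline", "make_demo"]


@dataclass
class RunConfig:
    outdir: str = "cellsolv_out"
    seed: int = 0
    topology_pdb: str = ""          # solvated system (topology + coordinates)
    trajectory: str = ""            # analysis trajectory (xyz)
    control_trajectory: str = ""    # control trajectory for calibration (xyz)
    forcefield: str = ""            # nonbonded parameter file ('' = builtin)
    peel_strand: int = 1
    # hydrogen-bond criteria
    d_ha_max: float = 2.45
    angle_max: float = 30.0
    d_da_max: float = 3.5
    # averaging window for per-glycan tables, ns
    window_ns: tuple[float, float] = (0.0, 1.0)
    # threshold calibration
    control_timepoints_ns: list[float] = field(default_factory=lambda: [0.01, 0.08, 0.16, 0.24])
    threshold_k: float = 4.0
    # energy
    energy_cutoff: float = 20.0
    # lifetime pairs evaluated at the trajectory resolution
    lifetime_pairs: list[str] = field(default_factory=lambda: ["O5:HO3-O3", "O6:HO2-O2"])
    # presentation smoothing (window, stride); scaled to short runs
    rolling: tuple[int, int] = (5, 1)
    stages: list[str] = field(
        default_factory=lambda: ["hbonds", "lifetimes", "dissolution", "twist", "energy"]
    )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.window_ns = tuple(cfg.window_ns)
        cfg.rolling = tuple(cfg.rolling)
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._as_plain(), fh, sort_keys=True)

    def _as_plain(self) -> dict:
        d = asdict(self)
        d["window_ns"] = list(self.window_ns)
        d["rolling"] = list(self.rolling)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self._as_plain(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def validate(self) -> None:
        for name in ("topology_pdb", "trajectory"):
            path = getattr(self, name)
            if not path or not os.path.exists(path):
                raise FileNotFoundError(f"config.{name}: missing input file {path!r}")
        if "dissolution" in self.stages and not os.path.exists(self.control_trajectory):
            raise FileNotFoundError(
                f"dissolution stage needs control_trajectory, got "
                f"{self.control_trajectory!r}"
            )
        if "energy" in self.stages and self.forcefield and not os.path.exists(self.forcefield):
            raise FileNotFoundError(
                f"energy stage: force-field file {self.forcefield!r} not found"
            )


def _setup_logging(outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    handlers = [logging.StreamHandler()]
    handlers.append(logging.FileHandler(os.path.join(outdir, "run.log"), mode="w"))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns (and writes) the JSON summary."""
    config.validate()
    _setup_logging(config.outdir)
    out = config.outdir
    summary: dict = {
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    criteria = hbond.HBondCriteria(config.d_ha_max, config.angle_max, config.d_da_max)

    topology, frame0 = io.read_structure(config.topology_pdb)
    traj = io.read_trajectory(config.trajectory, "xyz", topology)
    logger.info(
        "loaded %d atoms, %d strands, %d frames",
        topology.n_atoms, topology.n_strands, len(traj),
    )
    layout = synthetic.default_layout(topology.n_strands)
    class_map = synthetic.classify_strands(topology, layout)

    def stage(name):
        return name in config.stages

    try:
        if stage("hbonds"):
            bonds_per_frame = [
                hbond.classify_hbonds(
                    hbond.detect_hbonds(f, topology, criteria, frame_index=k),
                    topology,
                )
                for k, f in enumerate(traj.frames)
            ]
            table = hbond.per_glycan_class_average(
                bonds_per_frame, traj.times(), topology, class_map, config.window_ns
            )
            table.to_csv(os.path.join(out, "hbonds_per_glycan.csv"))
            rows = [
                {
                    "frame": b.frame_index,
                    "donor": b.donor + 1,
                    "hydrogen": b.hydrogen + 1,
                    "acceptor": b.acceptor + 1,
                    "class": b.bond_class,
                }
                for bonds in bonds_per_frame
                for b in bonds
            ]
            pd.DataFrame(rows).to_csv(os.path.join(out, "hbonds_list.csv"), index=False)
            summary["stages"]["hbonds"] = {
                "n_bonds_mean": float(np.mean([len(b) for b in bonds_per_frame])),
                "per_glycan_table": "hbonds_per_glycan.csv",
            }
            logger.info("hbonds: %.1f bonds/frame", summary["stages"]["hbonds"]["n_bonds_mean"])

        if stage("lifetimes"):
            rows = []
            for pair in config.lifetime_pairs:
                series = lifetime.existence_matrix(traj, pair, criteria)
                if not series:
                    rows.append({"pair": pair, "tau_ps": np.nan, "censored": "", "n_series": 0})
                    continue
                try:
                    res = lifetime.sample_average(series)
                except ValueError:  # short run: single full-window estimate
                    res = lifetime.lifetime_from_acf(
                        lifetime.autocorrelation(series), series[0].dt
                    )
                rows.append(
                    {
                        "pair": pair,
                        "tau_ps": res.tau,
                        "censored": res.censored,
                        "rendered": res.render(),
                        "n_series": len(series),
                    }
                )
            pd.DataFrame(rows).to_csv(os.path.join(out, "lifetimes.csv"), index=False)
            summary["stages"]["lifetimes"] = {
                r["pair"]: r.get("rendered", "NA") for r in rows
            }
            logger.info("lifetimes: %s", summary["stages"]["lifetimes"])

        if stage("dissolution"):
            control = io.read_trajectory(config.control_trajectory, "xyz", topology)
            cal = dissolution.calibrate_threshold(
                control, config.control_timepoints_ns, k=config.threshold_k
            )
            report = dissolution.analyze_dissolution(traj, cal.threshold)
            pd.DataFrame(
                {
                    "time_ns": report.times_ns,
                    "wt_percent": report.wt_percent,
                    "n_dissolved": report.n_dissolved,
                }
            ).to_csv(os.path.join(out, "dissolution_wt.csv"), index=False)
            pd.DataFrame(
                report.max_nn,
                index=report.times_ns,
                columns=[f"glycan_{j + 1}" for j in range(report.max_nn.shape[1])],
            ).to_csv(os.path.join(out, "max_nn_profile.csv"))
            summary["stages"]["dissolution"] = {
                "threshold_A": cal.threshold,
                "control_mean_A": cal.mean,
                "control_std_A": cal.std,
                "rate_wt_percent_per_ns": report.rate,
                "final_n_dissolved": int(report.n_dissolved[-1]),
            }
            logger.info("dissolution: threshold %.2f Å, rate %s", cal.threshold, report.rate)

        if stage("twist"):
            profile = conformation.twist_profile(traj, config.peel_strand)
            profile.to_frame().to_csv(os.path.join(out, "twist_profile.csv"), index=False)
            summary["stages"]["twist"] = {
                "strand": config.peel_strand,
                "angle_span_deg": float(np.ptp(profile.angles)),
            }

        if stage("energy"):
            params = (
                energy.load_forcefield(config.forcefield)
                if config.forcefield
                else energy.default_forcefield()
            )
            trace = energy.energy_trace(
                traj, params, config.peel_strand, cutoff=config.energy_cutoff
            )
            trace.to_csv(os.path.join(out, "energy_trace.csv"), index=False)
            window, stride = config.rolling
            smooth = energy.energy_trace(
                traj, params, config.peel_strand,
                cutoff=config.energy_cutoff, rolling=(window, stride),
            )
            smooth.to_csv(os.path.join(out, "energy_trace_smoothed.csv"))
            summary["stages"]["energy"] = {
                grp: float(trace[f"{grp}_total"].mean())
                for grp in ("Cl", "TBP", "water", "bundle_minus_strand")
                if f"{grp}_total" in trace
            }
            logger.info("energy means: %s", summary["stages"]["energy"])
    except Exception as exc:
        logger.error("stage failed: %s", exc)
        with open(os.path.join(out, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        raise

    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    logger.info("run complete: %s", os.path.join(out, "summary.json"))
    return summary


def make_demo(
    outdir: str,
    seed: int = 0,
    n_strands: int = 18,
    n_glycans: int = 12,
    n_tbpcl: int = 65,
    n_water: int = 111,
    n_frames: int = 60,
    dt_ps: float = 10.0,
) -> RunConfig:
    """Fabricate a miniature end-to-end study and its config.

    The solvent box holds 65 TBPCl ion pairs and 111 waters — the 63.1
    mol %-water solvent ratio at a desk-top scale.  One first-layer strand
    is planted to peel by 14 Å with thermal jitter; a jitter-only control
    provides the threshold calibration.  Ground truth (peeled strand,
    schedules, seeds) goes to ``ground_truth.json``.
    """
    os.makedirs(outdir, exist_ok=True)
    rng_seed = int(seed) % (2**31)
    spec = synthetic.BundleSpec(n_strands=n_strands, n_glycans_per_strand=n_glycans)
    bundle_topo, bundle_frame = synthetic.build_ibeta_bundle(spec)
    class_map = synthetic.classify_strands(bundle_topo, spec.layout)
    first_layer = class_map.strands_of("first_layer") or class_map.strands_of("corner")
    peel_strand = first_layer[0]

    displacement = np.linspace(0.0, 14.0, n_frames)
    plan = synthetic.PeelPlan(
        strands=[peel_strand],
        displacement={peel_strand: displacement},
        twist={peel_strand: np.linspace(0.0, 5.0, n_frames)},
        noise_sigma=0.15,
        seed=rng_seed + 1,
    )

    topology, frame = synthetic.pack_solvent(
        (bundle_topo, bundle_frame), n_tbpcl=n_tbpcl, n_water=n_water,
        box=bundle_frame.box, seed=rng_seed,
    )
    # carve the peel corridor: drop solvent molecules the planted strand
    # will sweep through (a real solvent would be pushed aside; the
    # kinematic surrogate cannot do that)
    noiseless = synthetic.PeelPlan(
        strands=[peel_strand],
        displacement={peel_strand: displacement},
        twist={peel_strand: np.linspace(0.0, 5.0, n_frames)},
        noise_sigma=0.0,
        seed=rng_seed + 1,
    )
    sweep_traj = synthetic.generate_peeling_trajectory(
        bundle_topo, bundle_frame, noiseless, n_frames, dt_ps
    )
    strand_idx = bundle_topo.strand_atoms(peel_strand)
    swept = np.concatenate([f.coords[strand_idx] for f in sweep_traj.frames])
    from scipy.spatial import cKDTree

    tree = cKDTree(np.mod(swept, frame.box), boxsize=frame.box)
    keep_atom = np.ones(topology.n_atoms, dtype=bool)
    kept_mols = []
    for species, idx in topology.solvent_molecules:
        near = tree.query_ball_point(
            np.mod(frame.coords[idx], frame.box), 2.5, return_length=True
        )
        if np.sum(near) > 0:
            keep_atom[idx] = False
        else:
            kept_mols.append((species, idx))
    if len(kept_mols) < len(topology.solvent_molecules):
        old_to_new = np.cumsum(keep_atom) - 1
        names = [a.name for a in topology.atoms]
        new_names = [n for n, kp in zip(names, keep_atom) if kp]
        new_strands = [
            [[int(old_to_new[i]) for i in glycan] for glycan in strand]
            for strand in topology.strands
        ]
        new_solvent = [
            (sp, [int(old_to_new[i]) for i in idx]) for sp, idx in kept_mols
        ]
        from .core import AtomRecord, Frame as _Frame, element_from_name, mass_of_element
        atoms = [
            AtomRecord(k + 1, n, element_from_name(n),
                       mass_of_element(element_from_name(n)))
            for k, n in enumerate(new_names)
        ]
        topology = type(topology)(
            atoms=atoms, strands=new_strands, solvent_molecules=new_solvent,
            bonds=io.build_residue_bonds(new_strands, new_solvent, new_names),
        )
        frame = _Frame(time=frame.time, box=frame.box, coords=frame.coords[keep_atom])

    top_pdb = os.path.join(outdir, "system.pdb")
    io.write_structure(top_pdb, topology, frame)

    traj = synthetic.generate_peeling_trajectory(topology, frame, plan, n_frames, dt_ps)
    traj_path = os.path.join(outdir, "peel.xyz")
    io.write_trajectory(traj_path, traj, "xyz")

    control_plan = synthetic.PeelPlan(strands=[], noise_sigma=0.15, seed=rng_seed + 2)
    n_control = 25
    control = synthetic.generate_peeling_trajectory(
        topology, frame, control_plan, n_control, dt_ps
    )
    control_path = os.path.join(outdir, "control.xyz")
    io.write_trajectory(control_path, control, "xyz")

    ff_path = os.path.join(outdir, "forcefield.txt")
    energy.write_forcefield(ff_path, energy.default_forcefield())

    mol_pct = composition.mol_percent_water(n_water, n_tbpcl)
    truth = {
        "seed": rng_seed,
        "peel_strand": peel_strand,
        "displacement_final_A": float(displacement[-1]),
        "twist_final_deg_per_junction": 5.0,
        "noise_sigma_A": 0.15,
        "mol_percent_water": round(mol_pct, 1),
        "n_tbpcl": n_tbpcl,
        "n_water": n_water,
    }
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)

    t_end_ns = (n_control - 1) * dt_ps / 1000.0
    config = RunConfig(
        outdir=os.path.join(outdir, "results"),
        seed=rng_seed,
        topology_pdb=top_pdb,
        trajectory=traj_path,
        control_trajectory=control_path,
        forcefield=ff_path,
        peel_strand=peel_strand,
        window_ns=(0.0, (n_frames - 1) * dt_ps / 1000.0),
        control_timepoints_ns=[
            round(f * t_end_ns, 4) for f in (0.05, 0.35, 0.65, 1.0)
        ],
    )
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    return config
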