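"""Strand-separation and dissolution statistics.

For every glycan j of every strand s the nearest-neighbor (NN) distance is
the minimum, over all other strands s', of the minimum-image distance
between the centers of mass of the *same-numbered* glycans:

    NN(s, j) = min_{s' != s}  | COM(s, j) - COM(s', j) |,

and maxNN(j) = max_s NN(s, j) profiles the furthest strand separation at
each position along the bundle.

A glycan counts as dissolved when its NN distance exceeds a threshold
calibrated on a control (pure-water) trajectory: pooled maxNN values at a
set of control timepoints give a mean and standard deviation, and the
threshold is mean + k*sigma with k = 4 — a separation statistically
incompatible with an intact bundle.  Dissolved glycans convert to a weight
percent through the anhydroglucose residue mass, and the dissolution rate
is the ordinary-least-squares slope of wt % against time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import composition
from .core import Frame, Topology, Trajectory, minimum_image_displacement

__all__ = [
    "GlycanNNProfile",
    "ThresholdCalibration",
    "DissolutionReport",
    "glycan_com",
    "matched_nn_profile",
    "calibrate_threshold",
    "calibrate_threshold_from_pool",
    "flag_dissolved",
    "analyze_dissolution",
    "dissolved_wt_percent",
    "dissolution_rate",
    "radius_of_gyration",
]


def glycan_com(frame: Frame, topology: Topology) -> np.ndarray:
    """Mass-weighted center of mass of every glycan, shape (n_strands, g, 3).

    Each glycan is unwrapped across the periodic boundary relative to its
    first atom, so a glycan straddling the box edge keeps a physical COM;
    strands are never unwrapped against each other.
    """
    masses = topology.masses()
    g = topology.n_glycans_per_strand
    out = np.empty((topology.n_strands, g, 3))
    for s, strand in enumerate(topology.strands):
        for j, glycan in enumerate(strand):
            idx = np.asarray(glycan, dtype=int)
            ref = frame.coords[idx[0]]
            rel = minimum_image_displacement(ref, frame.coords[idx], frame.box)
            m = masses[idx]
            out[s, j] = ref + (m[:, None] * rel).sum(axis=0) / m.sum()
    return out


@dataclass
class GlycanNNProfile:
    """Per-(strand, glycan) nearest-neighbor distances and the per-glycan
    maximum over strands."""

    nn: np.ndarray        # (n_strands, g)
    max_nn: np.ndarray    # (g,)
    neighbor: np.ndarray  # (n_strands, g) index of the nearest strand


def matched_nn_profile(coms: np.ndarray, box) -> GlycanNNProfile:
    """Nearest-neighbor profile over same-numbered glycan COMs; ties resolve
    to the lower strand index."""
    coms = np.asarray(coms)
    n_strands, g, _ = coms.shape
    if n_strands < 2:
        raise ValueError("nearest-neighbor profile requires at least 2 strands")
    nn = np.empty((n_strands, g))
    neighbor = np.empty((n_strands, g), dtype=int)
    for j in range(g):
        pts = coms[:, j]
        d = np.linalg.norm(
            minimum_image_displacement(pts[:, None], pts[None, :], box), axis=-1
        )
        np.fill_diagonal(d, np.inf)
        neighbor[:, j] = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
        nn[:, j] = d[np.arange(n_strands), neighbor[:, j]]
    return GlycanNNProfile(nn=nn, max_nn=nn.max(axis=0), neighbor=neighbor)


@dataclass
class ThresholdCalibration:
    """Control-trajectory statistics behind the dissolution threshold."""

    timepoints_ns: list[float]
    mean: float
    max: float
    std: float
    k: float
    threshold: float = field(init=False)

    def __post_init__(self):
        self.threshold = self.mean + self.k * self.std


def calibrate_threshold_from_pool(
    pool: Sequence[float], k: float = 4.0, timepoints_ns: Sequence[float] = ()
) -> ThresholdCalibration:
    """mean + k*sigma over a pool of maxNN control values (population sigma)."""
    pool = np.asarray(pool, dtype=float)
    if pool.size < 2:
        raise ValueError("threshold calibration needs at least 2 pooled values")
    return ThresholdCalibration(
        timepoints_ns=list(timepoints_ns),
        mean=float(pool.mean()),
        max=float(pool.max()),
        std=float(pool.std()),
        k=k,
    )


def calibrate_threshold(
    control: Trajectory, timepoints_ns: Sequence[float], k: float = 4.0
) -> ThresholdCalibration:
    """Pool maxNN(j) over all glycan numbers at the listed control
    timepoints (frames nearest each timepoint) and set mean + k*sigma."""
    times = control.times()
    pool = []
    for t_ns in timepoints_ns:
        t_ps = 1000.0 * t_ns
        if not (times.min() - control.dt <= t_ps <= times.max() + control.dt):
            raise ValueError(f"timepoint {t_ns} ns outside the control trajectory")
        kframe = int(np.argmin(np.abs(times - t_ps)))
        coms = glycan_com(control.frames[kframe], control.topology)
        profile = matched_nn_profile(coms, control.frames[kframe].box)
        pool.extend(profile.max_nn.tolist())
    return calibrate_threshold_from_pool(pool, k=k, timepoints_ns=timepoints_ns)


def flag_dissolved(profile: GlycanNNProfile, threshold: float) -> np.ndarray:
    """Dissolved flags per (strand, glycan): strictly NN > threshold (a
    glycan exactly at the threshold is not dissolved)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return profile.nn > threshold


def dissolved_wt_percent(
    flags: np.ndarray,
    topology: Topology,
    mass_model: composition.MassModel = composition.MassModel(),
) -> float:
    """Convert dissolved-glycan flags to wt % against the frame's solvent
    masses (summed per species from the topology)."""
    n_dissolved = int(np.sum(flags))
    m_dissolved = composition.dissolved_mass(n_dissolved, mass_model)
    masses = topology.masses()
    m_water = 0.0
    m_tbpcl = 0.0
    for species, idx in topology.solvent_molecules:
        m = float(masses[list(idx)].sum())
        if species == "water":
            m_water += m
        else:  # TBP and Cl together form the ionic liquid mass
            m_tbpcl += m
    if m_water + m_tbpcl == 0.0 and n_dissolved == 0:
        return 0.0
    return composition.wt_percent_dissolved(m_dissolved, m_water, m_tbpcl)


@dataclass
class DissolutionReport:
    """Per-frame dissolution summary for a trajectory."""

    times_ns: np.ndarray
    wt_percent: np.ndarray
    n_dissolved: np.ndarray
    flags: np.ndarray       # (n_frames, n_strands, g)
    max_nn: np.ndarray      # (n_frames, g)
    rate: Optional[float] = None
    rate_stderr: Optional[float] = None


def analyze_dissolution(
    trajectory: Trajectory,
    threshold: float,
    mass_model: composition.MassModel = composition.MassModel(),
) -> DissolutionReport:
    """Flag dissolved glycans in every frame and fit the dissolution rate."""
    topo = trajectory.topology
    all_flags, wt, nd, mx = [], [], [], []
    for frame in trajectory.frames:
        coms = glycan_com(frame, topo)
        profile = matched_nn_profile(coms, frame.box)
        flags = flag_dissolved(profile, threshold)
        all_flags.append(flags)
        nd.append(int(flags.sum()))
        wt.append(dissolved_wt_percent(flags, topo, mass_model))
        mx.append(profile.max_nn)
    times_ns = trajectory.times() / 1000.0
    report = DissolutionReport(
        times_ns=times_ns,
        wt_percent=np.asarray(wt),
        n_dissolved=np.asarray(nd),
        flags=np.asarray(all_flags),
        max_nn=np.asarray(mx),
    )
    if len(times_ns) >= 3 and np.ptp(times_ns) > 0:
        slope, _, stderr = dissolution_rate(times_ns, report.wt_percent)
        report.rate = slope
        report.rate_stderr = stderr
    return report


def dissolution_rate(
    times_ns: Sequence[float], wt_percent: Sequence[float]
) -> tuple[float, float, float]:
    """OLS slope of wt % against time: (slope wt%/ns, intercept, stderr)."""
    t = np.asarray(times_ns, dtype=float)
    y = np.asarray(wt_percent, dtype=float)
    if t.size < 3:
        raise ValueError("dissolution rate needs at least 3 points")
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis")
    fit = stats.linregress(t, y)
    return float(fit.slope), float(fit.intercept), float(fit.stderr)


def radius_of_gyration(
    frame: Frame, atom_indices: Sequence[int], topology: Topology
) -> float:
    """Mass-weighted RMS distance from the group's center of mass, Å."""
    idx = np.asarray(atom_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("atom set is empty")
    m = topology.masses()[idx]
    x = frame.coords[idx]
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((x - com) ** 2).sum(axis=1)).sum() / m.sum()))
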