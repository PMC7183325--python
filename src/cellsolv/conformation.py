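"""Glycosidic twist profiles and the rolling-average presentation transform.

Strand twisting is diagnosed by the signed torsion measured, in order, over
the O5-C1-O4-C4 atoms spanning each glycosidic junction (O5 and C1 from
glycan j, O4 and C4 from glycan j+1).  Junction angles are reported at the
average glycan number j + 0.5.  Time traces across the package are smoothed
with a centered 1000-point rolling mean and decimated to every 100th point
for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Frame, Topology, TopologyError, Trajectory

__all__ = ["TwistProfile", "dihedral", "twist_profile", "rolling_average"]


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees, IUPAC convention) about the p2-p3 axis.

    Returns values in (-180, 180]; raises on collinear triples.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p2 - p1
    b1 = p3 - p2
    b2 = p4 - p3
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("undefined dihedral: collinear atom triple")
    y = np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else float(ang)


@dataclass
class TwistProfile:
    """Per-junction dihedral time series for one strand; junction labels are
    the average glycan number (the junction between glycans 1 and 2 is 1.5)."""

    strand: int
    labels: np.ndarray      # (g-1,) junction labels j + 0.5
    times_ps: np.ndarray    # (n_frames,)
    angles: np.ndarray      # (n_frames, g-1) degrees

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, t in enumerate(self.times_ps):
            for lab, ang in zip(self.labels, self.angles[k]):
                rows.append({"time_ps": t, "junction": lab, "angle_deg": ang})
        return pd.DataFrame(rows)


def _junction_quads(topology: Topology, strand: int) -> list[tuple[int, int, int, int]]:
    quads = []
    names = topology.names()
    glycans = topology.strands[strand]
    if len(glycans) < 2:
        raise ValueError("twist profile requires a strand with >= 2 glycans")

    def pick(glycan, name):
        for i in glycan:
            if names[i] == name:
                return i
        raise TopologyError(
            f"strand {strand}: atom {name!r} missing from a glycan"
        )

    for j in range(len(glycans) - 1):
        quads.append(
            (
                pick(glycans[j], "O5"),
                pick(glycans[j], "C1"),
                pick(glycans[j + 1], "O4"),
                pick(glycans[j + 1], "C4"),
            )
        )
    return quads


def twist_profile(trajectory: Trajectory, strand: int) -> TwistProfile:
    """O5-C1-O4-C4 torsion at every glycosidic junction of one strand,
    for every frame."""
    quads = _junction_quads(trajectory.topology, strand)
    g = len(trajectory.topology.strands[strand])
    angles = np.empty((len(trajectory.frames), g - 1))
    for k, frame in enumerate(trajectory.frames):
        for q, (a1, a2, a3, a4) in enumerate(quads):
            angles[k, q] = dihedral(
                frame.coords[a1], frame.coords[a2],
                frame.coords[a3], frame.coords[a4],
            )
    labels = np.arange(1, g) + 0.5
    return TwistProfile(
        strand=strand, labels=labels, times_ps=trajectory.times(), angles=angles
    )


def rolling_average(
    series, window: int = 1000, stride: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving mean with truncated edge windows, then every
    ``stride``-th point; returns (indices, values)."""
    y = np.asarray(series, dtype=float)
    if y.size == 0:
        raise ValueError("empty series")
    if window < 1:
        raise ValueError("window must be >= 1")
    smooth = (
        pd.Series(y).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    idx = np.arange(0, y.size, stride)
    return idx, smooth[idx]
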