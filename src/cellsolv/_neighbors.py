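"""Periodic neighbor search shared by the hydrogen-bond and energy stages.

Uses a grid-backed k-d tree (scipy ``cKDTree`` with ``boxsize``) when the
cutoff fits inside half the smallest box edge — the periodic k-d tree
requirement — and falls back to exact minimum-image enumeration otherwise.
Both paths return identical pair sets; the tree is purely an acceleration.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .core import minimum_image_displacement

__all__ = ["pairs_within", "cross_pairs_within"]


def _wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    w = np.mod(coords, box)
    # guard against w == box from floating-point round-off
    w[w >= box] = 0.0
    return w


def pairs_within(coords: np.ndarray, box, cutoff: float):
    """All unordered pairs (i < j) within minimum-image ``cutoff``.

    Returns (i, j, d) index and distance arrays, ordered by (i, j).
    """
    coords = np.asarray(coords, dtype=float)
    box = np.asarray(box, dtype=float)
    n = len(coords)
    if n < 2:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))
    if cutoff < 0.5 * box.min():
        tree = cKDTree(_wrap(coords, box), boxsize=box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return (np.empty(0, int), np.empty(0, int), np.empty(0))
        i = np.minimum(pairs[:, 0], pairs[:, 1])
        j = np.maximum(pairs[:, 0], pairs[:, 1])
    else:
        ii, jj = np.triu_indices(n, k=1)
        d = np.linalg.norm(
            minimum_image_displacement(coords[ii], coords[jj], box), axis=-1
        )
        keep = d <= cutoff
        i, j = ii[keep], jj[keep]
    d = np.linalg.norm(
        minimum_image_displacement(coords[i], coords[j], box), axis=-1
    )
    keep = d <= cutoff
    i, j, d = i[keep], j[keep], d[keep]
    order = np.lexsort((j, i))
    return i[order], j[order], d[order]


def cross_pairs_within(coords_a: np.ndarray, coords_b: np.ndarray, box,
                       cutoff: float):
    """All pairs (ia, ib) between two coordinate sets within minimum-image
    ``cutoff``.  Returns (ia, ib, d), ordered by (ia, ib)."""
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    box = np.asarray(box, dtype=float)
    if len(coords_a) == 0 or len(coords_b) == 0:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))
    if cutoff < 0.5 * box.min():
        tree_a = cKDTree(_wrap(coords_a, box), boxsize=box)
        tree_b = cKDTree(_wrap(coords_b, box), boxsize=box)
        hits = tree_a.query_ball_tree(tree_b, cutoff)
        ia = np.array([i for i, hit in enumerate(hits) for _ in hit], dtype=int)
        ib = np.array([b for hit in hits for b in hit], dtype=int)
    else:
        ia, ib = np.meshgrid(np.arange(len(coords_a)), np.arange(len(coords_b)),
                             indexing="ij")
        ia, ib = ia.ravel(), ib.ravel()
    d = np.linalg.norm(
        minimum_image_displacement(coords_a[ia], coords_b[ib], box), axis=-1
    )
    keep = d <= cutoff
    ia, ib, d = ia[keep], ib[keep], d[keep]
    order = np.lexsort((ib, ia))
    return ia[order], ib[order], d[order]
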