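"""Base-stacking and hydrogen-bond classification over trajectories.

The stacking metric classifies a nucleobase as "in" when the projection of
its ring centre onto the plane of the ligand rings falls inside a rectangle
drawn around the projected ligand ring atoms, expanded by a margin (default
0.5 Å) on every side.  The rectangle is oriented along the in-plane principal
axes of the projected ring atoms, which makes the construction invariant
under rigid motions.  Hydrogen bonds use the geometric criterion
donor-acceptor distance < 3.5 Å and donor-H-acceptor angle > 120°.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_io import Trajectory

__all__ = [
    "Plane",
    "StackingResult",
    "HBondDefinition",
    "fit_plane",
    "stacking_state",
    "stacking_summary",
    "hbond_present",
    "hbond_occupancy",
]


@dataclass(frozen=True)
class Plane:
    centroid: np.ndarray
    normal: np.ndarray  # unit vector


@dataclass
class StackingResult:
    """Per-frame stacking flags and vertical distances, with summaries.

    ``mean_vertical_distance_in`` averages only over "in" frames and is NaN
    when no frame is "in" (``n_in`` carries the count).
    """

    flags: np.ndarray  # bool, True = "in"
    vertical_distance: np.ndarray  # Å, per frame

    @property
    def in_fraction(self) -> float:
        return float(np.mean(self.flags))

    @property
    def n_in(self) -> int:
        return int(np.sum(self.flags))

    @property
    def mean_vertical_distance_in(self) -> float:
        if self.n_in == 0:
            return float("nan")
        return float(np.mean(self.vertical_distance[self.flags]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"in": self.flags.astype(int), "vertical_distance_A": self.vertical_distance}
        )


@dataclass(frozen=True)
class HBondDefinition:
    """A donor/hydrogen/acceptor triple with geometric cutoffs.

    Atoms are identified by (residue_index, atom_name).  ``acceptors`` may
    list alternatives (an OR-group, counted as a single bond if any acceptor
    satisfies the criterion — as in occupancy tables that list "O6 / N7").
    """

    donor: tuple[int, str]
    hydrogen: tuple[int, str]
    acceptors: tuple[tuple[int, str], ...]
    distance_cutoff: float = 3.5
    angle_cutoff: float = 120.0
    label: str = ""

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.donor in self.acceptors:
            raise ValueError("donor and acceptor must differ")


def fit_plane(points: np.ndarray, reference_up: np.ndarray | None = None) -> Plane:
    """Least-squares plane through ``points`` (≥3, non-colinear).

    The unit normal is the singular vector of least variance; its sign is
    chosen so that ``normal · reference_up ≥ 0`` when a reference is given.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    # colinear points have at most one significant singular value
    if s[1] <= 1e-9 * max(s[0], 1e-30):
        raise ValueError("points are colinear or degenerate; plane undefined")
    normal = vt[2]
    if reference_up is not None and np.dot(normal, reference_up) < 0:
        normal = -normal
    return Plane(centroid=centroid, normal=normal / np.linalg.norm(normal))


def _rectangle_frame(ring: np.ndarray, plane: Plane) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-plane principal axes (u, v) and 2D coordinates of the ring atoms."""
    rel = ring - plane.centroid
    in_plane = rel - np.outer(rel @ plane.normal, plane.normal)
    cov = in_plane.T @ in_plane
    w, vecs = np.linalg.eigh(cov)
    u = vecs[:, 2]  # largest in-plane variance
    v = np.cross(plane.normal, u)
    coords2d = np.column_stack([in_plane @ u, in_plane @ v])
    return u, v, coords2d


def stacking_state(
    ligand_ring: np.ndarray, base_ring: np.ndarray, margin: float = 0.5
) -> tuple[bool, float]:
    """Classify one base against the ligand ring plane.

    Returns ``(flag, vertical_distance)``: *flag* is True ("in") iff the
    projection of the base-ring geometric centre lies inside the
    margin-expanded principal-axis bounding rectangle of the projected
    ligand ring atoms; *vertical_distance* is the unsigned distance of the
    base centre from the ligand plane.  A projection exactly on the edge
    counts as "in".
    """
    plane = fit_plane(ligand_ring)
    u, v, ring2d = _rectangle_frame(np.asarray(ligand_ring, float), plane)
    lo = ring2d.min(axis=0) - margin
    hi = ring2d.max(axis=0) + margin
    center = np.asarray(base_ring, dtype=float).mean(axis=0)
    rel = center - plane.centroid
    z = float(rel @ plane.normal)
    p2d = np.array([rel @ u, rel @ v])
    inside = bool(np.all(p2d >= lo) and np.all(p2d <= hi))
    return inside, abs(z)


def rectangle_corners(ligand_ring: np.ndarray, margin: float = 0.5) -> np.ndarray:
    """Explicit 3D corners of the stacking rectangle (for cross-checks)."""
    ring = np.asarray(ligand_ring, dtype=float)
    plane = fit_plane(ring)
    u, v, ring2d = _rectangle_frame(ring, plane)
    lo = ring2d.min(axis=0) - margin
    hi = ring2d.max(axis=0) + margin
    corners2d = np.array([[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]], [lo[0], hi[1]]])
    return plane.centroid + corners2d @ np.vstack([u, v])


def stacking_summary(
    trajectory: Trajectory,
    ligand_ring_sel: Sequence[tuple[int, str]],
    base_sel: Sequence[tuple[int, str]],
    margin: float = 0.5,
) -> StackingResult:
    """Apply :func:`stacking_state` to every frame of a trajectory."""
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    lig_idx = trajectory.topology.atom_indices(ligand_ring_sel)
    base_idx = trajectory.topology.atom_indices(base_sel)
    flags = np.empty(trajectory.n_frames, dtype=bool)
    vdist = np.empty(trajectory.n_frames, dtype=float)
    for f in range(trajectory.n_frames):
        flags[f], vdist[f] = stacking_state(
            trajectory.coordinates[f, lig_idx],
            trajectory.coordinates[f, base_idx],
            margin=margin,
        )
    return StackingResult(flags=flags, vertical_distance=vdist)


def hbond_present(frame: np.ndarray, definition: HBondDefinition, topology) -> bool:
    """Evaluate one hydrogen-bond definition on a single coordinate frame."""
    d = frame[topology.atom_index(*definition.donor)]
    h = frame[topology.atom_index(*definition.hydrogen)]
    for acc in definition.acceptors:
        a = frame[topology.atom_index(*acc)]
        if _hbond_geometry(d, h, a, definition.distance_cutoff, definition.angle_cutoff):
            return True
    return False


def _hbond_geometry(d, h, a, dist_cut, ang_cut) -> bool:
    if np.linalg.norm(a - d) >= dist_cut:
        return False
    v1 = d - h
    v2 = a - h
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return False
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang))) > ang_cut


def hbond_occupancy(
    trajectory: Trajectory, definitions: Sequence[HBondDefinition]
) -> pd.DataFrame:
    """Per-definition fraction of frames in which the bond is formed.

    OR-group alternatives inside one definition count as a single bond.
    Returns a table with columns ``label`` and ``occupancy``.
    """
    if not definitions:
        raise ValueError("at least one hydrogen-bond definition required")
    top = trajectory.topology
    rows = []
    for k, dfn in enumerate(definitions):
        di = top.atom_index(*dfn.donor)
        hi = top.atom_index(*dfn.hydrogen)
        ai = [top.atom_index(*a) for a in dfn.acceptors]
        count = 0
        for f in range(trajectory.n_frames):
            fr = trajectory.coordinates[f]
            if any(
                _hbond_geometry(fr[di], fr[hi], fr[j], dfn.distance_cutoff, dfn.angle_cutoff)
                for j in ai
            ):
                count += 1
        rows.append(
            {"label": dfn.label or f"hbond_{k}", "occupancy": count / trajectory.n_frames}
        )
    return pd.DataFrame(rows)
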