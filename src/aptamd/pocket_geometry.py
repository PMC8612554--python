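"""Pocket distances, collective variables, and spatial densities.

Collective variables follow the binding-pocket frame: ``r`` is the distance
from the ligand geometric centre to the pocket centre (geometric centre of
the heavy atoms of the six pocket-lining residues), ``z`` is the signed
coordinate of the ligand centre along the normal of a plane through three
named atoms that bisects the pocket.  The normal is oriented so the
front-marker midpoint has z > 0 ("front" positive).  The frame is
recomputed every frame, so the analysis lives in the moving frame of the
RNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .model_io import ReferenceSite, Trajectory
from .stacking_hbonds import fit_plane

__all__ = [
    "DistanceDefinition",
    "DistanceSeries",
    "PocketFrame",
    "PocketSpec",
    "CVTrace",
    "GridDensity",
    "distance_series",
    "pocket_frame",
    "cv_trace",
    "theta_angle",
    "cv_density_map",
    "grid_density",
    "site_occupancy",
]


@dataclass(frozen=True)
class DistanceDefinition:
    """A named atom-pair distance, e.g. d_15-30 between two C1' atoms."""

    label: str
    atom_a: tuple[int, str]
    atom_b: tuple[int, str]

    def __post_init__(self):
        if self.atom_a == self.atom_b:
            raise ValueError("distance endpoints must differ")


@dataclass
class DistanceSeries:
    label: str
    values: np.ndarray  # Å per frame
    bin_width: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin_edges, density) normalised to unit area."""
        lo = np.floor(self.values.min() / self.bin_width) * self.bin_width
        hi = np.ceil(self.values.max() / self.bin_width) * self.bin_width
        n = max(int(round((hi - lo) / self.bin_width)), 1)
        dens, edges = np.histogram(self.values, bins=n, range=(lo, hi), density=True)
        return edges, dens


@dataclass(frozen=True)
class PocketFrame:
    pocket_center: np.ndarray
    plane_origin: np.ndarray
    normal: np.ndarray  # unit, front-positive


@dataclass(frozen=True)
class PocketSpec:
    """Selections defining the pocket frame.

    ``pocket_residues``: residue indices whose heavy atoms define the pocket
    centre; ``plane_atoms``: three (residue, atom) pairs through which the
    bisecting plane passes; ``front_markers``: atoms whose midpoint fixes the
    positive (front) side of the normal.
    """

    pocket_residues: tuple[int, ...]
    plane_atoms: tuple[tuple[int, str], ...]
    front_markers: tuple[tuple[int, str], ...]


def distance_series(
    trajectory: Trajectory, definition: DistanceDefinition, bin_width: float = 0.2
) -> DistanceSeries:
    """Euclidean distance per frame between the two named atoms."""
    top = trajectory.topology
    ia = top.atom_index(*definition.atom_a)
    ib = top.atom_index(*definition.atom_b)
    values = np.linalg.norm(
        trajectory.coordinates[:, ia] - trajectory.coordinates[:, ib], axis=1
    )
    return DistanceSeries(label=definition.label, values=values, bin_width=bin_width)


def pocket_frame(frame: np.ndarray, topology, spec: PocketSpec) -> PocketFrame:
    """Build the pocket frame (centre + oriented bisecting plane) for one frame."""
    heavy: list[int] = []
    for r in spec.pocket_residues:
        heavy.extend(topology.heavy_indices(topology.residue_atom_indices(r)))
    center = frame[heavy].mean(axis=0)
    plane_idx = topology.atom_indices(spec.plane_atoms)
    plane = fit_plane(frame[plane_idx])
    marker_idx = topology.atom_indices(spec.front_markers)
    marker_mid = frame[marker_idx].mean(axis=0)
    zm = float((marker_mid - plane.centroid) @ plane.normal)
    if abs(zm) < 1e-9:
        raise ValueError(
            "front marker lies in the bisecting plane; orientation ambiguous — "
            "supply an explicit orientation"
        )
    normal = plane.normal if zm > 0 else -plane.normal
    return PocketFrame(pocket_center=center, plane_origin=plane.centroid, normal=normal)


@dataclass
class CVTrace:
    """(r, z) collective-variable trace with per-frame times (ps)."""

    r: np.ndarray
    z: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if not (len(self.r) == len(self.z) == len(self.times)):
            raise ValueError("r, z, times must have equal length")
        if np.any(self.r < 0):
            raise ValueError("r must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, "r_A": self.r, "z_A": self.z})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CVTrace":
        return cls(r=df["r_A"].to_numpy(), z=df["z_A"].to_numpy(), times=df["time_ps"].to_numpy())


def cv_trace(
    trajectory: Trajectory,
    ligand_sel: Sequence[tuple[int, str]] | int,
    spec: PocketSpec,
) -> CVTrace:
    """(r, z) of the ligand centre in the per-frame pocket frame.

    ``ligand_sel`` is either a list of (residue, atom) pairs or a residue
    index whose heavy atoms define the ligand centre.
    """
    top = trajectory.topology
    if isinstance(ligand_sel, int):
        lig_idx = top.heavy_indices(top.residue_atom_indices(ligand_sel))
    else:
        lig_idx = top.atom_indices(ligand_sel)
    r = np.empty(trajectory.n_frames)
    z = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        fr = trajectory.coordinates[f]
        pf = pocket_frame(fr, top, spec)
        lig_center = fr[lig_idx].mean(axis=0)
        r[f] = np.linalg.norm(lig_center - pf.pocket_center)
        z[f] = (lig_center - pf.plane_origin) @ pf.normal
    return CVTrace(r=r, z=z, times=trajectory.times)


def theta_angle(
    frame: np.ndarray,
    topology,
    group1: Sequence[Sequence[tuple[int, str]]],
    group2: Sequence[Sequence[tuple[int, str]]],
) -> float:
    """Mean acute inter-plane angle (degrees) between two groups of base rings.

    A plane is fitted to each base's ring atoms; the angle between two bases
    is the acute angle between their plane normals; Θ averages over all
    cross-group pairs, so it lies in [0°, 90°].
    """
    normals1 = [fit_plane(frame[topology.atom_indices(b)]).normal for b in group1]
    normals2 = [fit_plane(frame[topology.atom_indices(b)]).normal for b in group2]
    angles = []
    for n1 in normals1:
        for n2 in normals2:
            c = abs(float(np.clip(n1 @ n2, -1.0, 1.0)))
            angles.append(np.degrees(np.arccos(c)))
    return float(np.mean(angles))


def cv_density_map(
    trace_x: np.ndarray, trace_y: np.ndarray, bins: int | tuple[int, int] = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[float, float]]:
    """2D histogram over two collective variables, normalised to unit mass.

    Returns ``(hist, x_edges, y_edges, peak)`` where *peak* is the bin-centre
    of the maximum; ties are broken toward the lowest x, then lowest y.
    """
    x = np.asarray(trace_x, dtype=float)
    y = np.asarray(trace_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("traces must have equal length")
    hist, xe, ye = np.histogram2d(x, y, bins=bins)
    hist = hist / hist.sum()
    flat = np.argmax(hist)  # argmax returns the first (lowest x, then y) maximum
    i, j = np.unravel_index(flat, hist.shape)
    peak = (float((xe[i] + xe[i + 1]) / 2), float((ye[j] + ye[j + 1]) / 2))
    return hist, xe, ye, peak


@dataclass
class GridDensity:
    """3D position histogram for a selection of particles.

    ``counts[i, j, k]`` counts particle-frames whose position falls in the
    voxel with lower corner ``origin + spacing * (i, j, k)``.  Particles
    outside the grid are tallied in ``overflow`` so that
    ``counts.sum() + overflow == n_frames * n_particles``.
    """

    origin: np.ndarray
    spacing: float
    counts: np.ndarray
    n_frames: int
    n_particles: int
    overflow: int = 0

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.copy()


def grid_density(
    trajectory: Trajectory,
    selection: Sequence[tuple[int, str]] | np.ndarray,
    spacing: float = 0.5,
    smoothing_sd: float = 0.0,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
    padding: float = 3.0,
) -> GridDensity:
    """Histogram selected-atom positions on a 3D grid over all frames.

    The grid auto-sizes to the bounding box of the positions plus *padding*
    unless *origin* and *shape* are given.  Optional Gaussian smoothing
    (``smoothing_sd`` in Å) conserves total mass.
    """
    top = trajectory.topology
    if isinstance(selection, np.ndarray) and selection.dtype != object:
        idx = selection.astype(int)
    else:
        idx = top.atom_indices(selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    pos = trajectory.coordinates[:, idx].reshape(-1, 3)
    if origin is None:
        lo = pos.min(axis=0) - padding
        hi = pos.max(axis=0) + padding
        origin = lo
        shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)
    elif shape is None:
        raise ValueError("shape required when origin is given")
    origin = np.asarray(origin, dtype=float)
    ijk = np.floor((pos - origin) / spacing).astype(int)
    inside = np.all((ijk >= 0) & (ijk < np.array(shape)), axis=1)
    counts = np.zeros(shape, dtype=float)
    np.add.at(counts, tuple(ijk[inside].T), 1.0)
    overflow = int(np.sum(~inside))
    if smoothing_sd > 0:
        counts = ndimage.gaussian_filter(
            counts, sigma=smoothing_sd / spacing, mode="constant", truncate=6.0
        )
        # renormalise the small mass clipped at the grid boundary
        total = counts.sum()
        target = len(pos) - overflow
        if total > 0:
            counts *= target / total
    return GridDensity(
        origin=origin,
        spacing=spacing,
        counts=counts,
        n_frames=trajectory.n_frames,
        n_particles=len(idx),
        overflow=overflow,
    )


def density_peaks(density: GridDensity, threshold_fraction: float = 0.5) -> np.ndarray:
    """Positions of 26-neighbour local maxima above a fraction of the global max."""
    c = density.counts
    if c.max() <= 0:
        return np.empty((0, 3))
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = c == ndimage.maximum_filter(c, footprint=footprint, mode="constant")
    mask = local_max & (c >= threshold_fraction * c.max())
    ijk = np.argwhere(mask)
    return density.origin + (ijk + 0.5) * density.spacing


def site_occupancy(
    trajectory: Trajectory,
    selection: Sequence[tuple[int, str]] | np.ndarray,
    sites: Sequence[ReferenceSite],
    radius: float = 2.0,
    spacing: float = 0.5,
    peak_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-site fraction of frames with any selected atom within *radius*.

    Also reports, per site, the distance to the nearest density peak of the
    selection's grid density (local maxima above ``peak_threshold`` of the
    global maximum).
    """
    if not sites:
        raise ValueError("at least one reference site required")
    top = trajectory.topology
    if isinstance(selection, np.ndarray) and selection.dtype != object:
        idx = selection.astype(int)
    else:
        idx = top.atom_indices(selection)
    pos = trajectory.coordinates[:, idx]  # (F, S, 3)
    dens = grid_density(trajectory, idx, spacing=spacing)
    peaks = density_peaks(dens, threshold_fraction=peak_threshold)
    rows = []
    for site in sites:
        p = np.asarray(site.position)
        dmin = np.linalg.norm(pos - p, axis=2).min(axis=1)  # per frame
        occ = float(np.mean(dmin <= radius))
        if len(peaks):
            near = float(np.linalg.norm(peaks - p, axis=1).min())
        else:
            near = float("nan")
        rows.append(
            {
                "label": site.label,
                "x": p[0],
                "y": p[1],
                "z": p[2],
                "occupancy": occ,
                "nearest_peak_distance": near,
            }
        )
    return pd.DataFrame(rows)
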