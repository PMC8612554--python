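"""Synthetic toy systems standing in for aptamer-ligand MD data.

Three generators:

* a rigid six-nucleotide toy binding pocket (two stacking plates above and
  below a planar ligand ring, in-plane hydrogen-bond partners, front/back
  door marker atoms at configurable widths);
* programmed bound-state trajectories in which discrete states (base
  stacked/displaced, hydrogen bond formed/broken, C15-like base parallel/
  orthogonal, ion site occupied/in bulk) follow two-state Markov chains with
  prescribed stationary occupancies, plus Gaussian positional noise — so
  every analyzer can be validated against the ground-truth state log;
* a well-tempered metadynamics toy: overdamped Langevin dynamics of a point
  ligand in a two-channel escape potential (or a 1D double well), with
  Gaussian hills deposited on the distance-to-origin collective variable and
  scaled by the well-tempered rule  h = h0 * exp(-V_bias / ((gamma-1) kT)).

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .model_io import (
    AtomRecord,
    ReferenceSite,
    Segment,
    Topology,
    Trajectory,
    attach_parameters,
    read_parameter_table,
)
from .pocket_geometry import CVTrace, PocketSpec
from .stacking_hbonds import HBondDefinition

__all__ = [
    "ToyPocketSpec",
    "ToyComplex",
    "OccupancyProgram",
    "ToyPotentialSpec",
    "MetadynamicsParams",
    "MetadynamicsResult",
    "build_toy_complex",
    "simulate_bound_trajectory",
    "simulate_ion_occupancy",
    "simulate_wt_metadynamics",
    "simulate_wt_metadynamics_1d",
    "reconstruct_fes",
    "toy_parameter_table",
]

RING_RADIUS = 1.4  # Å, planar ligand ring radius
BASE_RING_RADIUS = 1.15  # Å, pseudo-base ring radius
FRAME_INTERVAL_PS = 10.0  # snapshot cadence metadata


def toy_parameter_table() -> pd.DataFrame:
    """The bundled per-atom parameter table for the toy complex."""
    text = (resources.files("aptamd") / "data" / "toy_params.tsv").read_text()
    return read_parameter_table(text)


@dataclass(frozen=True)
class ToyPocketSpec:
    """Geometry of the rigid toy pocket (lengths in Å)."""

    plate_gap: float = 3.4
    door_front_width: float = 12.0
    door_back_width: float = 7.8
    hbond_distance: float = 2.9
    ring_atom_count: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.door_front_width <= 0 or self.door_back_width <= 0:
            raise ValueError("door widths must be positive")
        if self.ring_atom_count < 3:
            raise ValueError("ring needs >= 3 atoms for plane fitting")
        if min(self.door_front_width, self.door_back_width) < 2 * RING_RADIUS:
            raise ValueError(
                "door width smaller than the ligand ring diameter is infeasible"
            )
        if self.ring_atom_count > 12:
            raise ValueError("toy parameter table covers at most 12 ring atoms")


@dataclass
class ToyComplex:
    """Toy topology + rigid reference frame + the selections that go with it."""

    topology: Topology
    reference: np.ndarray  # (n_atoms, 3)
    spec: ToyPocketSpec
    ligand_ring: list = field(default_factory=list)  # (res, atom) pairs
    plates: dict = field(default_factory=dict)  # base label -> ring selection
    hbonds: list = field(default_factory=list)  # HBondDefinition
    base_rings: dict = field(default_factory=dict)  # in-plane partner rings
    pocket_spec: PocketSpec | None = None
    ligand_residue: int = 34

    def reference_trajectory(self) -> Trajectory:
        return Trajectory(self.topology, self.reference[None], times=np.array([0.0]))


def _ring(center, radius, n, normal="z"):
    """Planar regular polygon; ``normal`` picks the ring plane orientation."""
    ang = 2 * np.pi * np.arange(n) / n
    circ = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)]) * radius
    if normal == "x":  # ring in the yz-plane
        circ = circ[:, [2, 0, 1]]
    return np.asarray(center) + circ


# in-plane directions (unit vectors in the xy-plane) of the H-bond partners
_HB_ANGLES = {"U6": 150.0, "C15": 210.0, "A29": 270.0}


def _dir(angle_deg):
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a), 0.0])


def build_toy_complex(spec: ToyPocketSpec = ToyPocketSpec()) -> ToyComplex:
    """Construct the rigid toy pocket around a planar ligand ring at the origin.

    Layout: the ligand ring lies in the xy-plane; the "G11" plate sits at
    +plate_gap/2 above it and the "G5"/"C16" plates below; pseudo-bases
    "U6", "C15", "A29" offer in-plane hydrogen-bond partners at
    ``hbond_distance``; C1' marker atoms of G5/G11 (front, +y) and C15/C30
    (back, -y) are separated by the configured door widths; three plane
    atoms (U6 C1', A10 C1', C15 C4) define the pocket-bisecting plane with
    front-positive normal +y.
    """
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = [0]

    def add(res_idx, res_name, name, xyz, element, segment):
        serial[0] += 1
        atoms.append(
            AtomRecord(
                serial=serial[0],
                atom_name=name,
                residue_name=res_name,
                residue_index=res_idx,
                segment=segment,
                element=element,
            )
        )
        coords.append(np.asarray(xyz, dtype=float))

    n = spec.ring_atom_count
    lig_res = 34
    ring = _ring((0, 0, 0), RING_RADIUS, n)
    for i, xyz in enumerate(ring, start=1):
        add(lig_res, "LIG", f"C{i}", xyz, "C", Segment.LIGAND)
    ligand_ring = [(lig_res, f"C{i}") for i in range(1, n + 1)]

    # ligand in-plane H-bond atoms: donor N1(+H1) toward U6, acceptor O1
    # toward C15, acceptor N2 toward A29
    d_l = RING_RADIUS + 1.2
    add(lig_res, "LIG", "N1", d_l * _dir(_HB_ANGLES["U6"]), "N", Segment.LIGAND)
    add(lig_res, "LIG", "H1", (d_l + 1.0) * _dir(_HB_ANGLES["U6"]), "H", Segment.LIGAND)
    add(lig_res, "LIG", "O1", d_l * _dir(_HB_ANGLES["C15"]), "O", Segment.LIGAND)
    add(lig_res, "LIG", "N2", d_l * _dir(_HB_ANGLES["A29"]), "N", Segment.LIGAND)

    half_gap = spec.plate_gap / 2.0
    plates = {}
    for label, res_idx, res_name, center in (
        ("G11", 11, "G", (0.0, 0.0, +half_gap)),
        ("G5", 5, "G", (-0.8, 0.0, -half_gap)),
        ("C16", 16, "C", (+0.8, 0.0, -half_gap)),
    ):
        ringsel = []
        for i, xyz in enumerate(_ring(center, BASE_RING_RADIUS, 6), start=1):
            add(res_idx, res_name, f"B{i}", xyz, "C", Segment.RNA)
            ringsel.append((res_idx, f"B{i}"))
        plates[label] = ringsel

    # in-plane partner bases: partner atom at hbond_distance from the ligand
    # H-bond atom, small ring beyond it, all in the xy-plane (parallel state)
    hb = spec.hbond_distance
    partners = {
        "U6": (6, "U", [("O4", 0.0)]),  # acceptor
        "C15": (15, "C", [("N4", 0.0), ("H4", -1.0)]),  # donor + its H
        "A29": (29, "A", [("N6", 0.0), ("H6", -1.0)]),  # donor + its H
    }
    base_rings = {}
    for label, (res_idx, res_name, atom_list) in partners.items():
        u = _dir(_HB_ANGLES[label])
        for name, off in atom_list:
            add(res_idx, res_name, name, (d_l + hb + off) * u, name[0], Segment.RNA)
        ringsel = []
        ring_center = (d_l + hb + 1.5) * u
        for i, xyz in enumerate(_ring(ring_center, BASE_RING_RADIUS, 4), start=1):
            add(res_idx, res_name, f"B{i}", xyz, "C", Segment.RNA)
            ringsel.append((res_idx, f"B{i}"))
        base_rings[label] = ringsel

    # back-door residue C30: marker + small ring near the back
    for i, xyz in enumerate(
        _ring((spec.door_back_width / 2, -5.5, 0.0), BASE_RING_RADIUS, 4), start=1
    ):
        add(30, "C", f"B{i}", xyz, "C", Segment.RNA)

    # door markers
    wf, wb = spec.door_front_width / 2, spec.door_back_width / 2
    add(5, "G", "C1'", (-wf, 4.0, 0.0), "C", Segment.RNA)
    add(11, "G", "C1'", (+wf, 4.0, 0.0), "C", Segment.RNA)
    add(15, "C", "C1'", (-wb, -4.0, 0.0), "C", Segment.RNA)
    add(30, "C", "C1'", (+wb, -4.0, 0.0), "C", Segment.RNA)

    # bisecting-plane atoms, shifted so the plane passes through the pocket
    # centre (which makes the (r, z) frame exact for embedding round-trips)
    topo_tmp = Topology(list(atoms))
    ref_tmp = np.array(coords)
    pocket_residues = (5, 6, 11, 15, 16, 30)
    heavy = []
    for r in pocket_residues:
        heavy.extend(topo_tmp.heavy_indices(topo_tmp.residue_atom_indices(r)))
    cy = float(ref_tmp[heavy, 1].mean())
    add(6, "U", "C1'", (5.5, cy, 0.5), "C", Segment.RNA)
    add(10, "A", "C1'", (-5.5, cy, 0.5), "C", Segment.RNA)
    add(15, "C", "C4", (0.0, cy, -3.0), "C", Segment.RNA)

    topology = attach_parameters(Topology(atoms), toy_parameter_table())
    reference = np.array(coords)

    hbonds = [
        HBondDefinition(
            donor=(lig_res, "N1"),
            hydrogen=(lig_res, "H1"),
            acceptors=((6, "O4"),),
            label="LIG_N1:U6_O4",
        ),
        HBondDefinition(
            donor=(15, "N4"),
            hydrogen=(15, "H4"),
            acceptors=((lig_res, "O1"),),
            label="C15_N4:LIG_O1",
        ),
        HBondDefinition(
            donor=(29, "N6"),
            hydrogen=(29, "H6"),
            acceptors=((lig_res, "N2"),),
            label="A29_N6:LIG_N2",
        ),
    ]
    pocket_spec = PocketSpec(
        pocket_residues=pocket_residues,
        plane_atoms=((6, "C1'"), (10, "C1'"), (15, "C4")),
        front_markers=((5, "C1'"), (11, "C1'")),
    )
    return ToyComplex(
        topology=topology,
        reference=reference,
        spec=spec,
        ligand_ring=ligand_ring,
        plates=plates,
        hbonds=hbonds,
        base_rings=base_rings,
        pocket_spec=pocket_spec,
        ligand_residue=lig_res,
    )


# ---------------------------------------------------------------------------
# Programmed bound-state trajectories


@dataclass(frozen=True)
class OccupancyProgram:
    """Stationary occupancies and kinetics of the programmed discrete states.

    ``state_switch_probability`` (s) sets the Markov-chain kinetics: from the
    occupied state the exit probability per frame is s*(1-p), from the empty
    state the entry probability is s*p, which leaves the stationary
    occupancy at p while retaining frame-to-frame autocorrelation (decay
    factor 1-s per frame), as real MD observables have.
    """

    stacking_in_fraction: dict = field(
        default_factory=lambda: {"G5": 0.95, "G11": 0.98, "C16": 0.98}
    )
    hbond_occupancy: dict = field(
        default_factory=lambda: {
            "LIG_N1:U6_O4": 0.85,
            "C15_N4:LIG_O1": 0.95,
            "A29_N6:LIG_N2": 0.88,
        }
    )
    c15_parallel_fraction: float = 1.0
    positional_noise_sd: float = 0.15  # Å
    state_switch_probability: float = 0.8

    def __post_init__(self):
        for p in (
            *self.stacking_in_fraction.values(),
            *self.hbond_occupancy.values(),
            self.c15_parallel_fraction,
            self.state_switch_probability,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _markov_chain(rng, p, s, n):
    """Two-state chain with stationary P(on) = p and switch parameter s."""
    states = np.empty(n, dtype=bool)
    state = bool(rng.random() < p)
    for i in range(n):
        states[i] = state
        if state:
            if rng.random() < s * (1 - p):
                state = False
        else:
            if rng.random() < s * p:
                state = True
    return states


#: displacement applied to a plate ring when its base is in the "out" state
PLATE_OUT_SHIFT = 5.0  # Å, lateral
#: extra donor-acceptor separation when a hydrogen bond is broken
HBOND_OFF_SHIFT = 1.6  # Å (2.9 -> 4.5, well past the 3.5 Å cutoff)


def simulate_bound_trajectory(
    toy: ToyComplex,
    program: OccupancyProgram = OccupancyProgram(),
    n_frames: int = 1000,
    seed: int = 0,
) -> tuple[Trajectory, pd.DataFrame]:
    """Bound-state trajectory with programmed discrete-state switching.

    Returns the trajectory and the ground-truth per-frame state log (one
    boolean column per programmed state).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    top = toy.topology
    s = program.state_switch_probability
    log: dict[str, np.ndarray] = {}
    for label, p in program.stacking_in_fraction.items():
        log[f"stack_{label}"] = _markov_chain(rng, p, s, n_frames)
    for label, p in program.hbond_occupancy.items():
        log[f"hbond_{label}"] = _markov_chain(rng, p, s, n_frames)
    log["c15_parallel"] = _markov_chain(rng, program.c15_parallel_fraction, s, n_frames)

    coords = np.repeat(toy.reference[None], n_frames, axis=0)

    # plate displacement when "out": lateral shift away from the rectangle
    for label, ringsel in toy.plates.items():
        if label not in program.stacking_in_fraction:
            continue
        idx = top.atom_indices(ringsel)
        center = toy.reference[idx].mean(axis=0)
        lateral = np.array([center[0], center[1], 0.0])
        norm = np.linalg.norm(lateral)
        direction = lateral / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        out = ~log[f"stack_{label}"]
        coords[np.ix_(out, idx)] += PLATE_OUT_SHIFT * direction

    # hydrogen bonds: when broken, move the distal partner group outward
    hb_atoms = {
        "LIG_N1:U6_O4": ([(6, "O4")], _HB_ANGLES["U6"]),
        "C15_N4:LIG_O1": ([(15, "N4"), (15, "H4")], _HB_ANGLES["C15"]),
        "A29_N6:LIG_N2": ([(29, "N6"), (29, "H6")], _HB_ANGLES["A29"]),
    }
    for label, (atom_sel, angle) in hb_atoms.items():
        if label not in program.hbond_occupancy:
            continue
        idx = top.atom_indices(atom_sel)
        off = ~log[f"hbond_{label}"]
        coords[np.ix_(off, idx)] += HBOND_OFF_SHIFT * _dir(angle)

    # C15 base-ring orientation: orthogonal state rotates the ring 90° about
    # its in-plane radial axis through the ring centre
    ringsel = toy.base_rings["C15"]
    idx = top.atom_indices(ringsel)
    center = toy.reference[idx].mean(axis=0)
    axis = _dir(_HB_ANGLES["C15"])
    R = _rotation_matrix(axis, np.pi / 2)
    rotated = center + (toy.reference[idx] - center) @ R.T
    ortho = ~log["c15_parallel"]
    coords[np.ix_(ortho, idx)] = rotated

    if program.positional_noise_sd > 0:
        coords = coords + rng.normal(
            0.0, program.positional_noise_sd, size=coords.shape
        )
    times = FRAME_INTERVAL_PS * np.arange(n_frames, dtype=float)
    log_df = pd.DataFrame({k: v.astype(int) for k, v in log.items()})
    log_df.insert(0, "frame", np.arange(n_frames))
    return Trajectory(top, coords, times=times), log_df


def _rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


# ---------------------------------------------------------------------------
# Ion-site occupancy trajectories


def simulate_ion_occupancy(
    sites: list[ReferenceSite],
    occupancies: dict[str, float],
    n_ions: int = 1,
    n_frames: int = 1000,
    seed: int = 0,
    noise_sd: float = 0.3,
    box: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[Trajectory, pd.DataFrame]:
    """Ion-only trajectory with programmed per-site occupancies.

    Each ion, independently per frame, resides at a named site (with
    Gaussian noise of ``noise_sd``) or in bulk (uniform in ``box``).  The
    per-site probabilities are ``occupancies``; the remainder is bulk.
    Returns the trajectory and the ground-truth site-assignment log.
    """
    probs = np.array([occupancies.get(s.label, 0.0) for s in sites])
    if probs.sum() > 1.0 + 1e-9:
        raise ValueError("site occupancies must sum to <= 1 per ion")
    positions = np.array([s.position for s in sites])
    if len(sites) > 1:
        from scipy.spatial.distance import pdist

        if pdist(positions).min() < 2 * noise_sd:
            warnings.warn(
                "reference sites closer than 2x noise sd; occupancies may mix",
                RuntimeWarning,
            )
    if box is None:
        center = positions.mean(axis=0)
        box = (center - 15.0, center + 15.0)
    lo, hi = np.asarray(box[0], float), np.asarray(box[1], float)

    rng = np.random.default_rng(seed)
    atoms = [
        AtomRecord(
            serial=i + 1,
            atom_name="MG",
            residue_name="MG",
            residue_index=100 + i,
            segment=Segment.ION,
            element="MG",
        )
        for i in range(n_ions)
    ]
    top = Topology(atoms)
    coords = np.empty((n_frames, n_ions, 3))
    choice = np.empty((n_frames, n_ions), dtype=int)  # site index, -1 = bulk
    cum = np.cumsum(probs)
    for f in range(n_frames):
        for k in range(n_ions):
            u = rng.random()
            site_idx = int(np.searchsorted(cum, u))
            if site_idx >= len(sites):
                choice[f, k] = -1
                coords[f, k] = lo + rng.random(3) * (hi - lo)
            else:
                choice[f, k] = site_idx
                coords[f, k] = positions[site_idx] + (
                    rng.normal(0.0, noise_sd, 3) if noise_sd > 0 else 0.0
                )
    times = FRAME_INTERVAL_PS * np.arange(n_frames, dtype=float)
    log = pd.DataFrame(
        {"frame": np.arange(n_frames)}
        | {f"ion{k}_site": choice[:, k] for k in range(n_ions)}
    )
    return Trajectory(top, coords, times=times), log


# ---------------------------------------------------------------------------
# Well-tempered metadynamics toy


@dataclass(frozen=True)
class ToyPotentialSpec:
    """Designed free-energy landscape for the escape toy (kcal/mol, Å).

    A bound well sits at the origin.  Beyond ``gate_radius`` an angular
    profile applies: two Gaussian channels around the +z (front) and -z
    (back) directions with floors at ``front_barrier`` and ``back_barrier``,
    separated by ``side_barrier`` walls — so an escaping particle must climb
    into, and then remains confined to, one of the two cones, and the sign
    of z records which door it used.  A soft harmonic wall beyond
    ``wall_radius`` keeps the particle near the pocket, mirroring the
    restraining potential used to keep a ligand close to the RNA.
    """

    form: str = "two_channel"
    well_depth: float = 6.0
    front_barrier: float = 3.0
    back_barrier: float = 5.0
    side_barrier: float = 12.0
    channel_half_angle: float = 30.0  # degrees
    kT: float = 0.596  # kcal/mol at 300 K
    gate_radius: float = 3.0
    gate_width: float = 0.5
    well_width: float = 2.0
    wall_radius: float = 12.0
    wall_k: float = 2.0  # kcal/mol/Å^2

    def __post_init__(self):
        if self.front_barrier <= 0 or self.back_barrier <= 0:
            raise ValueError("barriers must be positive")
        if self.kT <= 0:
            raise ValueError("kT must be positive")

    def energy(self, x: float, z: float) -> float:
        """Potential at 2D position (x, z); z is the channel (front) axis."""
        r = math.hypot(x, z)
        theta = math.atan2(abs(x), z) if r > 1e-9 else 0.0  # 0 = front, pi = back
        sigma = math.radians(self.channel_half_angle)
        g_front = math.exp(-((theta / sigma) ** 2))
        g_back = math.exp(-(((math.pi - theta) / sigma) ** 2))
        angular = (
            self.side_barrier
            - (self.side_barrier - self.front_barrier) * g_front
            - (self.side_barrier - self.back_barrier) * g_back
        )
        gate = 0.5 * (1.0 + math.tanh((r - self.gate_radius) / self.gate_width))
        u = -self.well_depth * math.exp(-((r / self.well_width) ** 2))
        u += gate * angular
        if r > self.wall_radius:
            u += self.wall_k * (r - self.wall_radius) ** 2
        return u

    def gradient(self, x: float, z: float, h: float = 1e-5) -> np.ndarray:
        gx = (self.energy(x + h, z) - self.energy(x - h, z)) / (2 * h)
        gz = (self.energy(x, z + h) - self.energy(x, z - h)) / (2 * h)
        return np.array([gx, gz])


@dataclass(frozen=True)
class MetadynamicsParams:
    """Hill deposition and Langevin integration parameters.

    Defaults mirror the biased-simulation settings of the study this package
    emulates: hill width 0.5 Å, initial height 1.2 kcal/mol, bias factor 15.
    The deposit interval (500 integration steps) and the overdamped-Langevin
    constants are toy choices: with diffusion D and timestep dt the random
    step sd is sqrt(2 D dt) = 0.1 Å, one fifth of the hill width.
    """

    gaussian_width: float = 0.5  # Å
    initial_height: float = 1.2  # kcal/mol
    bias_factor: float = 15.0
    deposit_interval: int = 500  # steps
    timestep: float = 0.02  # ps
    diffusion: float = 0.25  # Å^2/ps

    def __post_init__(self):
        if self.gaussian_width <= 0 or self.initial_height <= 0:
            raise ValueError("hill width and height must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")


@dataclass
class MetadynamicsResult:
    trace: CVTrace
    positions: np.ndarray  # (n_steps, 2) as (x, z)
    hills: pd.DataFrame  # step, center, width, height
    bias_grid: np.ndarray  # CV grid values
    bias: np.ndarray  # V_bias on the grid
    bias_time_average: np.ndarray  # averaged over post-burn-in deposits


class _GridBias:
    """Tabulated 1D bias potential with linear interpolation."""

    def __init__(self, lo, hi, spacing):
        self.grid = np.arange(lo, hi + spacing / 2, spacing)
        self.values = np.zeros_like(self.grid)
        self.spacing = spacing

    def __call__(self, s):
        return float(np.interp(s, self.grid, self.values))

    def force(self, s, h=0.05):
        return (self(s + h) - self(s - h)) / (2 * h)

    def deposit(self, center, width, height):
        self.values += height * np.exp(-((self.grid - center) ** 2) / (2 * width**2))


def simulate_wt_metadynamics(
    potential: ToyPotentialSpec = ToyPotentialSpec(),
    params: MetadynamicsParams = MetadynamicsParams(),
    n_steps: int = 200_000,
    seed: int = 0,
    start: tuple[float, float] = (0.0, 0.5),
) -> MetadynamicsResult:
    """Biased escape dynamics of a 2D particle; bias acts on r = |position|.

    Overdamped Langevin (Euler-Maruyama) integration; a Gaussian hill is
    deposited on the r grid every ``deposit_interval`` steps with the
    well-tempered height  h0 * exp(-V_bias(r)/((gamma-1) kT)).  The returned
    trace holds per-step (r, z) where z is the signed channel-axis
    coordinate.
    """
    rng = np.random.default_rng(seed)
    kT = potential.kT
    dt = params.timestep
    D = params.diffusion
    drift = D / kT * dt
    step_sd = math.sqrt(2 * D * dt)
    bias = _GridBias(0.0, potential.wall_radius + 5.0, params.gaussian_width / 5.0)
    gamma = params.bias_factor

    pos = np.array(start, dtype=float)
    positions = np.empty((n_steps, 2))
    hills = []
    avg = np.zeros_like(bias.values)
    n_avg = 0
    burn_in_deposits = max(1, n_steps // params.deposit_interval // 2)
    for step in range(n_steps):
        if step > 0 and step % params.deposit_interval == 0:
            r = float(np.linalg.norm(pos))
            height = params.initial_height * math.exp(
                -bias(r) / ((gamma - 1.0) * kT)
            )
            bias.deposit(r, params.gaussian_width, height)
            hills.append(
                {
                    "step": step,
                    "center": r,
                    "width": params.gaussian_width,
                    "height": height,
                }
            )
            if len(hills) > burn_in_deposits:
                avg += bias.values
                n_avg += 1
        r = float(np.linalg.norm(pos))
        grad = potential.gradient(pos[0], pos[1])
        if r > 1e-9:
            grad += bias.force(r) * pos / r
        delta = -drift * grad + step_sd * rng.normal(size=2)
        if np.any(np.abs(delta) > 5 * params.gaussian_width):
            raise FloatingPointError(
                f"divergent step |dx|={np.abs(delta).max():.2f} Å at step {step}; "
                "reduce the timestep"
            )
        pos = pos + delta
        positions[step] = pos
    times = dt * np.arange(n_steps)
    rtrace = np.linalg.norm(positions, axis=1)
    trace = CVTrace(r=rtrace, z=positions[:, 1], times=times)
    hills_df = pd.DataFrame(hills, columns=["step", "center", "width", "height"])
    bias_avg = avg / n_avg if n_avg else bias.values.copy()
    return MetadynamicsResult(
        trace=trace,
        positions=positions,
        hills=hills_df,
        bias_grid=bias.grid.copy(),
        bias=bias.values.copy(),
        bias_time_average=bias_avg,
    )


def simulate_wt_metadynamics_1d(
    potential_fn,
    params: MetadynamicsParams,
    n_steps: int,
    seed: int = 0,
    start: float = 0.0,
    domain: tuple[float, float] = (-5.0, 5.0),
    kT: float = 0.596,
) -> MetadynamicsResult:
    """1D variant (CV = x) for free-energy reconstruction checks."""
    rng = np.random.default_rng(seed)
    dt, D = params.timestep, params.diffusion
    drift = D / kT * dt
    step_sd = math.sqrt(2 * D * dt)
    bias = _GridBias(domain[0], domain[1], params.gaussian_width / 5.0)
    gamma = params.bias_factor
    h = 1e-5

    x = float(start)
    positions = np.empty(n_steps)
    hills = []
    avg = np.zeros_like(bias.values)
    n_avg = 0
    burn_in_deposits = max(1, n_steps // params.deposit_interval // 2)
    for step in range(n_steps):
        if step > 0 and step % params.deposit_interval == 0:
            height = params.initial_height * math.exp(-bias(x) / ((gamma - 1.0) * kT))
            bias.deposit(x, params.gaussian_width, height)
            hills.append(
                {"step": step, "center": x, "width": params.gaussian_width, "height": height}
            )
            if len(hills) > burn_in_deposits:
                avg += bias.values
                n_avg += 1
        grad = (potential_fn(x + h) - potential_fn(x - h)) / (2 * h) + bias.force(x)
        delta = -drift * grad + step_sd * rng.normal()
        if abs(delta) > 5 * params.gaussian_width:
            raise FloatingPointError(
                f"divergent step |dx|={abs(delta):.2f} Å at step {step}; "
                "reduce the timestep"
            )
        x += delta
        x = min(max(x, domain[0]), domain[1])  # reflective domain edges
        positions[step] = x
    times = dt * np.arange(n_steps)
    trace = CVTrace(r=np.abs(positions), z=positions, times=times)
    bias_avg = avg / n_avg if n_avg else bias.values.copy()
    return MetadynamicsResult(
        trace=trace,
        positions=positions[:, None],
        hills=pd.DataFrame(hills, columns=["step", "center", "width", "height"]),
        bias_grid=bias.grid.copy(),
        bias=bias.values.copy(),
        bias_time_average=bias_avg,
    )


def reconstruct_fes(bias_values: np.ndarray, bias_factor: float) -> np.ndarray:
    """Free-energy estimate from the well-tempered bias.

    At convergence V_bias -> -(1 - 1/gamma) F, so
    F = -(gamma/(gamma-1)) V_bias, up to an additive constant.
    """
    g = bias_factor
    return -(g / (g - 1.0)) * np.asarray(bias_values, dtype=float)


def embed_trace(toy: ToyComplex, positions: np.ndarray) -> Trajectory:
    """Embed 2D toy (x, z) ligand-centre positions into the 3D toy complex.

    The ligand is rigidly translated so its heavy-atom centre sits at
    pocket_center + x * ex + z * n, where n is the front-positive plane
    normal of the reference pocket frame and ex an in-plane unit vector.
    Used to verify that the 3D collective-variable machinery recovers the
    toy's (r, z) exactly.
    """
    from .pocket_geometry import pocket_frame

    top = toy.topology
    pf = pocket_frame(toy.reference, top, toy.pocket_spec)
    n = pf.normal
    ex = np.array([1.0, 0.0, 0.0])
    ex = ex - (ex @ n) * n
    ex /= np.linalg.norm(ex)
    lig_idx = top.heavy_indices(top.residue_atom_indices(toy.ligand_residue))
    lig_center = toy.reference[lig_idx].mean(axis=0)
    coords = np.repeat(toy.reference[None], len(positions), axis=0)
    all_lig = top.segment_indices(Segment.LIGAND)
    for f, (x, z) in enumerate(positions):
        target = pf.pocket_center + x * ex + z * n
        coords[f, all_lig] += target - lig_center
    return Trajectory(top, coords)
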