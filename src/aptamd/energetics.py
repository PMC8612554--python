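"""MM-PBSA end-state binding free energies and per-nucleotide decomposition.

The binding free energy is assembled from five components,

    dG_bind = dE_ele + dE_vdW + dG_pol + dG_nonpol - T*dS,

where dE_ele and dE_vdW are the intermolecular Coulomb and Lennard-Jones
energies (no cutoff), dG_pol is the finite-difference Poisson-Boltzmann
reaction-field difference between the complex and the separated partners,
dG_nonpol = gamma*SASA + beta, and the entropy combines quantum-harmonic-
oscillator vibrational terms with rigid-rotor rotational and Sackur-Tetrode
translational terms.  A single-trajectory protocol is assumed: receptor and
ligand coordinates are taken from the complex snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import constants
from scipy.spatial.distance import cdist

from .model_io import Segment, Topology
from .pb import PBResult, solve_pb_charges

__all__ = [
    "EnergeticsConfig",
    "EnergyComponents",
    "coulomb_inter",
    "lj_inter",
    "sasa",
    "nonpolar_term",
    "solve_pb",
    "pb_delta",
    "entropy_terms",
    "mmpbsa_summary",
    "per_residue_decomposition",
    "dg_from_kd",
]

#: gas constant in kcal/(mol K)
R_KCAL = 1.9872e-3


@dataclass(frozen=True)
class EnergeticsConfig:
    coulomb_constant: float = 332.0636  # kcal Å / (mol e^2)
    eps_solute: float = 1.0
    eps_solvent: float = 80.0
    pb_grid_spacing: float = 0.4  # Å
    pb_iterations: int = 5000
    pb_tolerance: float | None = 1e-8  # early exit once the SOR residual converges
    pb_omega: float = 1.9
    pb_padding_fraction: float = 0.3
    pb_min_padding: float = 6.0  # Å
    probe_radius: float = 1.4  # Å
    gamma_np: float = 0.00542  # kcal/(mol Å^2)
    beta_np: float = 0.92  # kcal/mol
    temperature: float = 300.0  # K
    pressure_atm: float = 1.0
    sasa_sphere_points: int = 960

    def __post_init__(self):
        if self.pb_grid_spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if not (self.eps_solvent > self.eps_solute >= 1):
            raise ValueError("require eps_solvent > eps_solute >= 1")


COMPONENT_KEYS = ("dE_ele", "dE_vdW", "dG_pol", "dG_nonpol")


@dataclass
class EnergyComponents:
    """MM-PBSA terms (kcal/mol) with replicate SEMs.

    Identities (checked on construction): dH is the sum of the four
    enthalpic components; dG_bind = dH - TdS.
    """

    dE_ele: float
    dE_vdW: float
    dG_pol: float
    dG_nonpol: float
    TdS: float
    sem: dict = field(default_factory=dict)
    n_replicates: int = 1

    @property
    def dH(self) -> float:
        return self.dE_ele + self.dE_vdW + self.dG_pol + self.dG_nonpol

    @property
    def dG_bind(self) -> float:
        return self.dH - self.TdS

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in (*COMPONENT_KEYS, "dH", "TdS", "dG_bind"):
            rows.append(
                {
                    "term": key,
                    "value_kcal_mol": getattr(self, key),
                    "sem_kcal_mol": self.sem.get(key, float("nan")),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gas-phase intermolecular terms


def _pair_distances(coordsA, coordsB):
    r = cdist(np.atleast_2d(coordsA), np.atleast_2d(coordsB))
    if np.any(r < 1e-6):
        raise ValueError("overlapping atoms (r < 1e-6 Å): Coulomb/LJ singular")
    return r


def coulomb_inter(coordsA, chargesA, coordsB, chargesB, config: EnergeticsConfig) -> float:
    """Intermolecular Coulomb energy, all cross pairs, no cutoff (kcal/mol)."""
    r = _pair_distances(coordsA, coordsB)
    qq = np.outer(chargesA, chargesB)
    return float(config.coulomb_constant * np.sum(qq / r))


def lj_inter(coordsA, paramsA, coordsB, paramsB, config: EnergeticsConfig) -> float:
    """Intermolecular 12-6 Lennard-Jones energy in Rmin/epsilon form.

    ``params`` are (rmin_half, epsilon) arrays; Lorentz-Berthelot combination
    R_ij = rmin_half_i + rmin_half_j, eps_ij = sqrt(eps_i eps_j).
    """
    rmA, epsA = np.asarray(paramsA[0], float), np.asarray(paramsA[1], float)
    rmB, epsB = np.asarray(paramsB[0], float), np.asarray(paramsB[1], float)
    r = _pair_distances(coordsA, coordsB)
    rij = rmA[:, None] + rmB[None, :]
    eij = np.sqrt(np.outer(epsA, epsB))
    x = (rij / r) ** 6
    return float(np.sum(eij * (x * x - 2.0 * x)))


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley sphere points)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(coords, radii, config: EnergeticsConfig) -> tuple[np.ndarray, float]:
    """Solvent-accessible surface area: (per-atom Å², total Å²).

    Sphere points on each probe-inflated atom sphere are tested against all
    neighbouring inflated spheres; the accessible fraction scales the exact
    sphere area, so per-atom areas sum to the total by construction.
    """
    coords = np.atleast_2d(np.asarray(coords, float))
    radii = np.asarray(radii, float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    inflated = radii + config.probe_radius
    pts = _sphere_points(config.sasa_sphere_points)
    n = len(coords)
    areas = np.zeros(n)
    for i in range(n):
        surface = coords[i] + inflated[i] * pts
        accessible = np.ones(len(pts), dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d = np.linalg.norm(surface - coords[j], axis=1)
            accessible &= d >= inflated[j]
        areas[i] = 4 * np.pi * inflated[i] ** 2 * accessible.mean()
    return areas, float(areas.sum())


def nonpolar_term(sasa_total: float, config: EnergeticsConfig) -> float:
    """Nonpolar solvation estimate gamma*SASA + beta (kcal/mol)."""
    if sasa_total < 0:
        raise ValueError("SASA must be non-negative")
    return config.gamma_np * sasa_total + config.beta_np


# ---------------------------------------------------------------------------
# Poisson-Boltzmann solvation


def solve_pb(topology: Topology, coords: np.ndarray, config: EnergeticsConfig,
             charges: np.ndarray | None = None) -> PBResult:
    """Polar solvation energy of the given (sub)system, kcal/mol."""
    if charges is None:
        charges = topology.charges()
    radii = np.array([a.pb_radius for a in topology.atoms])
    if np.any(np.isnan(charges)) or np.any(np.isnan(radii)):
        raise ValueError("topology not parameterized; run attach_parameters first")
    return solve_pb_charges(
        coords,
        charges,
        radii,
        spacing=config.pb_grid_spacing,
        iterations=config.pb_iterations,
        eps_solute=config.eps_solute,
        eps_solvent=config.eps_solvent,
        probe_radius=config.probe_radius,
        k_coulomb=config.coulomb_constant,
        omega=config.pb_omega,
        padding_fraction=config.pb_padding_fraction,
        min_padding=config.pb_min_padding,
        tolerance=config.pb_tolerance,
    )


def pb_delta(
    topology: Topology,
    coords: np.ndarray,
    receptor_idx: np.ndarray,
    ligand_idx: np.ndarray,
    config: EnergeticsConfig,
    charges: np.ndarray | None = None,
) -> float:
    """dG_pol = G_pol(complex) - G_pol(receptor) - G_pol(ligand).

    Single-trajectory protocol: the separated states reuse the complex
    coordinates.  Each state gets its own auto-sized grid at the same
    spacing.
    """
    if charges is None:
        charges = topology.charges()
    g_c = solve_pb(topology, coords, config, charges=charges).energy
    rec = topology.subset(receptor_idx)
    lig = topology.subset(ligand_idx)
    g_r = solve_pb(rec, coords[receptor_idx], config, charges=charges[receptor_idx]).energy
    g_l = solve_pb(lig, coords[ligand_idx], config, charges=charges[ligand_idx]).energy
    return g_c - g_r - g_l


# ---------------------------------------------------------------------------
# Entropy


def entropy_terms(
    frequencies_cm1,
    mass_amu: float,
    principal_moments_amu_A2,
    config: EnergeticsConfig,
    symmetry_number: int = 1,
) -> dict:
    """T*S contributions (kcal/mol) for one species at config.temperature.

    Vibrational: each mode as a quantum harmonic oscillator,
    S_vib/R = x/(e^x - 1) - ln(1 - e^-x) with x = h*c*nu/kT.
    Translational: Sackur-Tetrode at the configured pressure.
    Rotational: classical rigid rotor from the principal moments of inertia.
    """
    freqs = np.asarray(frequencies_cm1, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive; filter zero/imaginary modes")
    T = config.temperature
    x = constants.h * constants.c * 100.0 * freqs / (constants.k * T)
    s_vib = R_KCAL * np.sum(x / np.expm1(x) - np.log(-np.expm1(-x)))

    m = mass_amu * constants.atomic_mass
    V = constants.k * T / (config.pressure_atm * constants.atm)
    lam3 = (2 * np.pi * m * constants.k * T / constants.h**2) ** 1.5
    s_trans = R_KCAL * (np.log(lam3 * V) + 2.5)

    I = np.asarray(principal_moments_amu_A2, dtype=float) * constants.atomic_mass * 1e-20
    rot = (8 * np.pi**2 * constants.k * T / constants.h**2) ** 1.5
    s_rot = R_KCAL * (
        np.log(np.sqrt(np.pi * np.prod(I)) * rot / symmetry_number) + 1.5
    )
    return {
        "TS_vib": float(T * s_vib),
        "TS_trans": float(T * s_trans),
        "TS_rot": float(T * s_rot),
        "TS_total": float(T * (s_vib + s_trans + s_rot)),
    }


# ---------------------------------------------------------------------------
# Assembly and statistics


def mmpbsa_summary(
    replicate_components,
    TdS_per_replicate,
    config: EnergeticsConfig | None = None,
) -> EnergyComponents:
    """Average per-frame components per replicate, then mean ± SEM across
    replicates, assembled into dH and dG_bind.

    ``replicate_components`` is a sequence of DataFrames (one per replicate)
    with columns dE_ele, dE_vdW, dG_pol, dG_nonpol, one row per frame.
    ``TdS_per_replicate`` holds one T*dS value per replicate (kcal/mol).
    """
    reps = list(replicate_components)
    TdS = np.asarray(TdS_per_replicate, dtype=float)
    if len(reps) == 0 or len(TdS) != len(reps):
        raise ValueError("need >=1 replicate and one TdS per replicate")
    per_rep = []
    for df in reps:
        df = pd.DataFrame(df)
        if len(df) == 0:
            raise ValueError("replicate with zero frames")
        per_rep.append([df[k].mean() for k in COMPONENT_KEYS])
    arr = np.asarray(per_rep)  # (n_rep, 4)
    n = len(reps)
    means = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(4)
    dH_rep = arr.sum(axis=1)
    dG_rep = dH_rep - TdS
    sems = dict(zip(COMPONENT_KEYS, sem))
    if n > 1:
        sems["dH"] = float(dH_rep.std(ddof=1) / math.sqrt(n))
        sems["TdS"] = float(TdS.std(ddof=1) / math.sqrt(n))
        sems["dG_bind"] = float(dG_rep.std(ddof=1) / math.sqrt(n))
    return EnergyComponents(
        dE_ele=float(means[0]),
        dE_vdW=float(means[1]),
        dG_pol=float(means[2]),
        dG_nonpol=float(means[3]),
        TdS=float(TdS.mean()),
        sem={k: float(v) for k, v in sems.items()},
        n_replicates=n,
    )


# ---------------------------------------------------------------------------
# Per-residue decomposition


def per_residue_decomposition(
    topology: Topology,
    coords_ensemble: np.ndarray,
    config: EnergeticsConfig,
    include_pol: bool = True,
) -> pd.DataFrame:
    """Decompose the enthalpic components into per-nucleotide contributions.

    dE_ele and dE_vdW are pairwise-exact: each RNA residue receives its pair
    sums with the ligand, so residue contributions add up to the totals.
    dG_nonpol uses per-atom SASA differences (complex minus separated)
    scaled by gamma; RNA-atom terms are assigned to their residues and the
    ligand-atom terms plus the -beta offset to the ligand row, keeping the
    column sum equal to the total.  dG_pol (optional, PB-expensive) uses
    charge annihilation — zero one residue's charges, re-solve, difference —
    an approximate scheme because the PB response is not strictly additive.

    ``coords_ensemble`` has shape (n_frames, n_atoms, 3); contributions are
    averaged over frames.
    """
    coords_ensemble = np.asarray(coords_ensemble, dtype=float)
    if coords_ensemble.ndim == 2:
        coords_ensemble = coords_ensemble[None]
    rec_idx = topology.segment_indices(Segment.RNA)
    lig_idx = topology.segment_indices(Segment.LIGAND)
    if len(lig_idx) == 0:
        raise ValueError("no ligand atoms in topology")
    charges = topology.charges()
    rm = np.array([a.lj_rmin_half for a in topology.atoms])
    eps = np.array([a.lj_epsilon for a in topology.atoms])
    radii = np.array([a.pb_radius for a in topology.atoms])
    residues = sorted({topology.atoms[i].residue_index for i in rec_idx})
    lig_res = topology.atoms[lig_idx[0]].residue_index

    acc: dict[int, np.ndarray] = {r: np.zeros(4) for r in residues}  # ele, vdw, pol, np
    acc[lig_res] = np.zeros(4)
    n_frames = len(coords_ensemble)
    for frame in coords_ensemble:
        r = _pair_distances(frame[rec_idx], frame[lig_idx])
        qq = config.coulomb_constant * np.outer(charges[rec_idx], charges[lig_idx]) / r
        rij = rm[rec_idx][:, None] + rm[lig_idx][None, :]
        eij = np.sqrt(np.outer(eps[rec_idx], eps[lig_idx]))
        x6 = (rij / r) ** 6
        ljm = eij * (x6 * x6 - 2 * x6)
        res_of = np.array([topology.atoms[i].residue_index for i in rec_idx])
        for resi in residues:
            sel = res_of == resi
            acc[resi][0] += qq[sel].sum() / n_frames
            acc[resi][1] += ljm[sel].sum() / n_frames
        # nonpolar: per-atom SASA differences
        per_c, _ = sasa(frame, radii, config)
        per_r, _ = sasa(frame[rec_idx], radii[rec_idx], config)
        per_l, _ = sasa(frame[lig_idx], radii[lig_idx], config)
        datom = np.zeros(topology.n_atoms)
        datom[rec_idx] = per_c[rec_idx] - per_r
        datom[lig_idx] = per_c[lig_idx] - per_l
        for resi in residues:
            sel = rec_idx[res_of == resi]
            acc[resi][3] += config.gamma_np * datom[sel].sum() / n_frames
        acc[lig_res][3] += (
            config.gamma_np * datom[lig_idx].sum() - config.beta_np
        ) / n_frames
        if include_pol:
            total_pol = pb_delta(topology, frame, rec_idx, lig_idx, config)
            for resi in residues:
                q0 = charges.copy()
                q0[topology.residue_atom_indices(resi)] = 0.0
                pol0 = pb_delta(topology, frame, rec_idx, lig_idx, config, charges=q0)
                acc[resi][2] += (total_pol - pol0) / n_frames

    rows = []
    for resi in sorted(acc):
        ele, vdw, pol, np_ = acc[resi]
        name = next(
            a.residue_name for a in topology.atoms if a.residue_index == resi
        )
        rows.append(
            {
                "residue_index": resi,
                "residue_name": name,
                "dE_ele": ele,
                "dE_vdW": vdw,
                "dG_pol": pol,
                "dG_nonpol": np_,
                "total": ele + vdw + pol + np_,
            }
        )
    return pd.DataFrame(rows)


def contribution_correlation(vectors: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix between per-residue total-contribution
    vectors of different complexes (columns = complexes)."""
    return vectors.corr(method="pearson")


def dg_from_kd(kd_molar: float, temperature: float = 300.0) -> float:
    """Experimental binding free energy RT ln K_D (kcal/mol)."""
    if kd_molar <= 0:
        raise ValueError("K_D must be positive")
    return R_KCAL * temperature * math.log(kd_molar)
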