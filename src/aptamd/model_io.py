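"""Domain types and readers/writers for structures, trajectories and result tables.

Conventions used across the package: coordinates and lengths in Å, energies in
kcal/mol, times in ps, charges in elementary charge units.  Residue indices are
1-based author numbering as printed in the source structure files.
"""

from __future__ import annotations

import enum
import json
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "AtomRecord",
    "Topology",
    "Trajectory",
    "ReferenceSite",
    "PDBParseError",
    "ParameterError",
    "read_structure",
    "write_structure",
    "read_parameter_table",
    "attach_parameters",
    "read_reference_sites",
    "write_reference_sites",
    "write_tsv",
    "write_dx",
    "read_dx",
    "write_manifest",
]

#: residue names recognised as standard (ribo)nucleotides
NUCLEOTIDE_NAMES = frozenset(
    {"A", "U", "G", "C", "RA", "RU", "RG", "RC", "ADE", "URA", "GUA", "CYT"}
)
#: residue names recognised as monatomic ions
ION_NAMES = frozenset({"MG", "NA", "CL", "K", "MN", "ZN", "CA", "SR", "CS", "BR"})


class Segment(enum.Enum):
    RNA = "RNA"
    LIGAND = "LIGAND"
    ION = "ION"
    OTHER = "OTHER"


class PDBParseError(ValueError):
    """Raised for malformed or unsupported PDB content."""


class ParameterError(ValueError):
    """Raised when a parameter table does not cover the topology."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its per-atom force-field / continuum parameters.

    ``charge`` is in elementary charges, ``lj_rmin_half`` and ``pb_radius``
    in Å, ``lj_epsilon`` in kcal/mol.  Parameters default to NaN until
    :func:`attach_parameters` fills them in.
    """

    serial: int
    atom_name: str
    residue_name: str
    residue_index: int
    segment: Segment
    element: str = ""
    charge: float = float("nan")
    lj_rmin_half: float = float("nan")
    lj_epsilon: float = float("nan")
    pb_radius: float = float("nan")


@dataclass
class Topology:
    """Ordered atom list plus a derived residue table."""

    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for a in self.atoms:
            key = (a.residue_index, a.atom_name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in topology")
            seen.add(key)
        self._index = {(a.residue_index, a.atom_name): i for i, a in enumerate(self.atoms)}

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> pd.DataFrame:
        rows: dict[int, tuple[str, str]] = {}
        for a in self.atoms:
            rows.setdefault(a.residue_index, (a.residue_name, a.segment.value))
        return pd.DataFrame(
            [(i, n, s) for i, (n, s) in sorted(rows.items())],
            columns=["residue_index", "residue_name", "segment"],
        )

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """Index of the atom identified by (author residue number, atom name)."""
        try:
            return self._index[(residue_index, atom_name)]
        except KeyError:
            raise KeyError(
                f"atom ({residue_index}, {atom_name!r}) not found in topology"
            ) from None

    def atom_indices(self, selection: Iterable[tuple[int, str]]) -> np.ndarray:
        return np.array([self.atom_index(r, n) for r, n in selection], dtype=int)

    def segment_indices(self, segment: Segment) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.segment is segment], dtype=int
        )

    def residue_atom_indices(self, residue_index: int) -> np.ndarray:
        idx = np.array(
            [i for i, a in enumerate(self.atoms) if a.residue_index == residue_index],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(f"residue {residue_index} not found in topology")
        return idx

    def heavy_indices(self, atom_indices: Iterable[int] | None = None) -> np.ndarray:
        pool = range(self.n_atoms) if atom_indices is None else atom_indices
        return np.array(
            [i for i in pool if self.atoms[i].element.upper() != "H"], dtype=int
        )

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def segment_net_charges(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for a in self.atoms:
            out[a.segment.value] = out.get(a.segment.value, 0.0) + a.charge
        return out

    def subset(self, atom_indices: Sequence[int]) -> "Topology":
        return Topology([self.atoms[i] for i in atom_indices])


@dataclass
class Trajectory:
    """Frames of Cartesian coordinates (Å) with per-frame times (ps)."""

    topology: Topology
    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} != "
                f"topology size {self.topology.n_atoms}"
            )
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_frames,):
                raise ValueError("times length must equal number of frames")
            if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
                raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class ReferenceSite:
    """A labelled reference position, e.g. a crystallographic metal site."""

    label: str
    position: tuple[float, float, float]
    source: str = ""


# ---------------------------------------------------------------------------
# PDB reading / writing


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray, str]:
    name = line[12:16].strip()
    altloc = line[16:17].strip()
    resname = line[17:21].strip()
    try:
        serial = int(line[6:11])
        resseq = int(line[22:26])
    except ValueError:
        raise PDBParseError(f"line {lineno}: unparseable serial/residue number") from None
    icode = line[26:27].strip()
    if icode:
        raise PDBParseError(
            f"line {lineno}: insertion code {icode!r} not supported"
        )
    try:
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
    except ValueError:
        raise PDBParseError(f"line {lineno}: unparseable coordinate field") from None
    element = line[76:78].strip() if len(line) >= 77 else ""
    if not element:
        # fall back on the leading letter of the atom name
        element = next((c for c in name if c.isalpha()), "")
    rec = AtomRecord(
        serial=serial,
        atom_name=name,
        residue_name=resname,
        residue_index=resseq,
        segment=Segment.OTHER,  # assigned later
        element=element,
    )
    return rec, xyz, altloc


def _assign_segment(rec: AtomRecord, is_hetatm: bool, ligand_names: frozenset[str]) -> Segment:
    rn = rec.residue_name.upper()
    if rn in ligand_names:
        return Segment.LIGAND
    if rn in NUCLEOTIDE_NAMES:
        return Segment.RNA
    if rn in ION_NAMES or (is_hetatm and rec.element.upper() in ION_NAMES):
        return Segment.ION
    return Segment.OTHER


def read_structure(text: str, ligand_resnames: Iterable[str] = ("LIG",)) -> Trajectory:
    """Parse multi-model PDB text into a :class:`Trajectory`.

    One frame per MODEL block (a file without MODEL records is a single
    implicit model).  HETATM ions get segment ION, residues named in
    ``ligand_resnames`` become LIGAND, standard nucleotides RNA, the rest
    OTHER.  Only the first alternate location of an atom is kept; insertion
    codes are rejected.
    """
    ligand_names = frozenset(n.upper() for n in ligand_resnames)
    models: list[list[tuple[AtomRecord, np.ndarray, bool]]] = []
    current: list[tuple[AtomRecord, np.ndarray, bool]] = []
    seen_altloc: set[tuple[int, str]] = set()
    in_model = False
    model_label = "1"
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            if in_model:
                raise PDBParseError(f"line {lineno}: nested MODEL record")
            if current and not models:
                raise PDBParseError(
                    f"line {lineno}: MODEL record after implicit-model atoms"
                )
            in_model = True
            model_label = line[6:].strip() or str(len(models) + 1)
            current = []
            seen_altloc = set()
        elif record == "ENDMDL":
            if not in_model:
                raise PDBParseError(f"line {lineno}: ENDMDL without MODEL")
            _check_model(current, models, model_label)
            models.append(current)
            in_model = False
        elif record in ("ATOM", "HETATM"):
            rec, xyz, altloc = _parse_atom_line(line, lineno)
            key = (rec.residue_index, rec.atom_name)
            if altloc:
                if key in seen_altloc:
                    continue  # keep first altloc only
                seen_altloc.add(key)
            current.append((rec, xyz, record == "HETATM"))
    if in_model:
        raise PDBParseError(f"model {model_label}: missing ENDMDL")
    if current and not models:
        models.append(current)
    if not models:
        raise PDBParseError("no ATOM/HETATM records found")

    first = models[0]
    atoms = [
        replace(rec, segment=_assign_segment(rec, het, ligand_names))
        for rec, _, het in first
    ]
    coords = np.stack([np.array([xyz for _, xyz, _ in m]) for m in models])
    return Trajectory(Topology(atoms), coords)


def _check_model(
    current: list[tuple[AtomRecord, np.ndarray, bool]],
    models: list[list[tuple[AtomRecord, np.ndarray, bool]]],
    label: str,
) -> None:
    if not models:
        return
    ref = models[0]
    if len(current) != len(ref):
        raise PDBParseError(
            f"model {label}: {len(current)} atoms, expected {len(ref)}"
        )
    for (a, _, _), (b, _, _) in zip(current, ref):
        if (a.residue_index, a.atom_name) != (b.residue_index, b.atom_name):
            raise PDBParseError(
                f"model {label}: atom order differs at "
                f"({a.residue_index}, {a.atom_name!r})"
            )


def write_structure(trajectory: Trajectory) -> str:
    """Serialise a trajectory as multi-model PDB text (fixed columns)."""
    lines: list[str] = []
    multi = trajectory.n_frames > 1
    for f in range(trajectory.n_frames):
        if multi:
            lines.append(f"MODEL     {f + 1:>4d}")
        for i, atom in enumerate(trajectory.topology.atoms):
            x, y, z = trajectory.coordinates[f, i]
            record = "ATOM  " if atom.segment is Segment.RNA else "HETATM"
            name = atom.atom_name
            # PDB name column convention: start in col 14 unless 4 chars
            name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
            lines.append(
                f"{record}{atom.serial % 100000:>5d} {name_field}"
                f" {atom.residue_name:<4s}A{atom.residue_index:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Parameter tables

PARAM_COLUMNS = ["residue_name", "atom_name", "charge_e", "rmin_half_A", "epsilon_kcal", "pb_radius_A"]


def read_parameter_table(text: str) -> pd.DataFrame:
    """Read a TSV parameter table keyed by (residue_name, atom_name)."""
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", comment="#")
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"parameter table missing columns: {missing}")
    return df


def attach_parameters(topology: Topology, table: pd.DataFrame | str) -> Topology:
    """Return a copy of *topology* with per-atom parameters filled from *table*.

    Every atom must have a (residue_name, atom_name) entry; otherwise a
    :class:`ParameterError` listing all unmatched atoms is raised.
    """
    if isinstance(table, str):
        table = read_parameter_table(table)
    lookup = {
        (str(r.residue_name), str(r.atom_name)): r for r in table.itertuples(index=False)
    }
    unmatched = [
        (a.residue_name, a.atom_name)
        for a in topology.atoms
        if (a.residue_name, a.atom_name) not in lookup
    ]
    if unmatched:
        raise ParameterError(f"no parameters for atoms: {unmatched}")
    new_atoms = []
    for a in topology.atoms:
        row = lookup[(a.residue_name, a.atom_name)]
        if row.pb_radius_A < 0 or row.epsilon_kcal < 0:
            raise ParameterError(
                f"negative radius/epsilon for ({a.residue_name}, {a.atom_name})"
            )
        new_atoms.append(
            replace(
                a,
                charge=float(row.charge_e),
                lj_rmin_half=float(row.rmin_half_A),
                lj_epsilon=float(row.epsilon_kcal),
                pb_radius=float(row.pb_radius_A),
            )
        )
    return Topology(new_atoms)


# ---------------------------------------------------------------------------
# Reference sites


def read_reference_sites(
    text: str, element_filter: str, labels: Sequence[str] | None = None
) -> list[ReferenceSite]:
    """Extract HETATM positions matching *element_filter* as labelled sites.

    Sites are labelled M1, M2, ... in file order unless *labels* is given.
    """
    sites: list[ReferenceSite] = []
    want = element_filter.strip().upper()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6].strip() != "HETATM":
            continue
        rec, xyz, _ = _parse_atom_line(line, lineno)
        if rec.element.upper() != want and rec.residue_name.upper() != want:
            continue
        label = labels[len(sites)] if labels else f"M{len(sites) + 1}"
        sites.append(ReferenceSite(label=label, position=tuple(xyz), source="pdb"))
    return sites


def write_reference_sites(sites: Sequence[ReferenceSite], element: str = "MN") -> str:
    lines = []
    for i, s in enumerate(sites, start=1):
        x, y, z = s.position
        lines.append(
            f"HETATM{i:>5d} {element:<3s} {element:<4s}A{i:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Result export


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_dx(density, path: str | Path) -> Path:
    """Write a GridDensity (or anything with origin/spacing/counts) as OpenDX."""
    from gridData import Grid

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    counts = np.asarray(density.counts, dtype=float)
    g = Grid(
        counts,
        origin=np.asarray(density.origin, dtype=float),
        delta=float(density.spacing),
    )
    g.export(str(path), file_format="dx")
    return path


def read_dx(path: str | Path):
    """Read an OpenDX grid back as (origin, spacing, counts)."""
    from gridData import Grid

    g = Grid(str(path))
    delta = np.asarray(g.delta)
    spacing = float(delta[0] if delta.ndim else delta)
    return np.asarray(g.origin, dtype=float), spacing, np.asarray(g.grid)


def write_manifest(path: str | Path, config: Mapping, seed: int | None = None) -> Path:
    """Write a machine-readable run manifest (config echo, seed, versions)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": _jsonable(config),
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
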