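"""End-to-end orchestration: simulate-or-load -> analyze -> report.

A :class:`RunConfig` (typically loaded from YAML) names the stages to run,
the selections and thresholds, and the output directory.  All selections
are validated against the topology before any analysis starts, so a bad
config fails fast with every problem reported at once.  Every run writes a
machine-readable manifest (config echo, seed, package versions) so outputs
are regenerable.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthetic_data as syn
from .energetics import (
    EnergeticsConfig,
    coulomb_inter,
    lj_inter,
    mmpbsa_summary,
    nonpolar_term,
    pb_delta,
    sasa,
)
from .model_io import Segment, Trajectory, write_dx, write_manifest, write_tsv
from .pocket_geometry import DistanceDefinition, distance_series, cv_trace, grid_density
from .stacking_hbonds import hbond_occupancy, stacking_summary
from .unbinding_events import detect_events, tabulate_events

logger = logging.getLogger("aptamd")

DEFAULT_STAGES = ("simulate", "stacking", "hbonds", "geometry", "events", "energetics")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    output_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_frames: int = 500
    metadynamics_steps: int = 60_000
    metadynamics_runs: int = 3
    r_unbind: float = 9.0
    r_rebind: float = 1.0
    stacking_margin: float = 0.5
    pocket: syn.ToyPocketSpec = field(default_factory=syn.ToyPocketSpec)
    program: syn.OccupancyProgram = field(default_factory=syn.OccupancyProgram)
    potential: syn.ToyPotentialSpec = field(default_factory=syn.ToyPotentialSpec)
    metad: syn.MetadynamicsParams = field(default_factory=syn.MetadynamicsParams)
    energetics: EnergeticsConfig = field(default_factory=EnergeticsConfig)
    distances: tuple[DistanceDefinition, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        kwargs["output_dir"] = Path(raw.get("output_dir", "results"))
        for key in (
            "seed",
            "stages",
            "n_frames",
            "metadynamics_steps",
            "metadynamics_runs",
            "r_unbind",
            "r_rebind",
            "stacking_margin",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        for key, typ in (
            ("pocket", syn.ToyPocketSpec),
            ("program", syn.OccupancyProgram),
            ("potential", syn.ToyPotentialSpec),
            ("metad", syn.MetadynamicsParams),
            ("energetics", EnergeticsConfig),
        ):
            if key in raw:
                kwargs[key] = typ(**raw[key])
        if "distances" in raw:
            kwargs["distances"] = tuple(
                DistanceDefinition(
                    label=d["label"],
                    atom_a=(int(d["atom_a"][0]), str(d["atom_a"][1])),
                    atom_b=(int(d["atom_b"][0]), str(d["atom_b"][1])),
                )
                for d in raw["distances"]
            )
        return cls(**kwargs)


def validate_config(config: RunConfig, toy: syn.ToyComplex) -> list[str]:
    """Collect all selection-resolution problems before any compute."""
    problems = []
    top = toy.topology
    for d in config.distances:
        for pair in (d.atom_a, d.atom_b):
            try:
                top.atom_index(*pair)
            except KeyError:
                problems.append(f"distance {d.label}: unresolvable atom {pair}")
    unknown = set(config.stages) - set(DEFAULT_STAGES) - {"density", "report"}
    for s in sorted(unknown):
        problems.append(f"unknown stage {s!r}")
    if config.r_rebind >= config.r_unbind:
        problems.append("r_rebind must be smaller than r_unbind")
    return problems


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns a dict of output paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    toy = syn.build_toy_complex(config.pocket)
    problems = validate_config(config, toy)
    if problems:
        raise ValueError("config validation failed:\n" + "\n".join(problems))
    outputs: dict[str, Path] = {}
    write_manifest(out / "manifest.json", _echo_config(config), seed=config.seed)
    outputs["manifest"] = out / "manifest.json"

    trajectory = None
    log = None
    if "simulate" in config.stages:
        t0 = time.perf_counter()
        trajectory, log = syn.simulate_bound_trajectory(
            toy, config.program, n_frames=config.n_frames, seed=config.seed
        )
        outputs["state_log"] = write_tsv(log, out / "state_log.tsv")
        logger.info("simulate: %d frames in %.2fs", config.n_frames, time.perf_counter() - t0)

    if "stacking" in config.stages:
        trajectory = trajectory or _require_sim("stacking")
        rows = []
        for label, ringsel in toy.plates.items():
            res = stacking_summary(
                trajectory, toy.ligand_ring, ringsel, margin=config.stacking_margin
            )
            rows.append(
                {
                    "base": label,
                    "in_fraction": res.in_fraction,
                    "mean_vertical_distance_in_A": res.mean_vertical_distance_in,
                    "n_in": res.n_in,
                }
            )
        import pandas as pd

        outputs["stacking"] = write_tsv(pd.DataFrame(rows), out / "stacking.tsv")

    if "hbonds" in config.stages:
        trajectory = trajectory or _require_sim("hbonds")
        occ = hbond_occupancy(trajectory, toy.hbonds)
        outputs["hbonds"] = write_tsv(occ, out / "hbond_occupancy.tsv")

    if "geometry" in config.stages:
        trajectory = trajectory or _require_sim("geometry")
        import pandas as pd

        rows = []
        for d in config.distances or _default_distances():
            s = distance_series(trajectory, d)
            rows.append({"label": s.label, "mean_A": s.mean, "sd_A": s.sd})
        outputs["distances"] = write_tsv(pd.DataFrame(rows), out / "distances.tsv")
        trace = cv_trace(trajectory, toy.ligand_residue, toy.pocket_spec)
        outputs["cv_trace"] = write_tsv(trace.to_frame(), out / "cv_trace.tsv")

    if "density" in config.stages:
        trajectory = trajectory or _require_sim("density")
        lig_idx = trajectory.topology.segment_indices(Segment.LIGAND)
        dens = grid_density(trajectory, lig_idx)
        outputs["ligand_density"] = write_dx(dens, out / "ligand_density.dx")

    if "events" in config.stages:
        import pandas as pd

        event_lists = []
        for k in range(config.metadynamics_runs):
            result = syn.simulate_wt_metadynamics(
                config.potential,
                config.metad,
                n_steps=config.metadynamics_steps,
                seed=config.seed * 1000 + k,
            )
            event_lists.append(
                detect_events(result.trace, config.r_unbind, config.r_rebind)
            )
        table = tabulate_events(event_lists, labels=["toy"] * len(event_lists))
        outputs["events"] = write_tsv(table.to_frame(), out / "event_table.tsv")

    if "energetics" in config.stages:
        # energies are demonstrated on a contact-distance pose: the
        # rectangle-metric toy packs the plates closer than LJ contact
        en_toy = syn.build_toy_complex(
            syn.ToyPocketSpec(
                plate_gap=max(config.pocket.plate_gap, 7.0),
                door_front_width=config.pocket.door_front_width,
                door_back_width=config.pocket.door_back_width,
                hbond_distance=config.pocket.hbond_distance,
                ring_atom_count=config.pocket.ring_atom_count,
                seed=config.pocket.seed,
            )
        )
        outputs["energetics"] = write_tsv(
            _toy_mmpbsa(en_toy, config.energetics), out / "mmpbsa.tsv"
        )
    return outputs


def _require_sim(stage):
    raise ValueError(f"stage {stage!r} requires the 'simulate' stage")


def _default_distances() -> tuple[DistanceDefinition, ...]:
    return (
        DistanceDefinition("d_15-30", (15, "C1'"), (30, "C1'")),
        DistanceDefinition("d_5-11", (5, "C1'"), (11, "C1'")),
    )


def _toy_mmpbsa(toy: syn.ToyComplex, config: EnergeticsConfig):
    """Single-snapshot MM-PBSA of the rigid toy reference structure."""
    import pandas as pd

    top = toy.topology
    coords = toy.reference
    rec = top.segment_indices(Segment.RNA)
    lig = top.segment_indices(Segment.LIGAND)
    q = top.charges()
    rm = np.array([a.lj_rmin_half for a in top.atoms])
    eps = np.array([a.lj_epsilon for a in top.atoms])
    radii = np.array([a.pb_radius for a in top.atoms])
    ele = coulomb_inter(coords[rec], q[rec], coords[lig], q[lig], config)
    vdw = lj_inter(
        coords[rec], (rm[rec], eps[rec]), coords[lig], (rm[lig], eps[lig]), config
    )
    _, sc = sasa(coords, radii, config)
    _, sr = sasa(coords[rec], radii[rec], config)
    _, sl = sasa(coords[lig], radii[lig], config)
    nonpol = nonpolar_term(sc, config) - nonpolar_term(sr, config) - nonpolar_term(sl, config)
    pol = pb_delta(top, coords, rec, lig, config)
    comp = mmpbsa_summary(
        [pd.DataFrame({"dE_ele": [ele], "dE_vdW": [vdw], "dG_pol": [pol], "dG_nonpol": [nonpol]})],
        [0.0],
        config,
    )
    return comp.to_frame()


def _echo_config(config: RunConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    d["output_dir"] = str(d["output_dir"])
    return d
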