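# aptamd

Analysis stack for molecular-dynamics studies of RNA aptamer–ligand
recognition, built around the class-1 PreQ₁ riboswitch aptamer (a 33-nt
H-type pseudoknot that buries its ligand between two base-stacking plates
and a ring of in-plane hydrogen-bond partners).  The package implements,
as tested and reusable code, the full chain of trajectory analyses such a
study needs:

* **Base stacking** by the rectangle-projection metric: a nucleobase is
  "in" when its ring centre projects inside a 0.5 Å-margin rectangle drawn
  around the ligand ring atoms in the ligand-plane frame; the per-ensemble
  *in-fraction* and mean vertical distance summarise the stacking.
* **Hydrogen bonds** with the geometric criterion d(donor, acceptor) < 3.5 Å
  and donor–H–acceptor angle > 120°, including OR-groups of alternative
  acceptors, summarised as occupancies.
* **Pocket geometry**: named distances (d₁₅₋₃₀, d₅₋₁₁, d₄₋₁₃, d₁₄₋₁₆),
  the pocket centre and bisecting plane, the collective variables *r*
  (ligand-centre to pocket-centre distance) and *z* (signed coordinate
  along the front-positive plane normal), the inter-base-stack angle Θ,
  2D CV density maps, and 3D grid densities with crystal-site occupancy
  queries (OpenDX output).
* **Unbinding/rebinding events** from (r, z) traces: a two-state machine
  emits an unbind at the first r ≥ 9 Å and a rebind at the next r ≤ 1 Å,
  classifies each event through the front (z > 0) or back (z < 0) door, and
  tabulates door-resolved counts per ligand.
* **MM-PBSA energetics**:

  ΔG_bind = ΔE_ele + ΔE_vdW + ΔG_pol + ΔG_nonpol − TΔS

  with no-cutoff intermolecular Coulomb and 12-6 Lennard-Jones terms, a
  finite-difference linear Poisson–Boltzmann solver (0.4 Å cubic grid,
  ε = 1/80, molecular surface from a 1.4 Å probe, SOR relaxation),
  ΔG_nonpol = γ·SASA + β with γ = 0.00542 kcal/mol·Å² and β = 0.92
  kcal/mol (Shrake–Rupley SASA), quantum-harmonic-oscillator vibrational +
  rigid-rotor + Sackur–Tetrode entropies, replicate SEMs, per-nucleotide
  decomposition of the enthalpic terms, and ΔG_exp = RT ln K_D.
* **Synthetic data**: a rigid six-nucleotide toy pocket, bound-state
  trajectories whose discrete states (stacked/unstacked, H-bond on/off,
  base parallel/orthogonal, ion site occupancy) follow two-state Markov
  chains with programmed stationary occupancies, and a well-tempered
  metadynamics toy (overdamped Langevin particle, Gaussian hills of width
  0.5 Å and initial height 1.2 kcal/mol tempered with bias factor 15) in a
  two-channel escape potential — so every analyzer is validated against
  known ground truth without any external trajectory data.

## Worked example

Simulate a programmed pocket ensemble and recover its occupancies:

```python
from aptamd import synthetic_data as syn
from aptamd.stacking_hbonds import stacking_summary, hbond_occupancy

toy = syn.build_toy_complex()
prog = syn.OccupancyProgram(stacking_in_fraction={"G5": 0.70, "G11": 0.95, "C16": 0.90})
traj, log = syn.simulate_bound_trajectory(toy, prog, n_frames=5000, seed=1)
res = stacking_summary(traj, toy.ligand_ring, toy.plates["G5"])
print(res.in_fraction, res.mean_vertical_distance_in)
```

prints

```
0.704 1.695016...
```

i.e. the analyzer recovers the programmed 0.70 in-fraction to within
sampling error, and the mean vertical plate distance equals the designed
plate half-gap (1.7 Å) up to positional noise.  The numbered drivers under
`analysis/` run the same machinery end to end:

```sh
python analysis/01_build_toy_complex.py        # designed pocket geometry
python analysis/02_simulate_and_recover_occupancies.py
python analysis/03_pocket_geometry_and_densities.py
python analysis/04_metadynamics_unbinding.py   # door-resolved event table
python analysis/05_mmpbsa_energetics.py        # free-energy tables
```

For instance `04_metadynamics_unbinding.py` prints a door-resolved event
table for the two-channel toy with the front barrier 2 kcal/mol below the
back:

```
 ligand  unbind_front  unbind_back  rebind_front  rebind_back
toy-2ch            33            2            37            3

front-door unbind fraction: 0.94 over 35 events
1D double-well PMF reconstruction RMS: 0.290 kcal/mol over 77 bins
```

A thin CLI wraps the same pipeline (`aptamd demo`, `aptamd run config.yaml`).

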