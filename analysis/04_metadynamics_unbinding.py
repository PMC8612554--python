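#!/usr/bin/env python
"""Biased escape simulations: door-resolved event counts and PMF recovery.

Runs an ensemble of well-tempered metadynamics toy simulations in the
two-channel pocket (front barrier 2 kcal/mol below the back), detects
unbinding/rebinding events with the 9 Å / 1 Å thresholds, and tabulates
them by door.  Also reconstructs the 1D double-well free energy from the
accumulated bias as a convergence control.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from aptamd import synthetic_data as syn
from aptamd.model_io import write_tsv
from aptamd.unbinding_events import detect_events, tabulate_events

OUT = Path("results/analysis")
SEED = 11
N_RUNS = 6
N_STEPS = 200_000


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    pot = syn.ToyPotentialSpec(front_barrier=3.0, back_barrier=5.0)
    event_lists = []
    for k in range(N_RUNS):
        res = syn.simulate_wt_metadynamics(pot, n_steps=N_STEPS, seed=SEED * 100 + k)
        event_lists.append(detect_events(res.trace))
    table = tabulate_events(event_lists, labels=["toy-2ch"] * N_RUNS).to_frame()
    write_tsv(table, OUT / "event_table.tsv")
    print(table.to_string(index=False))
    row = table.iloc[0]
    n_un = row.unbind_front + row.unbind_back
    if n_un:
        print(f"\nfront-door unbind fraction: {row.unbind_front / n_un:.2f} "
              f"over {n_un} events (front barrier 2 kcal/mol lower)")

    B, x0 = 3.0, 2.0
    dw = lambda x: B * ((x / x0) ** 2 - 1.0) ** 2
    params = syn.MetadynamicsParams()
    res = syn.simulate_wt_metadynamics_1d(
        dw, params, n_steps=400_000, seed=SEED, start=-x0, domain=(-4.0, 4.0)
    )
    fes = syn.reconstruct_fes(res.bias_time_average, params.bias_factor)
    grid = res.bias_grid
    hist, _ = np.histogram(res.positions[:, 0], bins=len(grid), range=(grid[0], grid[-1] + 1e-9))
    mask = hist > 50
    diff = fes - dw(grid)
    diff -= diff[mask].mean()
    rms = float(np.sqrt(np.mean(diff[mask] ** 2)))
    pmf = pd.DataFrame({"x_A": grid[mask], "fes_kcal": (fes - fes[mask].min())[mask],
                        "designed_kcal": dw(grid[mask])})
    write_tsv(pmf, OUT / "double_well_pmf.tsv")
    print(f"1D double-well PMF reconstruction RMS: {rms:.3f} kcal/mol "
          f"over {int(mask.sum())} bins")


if __name__ == "__main__":
    main()
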