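"""Recover the length scale of a spatial dependency with a resolution screen.

Data are generated with niche effects acting at 50 um; the screen fits the
linear NCEM at several neighbourhood radii (plus the graph-free baseline on
the same splits) and reports held-out R2.  Peak test R2 should sit at the
generating radius.
"""

import ncem

cfg = ncem.SimulationConfig(n_cells=1000, n_genes=40, interaction_radius=50.0, seed=1)
dataset, _ = ncem.simulate_dependency(cfg)

grid = [15.0, 30.0, 50.0, 80.0, 130.0]
table = ncem.resolution_screen(dataset, grid, variant="interaction", seeds=(0, 1, 2))
summary = table.groupby("resolution")[["ncem_r2", "baseline_r2", "delta_r2"]].mean()
print(summary.round(4).to_string())
print(f"\nbest resolution: {table['best_resolution'].iloc[0]:.0f} um "
      f"(paired t-test vs baseline across splits: p = {table['paired_t_p'].iloc[0]:.2e})")
print("The baseline column is flat because a nonspatial model ignores the graph; "
      "the NCEM column peaks at the radius the data were generated with.")
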