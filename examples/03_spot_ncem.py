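"""Spot NCEM: niche effects from deconvoluted spot transcriptomics.

Cells are binned into square capture spots; the per-(spot, type) mean
expression plays the role of deconvolution output and the per-spot type
counts the role of estimated abundances.  The spot NCEM regresses each
type-in-spot expression vector on the spot composition; the baseline sees
only the target type.
"""

import ncem

cfg = ncem.SimulationConfig(n_cells=2000, n_genes=40, interaction_radius=40.0, seed=2)
spots, cells, truth = ncem.simulate_spots(cfg)
print(f"{spots.n_spots} spots x {spots.n_types} types, "
      f"{int(spots.spot_composition.sum())} cells binned")

fit, summary = ncem.fit_spot_ncem(spots, seeds=(0, 1, 2))
pooled = summary[summary["cell_type"] == "all"]
print(pooled[["seed", "ncem_r2", "baseline_r2", "delta_r2"]].round(4).to_string(index=False))
print("\ndelta_r2 > 0 in each split: spot composition predicts within-type "
      "expression variation, which is exactly the planted niche dependency.")
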