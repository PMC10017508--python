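"""Nonlinear NCEM with indicator and graph-convolution niche encoders.

Trains the neural models with Adam (reduce-on-plateau scheduler, early
stopping) across a learning-rate grid, selecting by validation R2, and
compares them with the nonspatial neural baseline on held-out cells.
"""

import ncem
from ncem.neural import NicheEncoderConfig, TrainingConfig, fit_nl_ncem

cfg = ncem.SimulationConfig(n_cells=500, n_genes=30, interaction_radius=50.0, seed=3)
dataset, _ = ncem.simulate_dependency(cfg)
graph = ncem.build_graph(dataset, 50.0)
splits = ncem.split_nodes(dataset, seed=0)
tc = TrainingConfig(max_epochs=600, nodes_per_image=400)

for label, encoder, spatial in [
    ("indicator, depth 0 (== linear NCEM)", NicheEncoderConfig(depth=0), True),
    ("indicator, depth 1", NicheEncoderConfig(depth=1), True),
    ("graph convolution, depth 1", NicheEncoderConfig(aggregator="gcn", depth=1), True),
    ("nonspatial baseline", NicheEncoderConfig(depth=1), False),
]:
    _, hist, summary = fit_nl_ncem(
        dataset, graph if spatial else None, encoder, tc,
        lr_grid=(0.05, 0.005), splits=splits, spatial=spatial, seed=0,
    )
    print(f"{label:40s} test R2 = {summary['test_r2']:.4f} "
          f"(lr {summary['selected_lr']}, stopped at epoch {hist.best_epoch})")

print("\nSpatial encoders beat the nonspatial baseline on niche-dependent data; "
      "the zero-depth indicator model reproduces the linear NCEM.")
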