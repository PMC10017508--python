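"""CVAE-NCEM: latent cell states, reconstruction, and niche style transfer.

The conditional VAE encodes each cell's expression together with its type,
niche indicator and domain, and decodes it under the same conditions.  Style
transfer decodes one cell's latent state under another cell's niche: if the
decoder attributes the planted niche effect to the conditions, moving a cell
into an effect-bearing niche shifts its predicted expression upward on the
planted genes.

The KL weight controls a trade-off: at the default weight of 1 the posterior
stays close to the prior, reconstruction is moderate, and niche effects live
in the conditions (style transfer works); lowering the weight opens the
latent channel, reconstruction rises sharply, but niche information can leak
into the latent state and the transfer signal fades.
"""

import numpy as np

import ncem
from ncem.cvae import CvaeConfig, CvaeNCEM, style_transfer
from ncem.neural import TrainingConfig, train
from ncem.linear import r_squared

cfg = ncem.SimulationConfig(n_cells=400, n_genes=30, interaction_radius=50.0, seed=5)
dataset, truth = ncem.simulate_dependency(cfg)
graph = ncem.build_graph(dataset, 50.0)
splits = ncem.split_nodes(dataset, seed=0)

model = CvaeNCEM(dataset, graph, CvaeConfig(latent_dim=8, hidden_width=32), seed=0)
train(model, splits, TrainingConfig(max_epochs=800, learning_rate=0.005,
                                    nodes_per_image=400))
mu_train = model.y[splits.train].mean(axis=0)
_, recon = r_squared(model.y[splits.test], model.predict(splits.test), mu_train)
print(f"reconstruction R2 on held-out cells (KL weight 1): {recon:.3f}")

# move type_0 cells without type_1 neighbours into effect-bearing niches
presence = ncem.sender_presence(graph, dataset.type_onehot())
t0 = dataset.cell_type == "type_0"
without = np.flatnonzero(t0 & (presence[:, 1] == 0))
with_n = np.flatnonzero(t0 & (presence[:, 1] > 0))
genes = [int(g.split("_")[1]) for g in truth["effects"].query("receiver == 'type_0'")["gene"]]
rng = np.random.default_rng(0)
shifts = []
for _ in range(20):
    a, b = int(rng.choice(without)), int(rng.choice(with_n))
    delta = style_transfer(model, a, b) - model.predict(np.array([a]))[0]
    shifts.append(np.median(delta[genes]))
print(f"median predicted shift on planted-effect genes over 20 transfers: "
      f"{np.median(shifts):+.2f} (planted effects are 4-6)")
print("A positive shift shows the decoder attributes the niche effect to the "
      "conditions, so transferring a cell into an effect-bearing niche raises "
      "its predicted expression on exactly the planted genes.")
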