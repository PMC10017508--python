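# ncem-niche — node-centric expression models for spatial omics

Cells in a tissue do not express genes in isolation: surface receptors, tight
junctions and soluble factors couple a cell's state to the composition of its
local neighbourhood.  Spatial molecular profiling assays (MERFISH, CODEX,
MIBI-TOF, chip cytometry, deconvoluted Visium) observe both the expression
vector and the position of every cell, which makes that coupling directly
estimable.  This package implements **node-centric expression models (NCEM)**:
models that predict a cell's expression vector from its own type, the
composition of its spatial niche, and batch covariates — and statistical tests
that turn the fitted niche coefficients into cell-type coupling hypotheses.
It is aimed at computational biologists analysing segmented spatial data who
want unbiased (not ligand-list-limited) cell-communication inference, and at
method developers who need a fully simulatable reference implementation.

## The models

Cells in each image form a radius graph: `A_ab = 1` iff `d(x_a, x_b) ≤ δ_max`
with the *resolution* `δ_max` in µm; `Ā = D⁻¹A` is the row-normalised
adjacency.  With one-hot cell types `X^l ∈ {0,1}^{N×L}` and domains
`X^c ∈ {0,1}^{N×C}`:

- **Linear NCEM** — sender presence `X^S = 1(A X^l > 0)`, interaction block
  `X^TS = X^l ⊗ X^S` (receiver-major), design `X^D = (X^l | X^TS | X^c)`, fit
  `Ŷ = X^D β` by OLS.  Interaction coefficients are tested with Wald tests
  (t with `N − rank` dof, BH-corrected); a *type coupling* is the number of
  significant genes and the L1 norm of their coefficients per (sender,
  receiver) pair.  Variants: nonspatial baseline `(X^l | X^c)` and
  global-sender `(X^l | X^S | X^c)`.
- **Spot NCEM** — for deconvoluted spot data, each (spot, type) expression
  vector is an observation and the spot's inferred type abundances replace the
  graph kernel: row = `[one-hot(k) | one-hot(k) ⊗ composition_s | covariates]`.
- **Nonlinear NCEM** — a niche encoder (binary indicator pooling, or a
  one-layer graph convolution `g(A, X^l) = softmax(ReLU(Ā X^l W))`) feeding an
  MLP encoder/decoder with a Gaussian likelihood (free per-gene σ).  With the
  indicator encoder and zero hidden layers it reduces exactly to the linear
  NCEM.
- **Ligand–receptor NCEM** — a graph kernel
  `z_ik = f_R(Y_{i,r(k)}) · Σ_{m∈niche} f_L(Y_{m,l(k)})` embeds each cell in a
  latent space with one unit per ligand–receptor pair; a decoder predicts all
  genes from `z`.  Differential receptor activity between cells with/without a
  sender type in the niche is ranked by per-unit t-tests.
- **CVAE-NCEM** — a conditional variational autoencoder over node states with
  the type, niche embedding and domain as conditions in both encoder and
  decoder; loss `−ll + D_KL(q_φ(z)‖p(z))`; style transfer decodes one cell's
  latent state under another cell's conditions.

A synthetic-tissue module generates all validation data: random-geometric
tissues with gene means U(0, 10), niche effects U(4, 6) on half the genes when
the other type is within the interaction radius, unit Gaussian noise, plus
segmentation-error corruption, spot binning, and a ligand-driven design.

## Worked example

`examples/02_resolution_screen.py` generates a 1000-cell tissue with niche
effects acting at 50 µm and screens neighbourhood radii:

```
            ncem_r2  baseline_r2  delta_r2
resolution
15.0         0.0472       0.0299    0.0173
30.0         0.1339       0.0299    0.1040
50.0         0.6335       0.0299    0.6036
80.0         0.0637       0.0299    0.0339
130.0        0.0299       0.0299    0.0000

best resolution: 50 um (paired t-test vs baseline across splits: p = 1.35e-04)
```

Each row is the mean held-out R² over three cross-validation splits.  The
baseline ignores the graph, so its column is flat; the NCEM column peaks at
exactly the radius the dependency was generated with — the screen recovers the
length scale of cell–cell communication.  The other scripts in `examples/`
walk through couplings (`01`), spot data (`03`), the neural and
ligand–receptor models (`04`, `05`) and CVAE style transfer (`06`); each
prints the numbers it computes and one line on how to read them.

A thin CLI mirrors the library (`ncem simulate | fit-linear | screen |
fit-spot | fit-nl | fit-lr | diff-receptor | fit-cvae | style-transfer |
couplings`), writing TSV outputs plus a JSON run manifest.

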