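# spotcell

Single-cell resolution for spot-level spatial transcriptomics.

Sequencing-based spatial transcriptomics (10x Visium, Slide-seq) measures
gene expression at capture spots that mix the transcripts of several cells,
while imaging-based platforms (MERFISH, STARmap) resolve single cells but
only for small gene panels. `spotcell` integrates an annotated scRNA-seq
reference with spatial data to recover what each platform lacks:

* **Cell typing inside spots.** Given per-spot cell counts `M_i` from
  external segmentation, each cell gets a type label by MAP estimation
  under a Poisson model — `y_ig ~ Poisson(N_i λ_ig)` with
  `log λ_ig = α_i + log((1/M_i) Σ_m μ_{k_im,g}) + γ_g + ε_ig` — combined
  with a Potts prior `U(K) = Σ_pairs ν[1 − 𝟙(k = k′)]` over a cell-level
  neighbor graph, optimized by pairwise iterated conditional modes.
  `γ_g` and `α_i` are gene- and spot-level platform effects estimated from
  a pseudo-bulk fit against the reference profiles.
* **Expression decomposition.** A conditional score-based generative model
  `s_θ(x, σ_l, μ_k) ≈ ∇_x log p_σ(x | k)` of per-type log-centered
  expression is trained on the reference by multi-level denoising score
  matching, and per-cell expression is sampled from the posterior
  `p(X_i | y_i, k_i)` with `y_i | X_i ~ N(Σ_m(exp(x_m + μ_{k_m}) − 1),
  σ_yl² I)` by annealed Langevin dynamics.
* **Dropout correction and imputation.** The same posterior machinery
  de-noises sparse near-single-cell spots (singlet/doublet classification,
  at most two types per spot) and completes panel-measured cells to the
  full reference transcriptome through a masked observation model.

A synthetic-data module generates grid-aggregated spots with known
ground truth (per-type negative-binomial expression, Potts-coherent label
fields, platform effects, binomial UMI thinning), so the whole chain is
validated without downloads. See `docs/methods.md` for the models,
estimation details and limitations.

## Worked example

```python
import numpy as np
import spotcell as sc

spec = sc.SimulationSpec(n_types=3, n_genes=40, cells_per_type=[300] * 3,
                         grid_shape=(8, 8), cells_per_spot=(1, 2),
                         label_coherence=1.0, gamma_sd=0.3, seed=7)
ref = sc.simulate_reference(spec)          # (genes x cells, label table)
spots, truth = sc.simulate_spots(ref, spec)

profile = sc.estimate_type_profiles(*ref)
effects = sc.estimate_platform_effects(spots, profile)
graph = sc.build_neighbor_graph(spots, radius=1.01)
field = sc.icm_map_labels(spots, graph, profile, effects, nu=10.0, seed=0)

print(f"gamma correlation: "
      f"{np.corrcoef(effects.gamma, truth.gamma)[0, 1]:.3f}")
print(f"typing error: {np.mean(field.labels != truth.cell_types):.3f} "
      f"({graph.n_cells} cells, energy {field.energy:.1f})")
```

prints

```
gamma correlation: 0.948
typing error: 0.010 (96 cells, energy 6373.0)
```

The gene-level platform effects (drawn with sd 0.3) are recovered with
Pearson 0.95 from the pseudo-bulk fit, and 99 % of the 96 cells on the
8×8 grid get the correct type. Training the score prior and decomposing
spots to per-cell expression follows the same pattern with
`sc.train_score_model` and `sc.decompose_dataset`; the pipeline module
chains everything from files (`spotcell run --config cfg.yaml`).

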