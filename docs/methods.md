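# Methods

`spotcell` turns spot-level spatial transcriptomics (ST) into single-cell
resolution in three stages: (1) per-cell type labels inside each spot, (2) a
conditional generative prior of per-type expression learned from an annotated
scRNA-seq reference, and (3) posterior sampling of per-cell expression given
the spot measurement. This note describes the models, the estimation and
numerical choices, and what the synthetic validation does and does not show.

## Observation model for cell typing

For spot `i` with `M_i` segmented cells of (unknown) types `k_{i,m}`:

    y_ig | λ_ig ~ Poisson(N_i λ_ig)
    log λ_ig = α_i + log( (1/M_i) Σ_m μ_{k_im,g} ) + γ_g + ε_ig

`N_i` is the spot's UMI total, `μ_{k,g}` the relative expression of gene `g`
in type `k` (per-cell counts normalized to sum to one before averaging, so
`λ` is a rate and `exp(α_i)` absorbs depth), `γ_g ~ N(0, σ_γ²)` a gene-level
platform effect, `α_i` a spot-level effect, and `ε_ig ~ N(0, σ_ε²)`
extra-Poisson noise. The `ε` marginal is computed with 16-node Gauss–Hermite
quadrature; the `σ_ε = 0` path is the exact Poisson log-pmf, and the two
agree to ≤ 1e-6 as `σ_ε → 0`. Rates are floored at 1e-12 before logs.

Spatial smoothness is a Potts prior on a cell-level neighbor graph
(cells sharing a spot form a clique; spots within a radius are linked
all-to-all; optional nearest-spot links across slices):

    U(K) = Σ_{unordered neighbor pairs} ν · [1 − 1(labels equal)]

with `ν = 10` by default. The MAP labeling minimizes
`−log p(Y|K) + U(K)` by iterated conditional modes that update the two
labels of a within-spot pair jointly (`K²` candidates per pair; single-label
updates where `M_i = 1`), spots visited in seed-shuffled order.
Initialization is the per-spot independent maximum-likelihood assignment;
restarts (default 5) flip 10 % of cells at random. Accepted moves strictly
decrease the objective, so each run terminates in a pairwise-move local
optimum; on 6-cell instances 5-restart ICM recovers the exhaustively
enumerated global optimum in ≥ 18/20 random instances.

Platform effects are estimated from pseudo-bulk: all spots are summed into
one bulk vector, type weights fitted by nonnegative least squares against
the profile rows, and `γ̂_g` is the centered log-residual shrunk by
`σ_γ²/(σ_γ² + 1/fitted_g)`, with `σ_γ²` and `σ_ε²` by method of moments
(the log of a Poisson count has variance ≈ 1/mean). Genes with zero counts
in both bulk and profiles get `γ̂ = 0` and are flagged. Spot correction
divides gene `g` by `exp(γ̂_g)` and rescales the spot total to
`M_i ×` (mean per-cell reference total); the correction is exact up to gene
proportions when the true `γ` is supplied.

For near-single-cell platforms without images, per-spot multiplicity is
classified by comparing the best single-type Poisson fit against the best
two-type fit (pair-averaged rate, at most two types per spot); the spot
scalar `α` is profiled out per candidate so the decision depends only on
composition, and a doublet is declared only when the log-likelihood gain
exceeds a threshold (default 2.0 — roughly an AIC penalty for the extra
type; ties resolve to singlet).

## Conditional score prior

Reference cells are transformed to `x = log1p(counts) − μ_k`, with `μ_k`
the per-type mean of `log1p` counts. The prior on `x` given type `k` is
learned by multi-level denoising score matching over a geometric noise
ladder `σ_1 < … < σ_L` with weights `λ_l = σ_l²`; the target at level `l`
is `−(x^l − x)/σ_l²`. Type conditioning feeds `μ_k` itself to the network —
a conditioning vector with the same dimension as `x` cannot be ignored the
way a scalar label can.

The network is a residual MLP (two hidden layers, width `min(max(2G, 64),
256)`, SiLU) over `[x, μ_k, log σ features]`, trained with Adam (lr 1e-3,
batch 128, one uniformly drawn noise level per minibatch), written in numpy
with manual backpropagation; training is bit-reproducible from the seed.
The score is parameterized around the Gaussian reference solution,

    s_θ(x, σ, μ_k) = (F_θ(x, σ, μ_k) − x) / (sd² + σ²),

where `sd` is the training-data standard deviation. For Gaussian data the
optimal `F` is identically zero, so the network learns only the departure
from Gaussianity, and the `1/(sd² + σ²)` scale bounds how much network
error can distort the score at the smallest noise levels, where scores are
largest. On a 1-D Gaussian reference the trained score matches the analytic
convolution score `−x/(s² + σ_l²)` with relative L2 error ≈ 0.03 at the
three smallest levels after 2000 epochs.

Defaults: `L = 232`, `T = 5` steps per level, 7500 epochs at full scale;
the desk-scale preset used throughout the tests is `L = 50`, 2000 epochs,
≤ 64 genes. `σ_min = 0.01`; `σ_max` is the maximum pairwise distance within
a 500-vector subsample (the usual score-model rule). An analytic Gaussian
backend `score(x, σ) = −(Σ + σ²I)⁻¹(x − mean)` implements the same contract
exactly and anchors every sampler test to closed forms.

## Annealed Langevin sampling and the inverse problems

Sampling runs `x ← x + η[∇ log p(y|x) + s_θ(x, σ_l, μ_k)] + √(2η) z` from
`l = L` down to 1, warm-started across levels, with `η = η₀ σ_l²/σ_1²`.
Chains start at `N(0, σ_L²)`.

* Decomposition: `y_i | X_i ~ N(f(X_i), σ_yl² I)` with
  `f = Σ_m (exp(x_m + μ_{k_m}) − 1)`; likelihood gradient
  `exp(x_m + μ) ⊙ (y − f)/σ_yl²` per cell; `σ_yl = √σ_l` by default.
* Imputation: the observation is `I_mask(exp(x + μ_k) − 1)` plus
  `N(0, σ_ε²)` noise; an empty mask reduces to prior sampling, a full mask
  to denoising.
* Dropout correction: batch-correct the spot, then decompose with `M = 1`
  or `M = 2` from the singlet/doublet classifier.

The posterior summary is the average of `R` independent annealed runs
(default `R = 10`); the count-scale summary averages `exp(x + μ) − 1`
(clipped at 0) across runs *after* the nonlinearity — exponentiating the
averaged log state underestimates counts by the Jensen gap of the posterior
spread. A `linear` likelihood link (`f = Σ_m x_m`, identity observation
map) is a first-class switch so the engine is testable against
conjugate-Gaussian closed forms; that oracle equivalence (posterior means
within 3 Monte-Carlo SE) is the primary correctness gate of the whole
sampling engine.

Numerical guards, all annealing-scheduled so they vanish on well-scaled
problems: exponential arguments are capped at 30; the deterministic drift
is clipped elementwise to `0.5 σ_l` per step (the exponential-link gradient
is astronomically large whenever a chain overshoots — only its direction is
informative there); and the state is kept inside `±(3σ_l + 6)`, the band
the level-`l` perturbed density itself occupies, which prevents rare chains
from stalling in regions the score network never saw (log-centered
expression satisfies `|x| < 6` for any realistic count). Without the state
bound, occasional stuck chains produce `exp`-scale outliers that dominate
the count-scale posterior mean as `R` grows.

Step-size calibration: the relaxation rate per step at level `l` is
`η₀ σ_l²/σ_1²` relative to the local variance scale. The studies use
`η₀ = 5e-5` with `σ_1 = 0.01` (relaxation constant 0.5), which equilibrates
Gaussian oracles to a few percent in variance at `L = 50, T = 5`; the
conservative production default is `η₀ = 1e-5`. Larger constants
destabilize the top levels (the Euler–Maruyama step approaches the local
variance), smaller ones under-mix. The closed-form oracle studies use
`T = 10`, which brings the low-level discretization bias of the posterior
mean (≈ 0.03 on a unit-scale conditional mean at `T = 5`) well under the
Monte-Carlo standard error.

## Synthetic data generator

The generator emulates the standard grid-and-aggregate benchmark: per-type
expression is negative binomial (Gamma–Poisson, dispersion `r`, per-type
mean vectors with marker blocks over a shared log-normal baseline), a
Potts-Gibbs label field (4-neighborhood, 50 sweeps, configurable
interaction) assigns a type per spot, each spot aggregates 1–20 sampled
cells of its type, and platform effects multiply counts by `exp(γ_g)`
(γ ~ N(0, σ_γ²)) and a log-normal per-spot depth factor (sd 0.3 by
default). UMI capture is binomial thinning per entry. Ground truth (cell
counts, types, spot assignments, `γ`, depth factors) is recorded exactly;
with no effects the spot counts equal the per-cell sums exactly.

Study conditions: the decomposition benchmark uses K = 4 types, G = 64
genes, 700 reference cells per type (~470 UMI/cell, so ≈ 950 UMI per 2-cell
spot), NB dispersion 2, 8-fold markers, a 6×6 grid with exactly 2 cells per
spot, and capture rates {0.25, 0.5, 1}; the typing benchmark deliberately
uses overlapping types (G = 150, 1.8-fold markers, dispersion 0.7) on a
10×10 grid with strongly coherent domains (Potts interaction 3.0), so
expression alone is ambiguous while the label field has the domain
structure that smoothing exploits — with fragmented fields (many
single-spot islands) a smoothness prior of `ν = 10` erodes the islands
faster than it fixes noise, which is a real property of the model, not an
estimator defect;
platform-effect recovery uses G = 200, I = 500, γ ~ N(0, 0.5²); dropout
correction thins the strongest marker gene to 3 % capture on an 8×8
near-single-cell grid.

What the generator does *not* emulate: hexagonal spot geometry (adjacency
is configurable but square by default), gene–gene correlation within a type
beyond what NB mixing induces (genes are conditionally independent given
type, so imputation leans on type identity rather than co-expression
modules), ambient RNA, segmentation errors in `M_i`, and cell-type
composition gradients within a spot. Passing tests therefore demonstrate
the estimators' correctness and the advertised qualitative behaviors
(smoothing benefit, capture-rate monotonicity, dropout restoration), not
performance on real tissue.

## Known limitations

* The score network is a small MLP; atlas-scale references and thousands of
  genes would need minibatch pipelines and accelerators out of scope here.
* MAP typing returns no label posteriors, and `ν` is not estimated from
  data.
* The pseudo-bulk `α_i`/`σ_ε` estimators are method-of-moments
  approximations; they are accurate in the regimes tested (γ correlation
  ≥ 0.9) but are not maximum likelihood.
* Count-scale posterior means are clipped at zero; strictly positive
  estimands near zero are therefore slightly biased upward.
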