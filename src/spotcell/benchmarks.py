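"""Synthetic validation studies exercising every stage of the package.

Each study builds its own inputs with :mod:`spotcell.simulate` (or closed
forms), runs the corresponding method, and returns the measured quantities
together with the reference values they are compared against. They are the
backbone of the test suite and of ``scripts/acceptance.py``.

Problem sizes are desk scale by design: gene panels of 1-200 genes, grids
of 36-500 spots, score models trained for 2000 epochs on <= 64 genes.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .celltyping import (build_neighbor_graph, classify_spot_multiplicity,
                         icm_map_labels, potts_energy, spot_log_likelihood)
from .reference import (PlatformEffects, SpotDataset, correct_spot_expression,
                        estimate_platform_effects, estimate_type_profiles)
from .sampler import (DecompositionTask, ImputationTask, correct_dropout,
                      decompose_dataset, decompose_spot, impute_cell)
from .score import (AnalyticGaussianScore, TrainedScorePrior, default_sigma_max,
                    dsm_loss, make_noise_schedule, train_score_model)
from .simulate import (SimulationSpec, default_type_means, downsample_counts,
                       simulate_reference, simulate_spots)

__all__ = [
    "gaussian_sampler_study",
    "score_learning_study",
    "icm_bruteforce_study",
    "potts_benefit_study",
    "gamma_recovery_study",
    "make_benchmark_reference",
    "train_benchmark_prior",
    "end_to_end_study",
    "dropout_study",
]

# desk-scale Langevin settings used across the studies: the sigma_min=0.01
# ladder with eta0 = 5e-5 equilibrates Gaussian oracles to within a few
# percent in variance (see docs/methods.md)
_ETA0 = 5e-5
_SIGMA_MIN = 0.01


def _mean_cosine(A: np.ndarray, B: np.ndarray) -> float:
    num = np.sum(A * B, axis=1)
    den = np.linalg.norm(A, axis=1) * np.linalg.norm(B, axis=1) + 1e-12
    return float(np.mean(num / den))


def gaussian_sampler_study(seed: int = 0, R: int = 400) -> dict:
    """Posterior sampling against conjugate-Gaussian closed forms.

    Decomposition: standard-normal priors, linear link, M = 2 cells,
    sigma_y = 1, y = 2 — exact per-cell posterior mean y/(M + sigma_y^2)
    = 2/3 with marginal variance 2/3. Imputation: bivariate unit-variance
    prior with correlation rho = 0.8, coordinate 1 observed at v = 1 with
    noise 0.1 — exact conditional mean rho*v/(1 + sigma_eps^2).
    """
    # T = 10 keeps the low-level discretization bias well under the MC SE
    L = 50
    sched = make_noise_schedule(_SIGMA_MIN, 1.0, L, eta0=_ETA0, T=10)
    oracle1 = AnalyticGaussianScore(np.zeros(1), np.eye(1))
    task = DecompositionTask(y_corrected=np.array([2.0]), labels=np.array([0, 0]),
                             sigma_y=np.ones(L), R=R)
    res = decompose_spot(task, oracle1, sched, seed=seed, link="linear")
    dec_mean = float(res.per_run.mean())
    # estimator variance accounts for the -1/3 cell-cell posterior correlation
    dec_se = float(np.sqrt(1.0 / (6 * R)))

    rho, v, sig = 0.8, 1.0, 0.1
    oracle2 = AnalyticGaussianScore(np.zeros(2), np.array([[1, rho], [rho, 1]]))
    itask = ImputationTask(y_obs=np.array([v]), mask=np.array([0]),
                           type_id=0, sigma_eps=sig)
    ires = impute_cell(itask, oracle2, sched, R=R, seed=seed + 1, link="linear")
    imp_mean = float(ires.per_run[:, 1].mean())
    imp_expected = rho * v / (1 + sig ** 2)
    imp_var = 1 - rho ** 2 / (1 + sig ** 2)
    return {
        "decompose_mean": dec_mean, "decompose_expected": 2.0 / 3.0,
        "decompose_se": dec_se,
        "impute_mean": imp_mean, "impute_expected": imp_expected,
        "impute_se": float(np.sqrt(imp_var / R)),
    }


def score_learning_study(seed: int = 0, epochs: int = 2000) -> dict:
    """Score learning on a 1-D Gaussian reference N(0, 0.5^2).

    Compares the trained score with the analytic convolution score
    -x/(s^2 + sigma_l^2) on the probe grid x in {-2, ..., 2} at the three
    smallest noise levels, and the DSM loss of the zero function with its
    expectation L*G.
    """
    rng = np.random.default_rng(seed)
    s_true = 0.5
    n, G, L = 2000, 1, 50
    X = rng.normal(0.0, s_true, size=(n, G))
    sched = make_noise_schedule(_SIGMA_MIN, default_sigma_max(X, rng), L,
                                eta0=_ETA0, T=5)
    zeros = np.zeros(n, dtype=int)
    mu0 = np.zeros((1, G))
    prior = train_score_model(X, zeros, mu0, sched, epochs=epochs, seed=seed)
    grid = np.linspace(-2, 2, 9)[:, None]
    rel = []
    for sigma in sched.sigmas[:3]:
        learned = prior.score(grid, sigma, np.zeros_like(grid)).ravel()
        exact = (-grid / (s_true ** 2 + sigma ** 2)).ravel()
        rel.append(float(np.linalg.norm(learned - exact) / np.linalg.norm(exact)))

    def zero_fn(x, s, m):
        return np.zeros_like(x)

    zero_loss = dsm_loss(zero_fn, X, zeros, sched, mu0, seed=seed + 1)
    # per level the per-sample ||eps||^2 has variance 2G
    zero_se = float(np.sqrt(L * 2 * G / n))
    trained_loss = dsm_loss(prior.score, X[:500], zeros[:500], sched, mu0,
                            seed=seed + 1)
    return {
        "rel_l2": rel, "zero_loss": zero_loss, "zero_expected": float(L * G),
        "zero_se": zero_se, "trained_loss": trained_loss, "prior": prior,
        "schedule": sched,
    }


def _random_typing_instance(seed: int):
    r = np.random.default_rng(seed)
    K, G = 3, 12
    mm = default_type_means(K, G, r, base_mean=1.5, marker_fold=3.0)
    sp = SimulationSpec(n_types=K, n_genes=G, cells_per_type=[60] * K,
                        means=mm, dispersion=1.0, seed=seed)
    prof = estimate_type_profiles(*simulate_reference(sp))
    coords = pd.DataFrame({"spot_id": ["a", "b", "c"],
                           "x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0],
                           "slice": 0})
    y = r.poisson(8.0, size=(3, G)).astype(float)
    spots = SpotDataset(counts=y, coords=coords,
                        cell_counts=np.array([2, 2, 2]))
    effects = PlatformEffects.null(G, 3)
    graph = build_neighbor_graph(spots, radius=1.01)
    return spots, graph, prof, effects


def icm_bruteforce_study(seed: int = 0, n_instances: int = 20) -> dict:
    """Pairwise ICM against exhaustive enumeration on 6-cell instances.

    Counts how often 5-restart ICM attains the global MAP energy over all
    3^6 labelings, and whether its result is always pairwise-move locally
    optimal.
    """
    nu, K = 2.0, 3
    hits = local = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for inst in range(n_instances):
            spots, graph, prof, eff = _random_typing_instance(500 + seed * 1000 + inst)
            y = spots.counts

            def objective(lab: np.ndarray) -> float:
                ll = sum(spot_log_likelihood(y[i], y[i].sum(), lab[2 * i:2 * i + 2],
                                             prof, eff) for i in range(3))
                return -ll + potts_energy(lab, graph, nu)

            best = min(objective(np.array(l))
                       for l in itertools.product(range(K), repeat=6))
            field = icm_map_labels(spots, graph, prof, eff, nu=nu,
                                   n_restarts=5, seed=seed + inst)
            hits += abs(field.energy - best) < 1e-6
            ok = True
            cur = objective(field.labels)
            for i in range(3):
                for a in range(K):
                    for b in range(K):
                        l2 = field.labels.copy()
                        l2[2 * i], l2[2 * i + 1] = a, b
                        if objective(l2) < cur - 1e-9:
                            ok = False
            local += ok
    return {"global_hits": hits, "locally_optimal": local,
            "n_instances": n_instances}


def potts_benefit_study(seed: int = 0, n_seeds: int = 10) -> dict:
    """Typing error with (nu = 10) and without (nu = 0) the Potts prior on
    spatially coherent synthetic labels, paired over seeds.

    Types overlap deliberately (1.8-fold markers over a shared baseline,
    strong negative-binomial noise) so that expression alone is ambiguous,
    and the label field forms coherent domains (interaction 3.0) as real
    tissue does — the regime the smoothness prior is built for.
    """
    err0, err10 = [], []
    for s in range(n_seeds):
        inst_seed = seed * 1000 + s
        rng = np.random.default_rng(100 + inst_seed)
        means = default_type_means(3, 150, rng, base_mean=2.0,
                                   marker_fold=1.8)
        spec = SimulationSpec(n_types=3, n_genes=150,
                              cells_per_type=[260] * 3,
                              means=means, dispersion=0.7, grid_shape=(10, 10),
                              cells_per_spot=(1, 2), label_coherence=3.0,
                              seed=inst_seed)
        ref = simulate_reference(spec)
        spots, truth = simulate_spots(ref, spec)
        prof = estimate_type_profiles(*ref)
        eff = estimate_platform_effects(spots, prof)
        graph = build_neighbor_graph(spots, radius=1.01)
        for nu, acc in ((0.0, err0), (10.0, err10)):
            field = icm_map_labels(spots, graph, prof, eff, nu=nu,
                                   n_restarts=3, seed=inst_seed)
            acc.append(float(np.mean(field.labels != truth.cell_types)))
    return {"err_nu0": err0, "err_nu10": err10,
            "mean_err_nu0": float(np.mean(err0)),
            "mean_err_nu10": float(np.mean(err10))}


def gamma_recovery_study(seed: int = 0, n_seeds: int = 10) -> dict:
    """Recovery of gene-level platform effects gamma ~ N(0, 0.5^2) from the
    pseudo-bulk fit at G = 200 genes and I = 500 spots."""
    rs = []
    for s in range(n_seeds):
        spec = SimulationSpec(n_types=4, n_genes=200, cells_per_type=[300] * 4,
                              grid_shape=(25, 20), cells_per_spot=(1, 2),
                              gamma_sd=0.5, depth_sd=0.3, label_coherence=0.0,
                              seed=seed * 1000 + s)
        ref = simulate_reference(spec)
        spots, truth = simulate_spots(ref, spec)
        prof = estimate_type_profiles(*ref)
        eff = estimate_platform_effects(spots, prof)
        rs.append(float(np.corrcoef(eff.gamma, truth.gamma)[0, 1]))
    return {"pearson": rs, "min_pearson": float(np.min(rs)),
            "mean_pearson": float(np.mean(rs))}


def make_benchmark_reference(seed: int = 999):
    """The shared synthetic reference of the decomposition studies:
    K = 4 types, G = 64 genes, 700 cells per type, negative-binomial
    expression with 8-fold markers; around 470 UMIs per cell, so a 2-cell
    spot carries roughly 900-1000 UMIs."""
    meta_rng = np.random.default_rng(12345)
    means = default_type_means(4, 64, meta_rng, base_mean=3.0, marker_fold=8.0)
    spec = SimulationSpec(n_types=4, n_genes=64, cells_per_type=[700] * 4,
                          means=means, dispersion=2.0, grid_shape=(6, 6),
                          cells_per_spot=(2, 2), label_coherence=1.0, seed=seed)
    ref = simulate_reference(spec)
    prof = estimate_type_profiles(*ref)
    return means, ref, prof


def train_benchmark_prior(ref, prof, seed: int = 0, epochs: int = 2000):
    """Train the conditional score prior on the benchmark reference."""
    counts, labels = ref
    logc = np.log1p(counts.astype(float)).T
    tid = np.array([prof.type_names.index(t) for t in labels["cell_type"]])
    logc = logc - prof.log_mean[tid]
    rng = np.random.default_rng(seed)
    sched = make_noise_schedule(_SIGMA_MIN, default_sigma_max(logc, rng), 50,
                                eta0=_ETA0, T=5)
    prior = train_score_model(logc, tid, prof.log_mean, sched, epochs=epochs,
                              seed=seed, type_names=prof.type_names)
    return prior, sched


def _decompose_run(means, ref, prof, prior, sched, seed: int, rate: float,
                   R: int = 48) -> tuple[float, float, float]:
    """One end-to-end pass: simulate spots, thin, fit effects, type cells,
    batch-correct, decompose; returns (decomposed, baseline, reconstruction)
    cosine scores against the ground truth / corrected spot."""
    spec = SimulationSpec(n_types=4, n_genes=64, cells_per_type=[700] * 4,
                          means=means, dispersion=2.0, grid_shape=(6, 6),
                          cells_per_spot=(2, 2), label_coherence=1.0, seed=seed)
    spots, truth = simulate_spots(ref, spec)
    y = spots.counts
    if rate < 1:
        y = downsample_counts(y, rate, seed=seed + 77).astype(float)
    spots = SpotDataset(counts=y, coords=spots.coords,
                        cell_counts=spots.cell_counts)
    eff = estimate_platform_effects(spots, prof)
    graph = build_neighbor_graph(spots, radius=1.01)
    field = icm_map_labels(spots, graph, prof, eff, nu=10.0, n_restarts=2,
                           seed=seed)
    y_corr = np.stack([
        correct_spot_expression(spots.counts[i], eff,
                                prof.cell_total_mean * spots.cell_counts[i])
        for i in range(spots.n_spots)])
    labels_per_spot = [field.labels[c] for c in graph.spot_cells]
    res = decompose_dataset(y_corr, labels_per_spot, prior, sched, seed=seed,
                            R=R)
    dec = np.concatenate([r.counts for r in res], axis=0)
    recon = np.stack([r.counts.sum(axis=0) for r in res])
    baseline = np.expm1(prof.log_mean)[field.labels]
    tru = truth.cell_counts.astype(float)
    num = np.sum(recon * y_corr, axis=1)
    den = np.linalg.norm(recon, axis=1) * np.linalg.norm(y_corr, axis=1) + 1e-12
    return (_mean_cosine(dec, tru), _mean_cosine(baseline, tru),
            float(np.median(num / den)))


def end_to_end_study(seed: int = 0, n_seeds: int = 10, R: int = 48,
                     prior_bundle=None) -> dict:
    """Decomposition accuracy vs the per-type mean-profile baseline and
    across capture rates {0.25, 0.5, 1.0}, paired over seeds."""
    means, ref, prof = make_benchmark_reference()
    if prior_bundle is None:
        prior, sched = train_benchmark_prior(ref, prof, seed=seed)
    else:
        prior, sched = prior_bundle
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(1, n_seeds + 1):
            run_seed = seed * 1000 + s
            c25, _, _ = _decompose_run(means, ref, prof, prior, sched,
                                       run_seed, 0.25, R)
            c50, _, _ = _decompose_run(means, ref, prof, prior, sched,
                                       run_seed, 0.5, R)
            c100, base, recon = _decompose_run(means, ref, prof, prior, sched,
                                               run_seed, 1.0, R)
            rows.append((c25, c50, c100, base, recon))
    c25, c50, c100, base, recon = map(np.array, zip(*rows))
    return {
        "cos_rate_025": c25.tolist(), "cos_rate_05": c50.tolist(),
        "cos_rate_1": c100.tolist(), "baseline": base.tolist(),
        "recon_median": recon.tolist(),
        "wins_vs_baseline": int(np.sum(c100 > base)),
        "monotone_seeds": int(np.sum((c25 <= c50) & (c50 <= c100))),
        "n_seeds": n_seeds,
        "mean_cos": float(c100.mean()), "mean_baseline": float(base.mean()),
    }


def dropout_study(seed: int = 0, rate: float = 0.03, R: int = 5,
                  prior_bundle=None) -> dict:
    """Dropout correction on a near-single-cell grid.

    The strongest type-0 marker gene is binomially thinned to near-zero
    counts; the pipeline (singlet/doublet classification, platform-effect
    estimation, batch correction, prior-guided decomposition) restores it,
    measured by the spatial Pearson correlation of the corrected per-spot
    values with the pre-thinning truth.
    """
    means, ref, prof = make_benchmark_reference()
    if prior_bundle is None:
        prior, sched = train_benchmark_prior(ref, prof, seed=seed)
    else:
        prior, sched = prior_bundle
    spec = SimulationSpec(n_types=4, n_genes=64, cells_per_type=[700] * 4,
                          means=means, dispersion=2.0, grid_shape=(8, 8),
                          cells_per_spot=(1, 2), label_coherence=1.0,
                          seed=seed * 1000 + 21)
    spots, truth = simulate_spots(ref, spec)
    gene = int(np.argmax(means[0] / (means[1:].mean(axis=0) + 1e-9)))
    truth_gene = spots.counts[:, gene].copy()
    y = spots.counts.copy()
    y[:, gene] = downsample_counts(y[:, gene].astype(int), rate,
                                   seed=seed * 1000 + 5)
    spots = SpotDataset(counts=y, coords=spots.coords,
                        cell_counts=spots.cell_counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eff = estimate_platform_effects(spots, prof)
        corrected = np.zeros(spots.n_spots)
        for i in range(spots.n_spots):
            mult = classify_spot_multiplicity(spots.counts[i], prof, eff)
            res = correct_dropout(spots.counts[i], mult, prior, sched, eff,
                                  prof.cell_total_mean,
                                  seed=seed * 1000 + 100 + i, R=R)
            corrected[i] = res.counts[:, gene].sum()
    return {
        "gene": gene,
        "pearson_corrected": float(np.corrcoef(corrected, truth_gene)[0, 1]),
        "pearson_thinned": float(np.corrcoef(y[:, gene], truth_gene)[0, 1]),
        "mean_corrected": float(corrected.mean()),
        "mean_thinned": float(y[:, gene].mean()),
        "gamma_hat_gene": float(eff.gamma[gene]),
    }
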