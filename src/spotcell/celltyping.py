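"""Cell-type identification inside spots by MAP estimation.

Each spot i holds M_i segmented cells with unknown types k_{i,m}. The
observation model is the Poisson rate model of :mod:`spotcell.reference`;
spatial smoothness is encoded by a Potts prior over the cell-level neighbor
graph,

    U(K) = sum over unordered neighbor pairs of nu * [1 - 1(equal labels)],

and the MAP labeling maximizes log p(Y|K) - U(K). The optimizer is an
iterated-conditional-modes scheme that updates the two labels of a
within-spot pair jointly (K^2 candidates per pair), which never increases
the objective and terminates in a pairwise-move local optimum. Restarts
from perturbed initializations guard against poor local optima.

For high-resolution data without images (no per-spot cell counts), a
singlet/doublet classifier compares the best single-type fit against the
best two-type fit, assuming at most two cell types co-exist in a spot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import gammaln, logsumexp

from .reference import PlatformEffects, ReferenceProfile, SpotDataset

__all__ = [
    "NeighborGraph",
    "LabelField",
    "build_neighbor_graph",
    "potts_energy",
    "spot_log_likelihood",
    "icm_map_labels",
    "classify_spot_multiplicity",
]

_RATE_FLOOR = 1e-12
_GH_NODES = 16


@dataclass
class NeighborGraph:
    """Cell-level neighbor graph. Cells are indexed globally; ``cell_spot``
    maps each cell to its spot and ``spot_cells`` lists each spot's cells."""

    n_cells: int
    edges: np.ndarray           # (E, 2) unordered pairs, u < v
    cell_spot: np.ndarray       # (n_cells,) spot index per cell
    spot_cells: list[np.ndarray]

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-edges are not allowed")
        self.adjacency: list[list[int]] = [[] for _ in range(self.n_cells)]
        for u, v in self.edges:
            self.adjacency[u].append(v)
            self.adjacency[v].append(u)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class LabelField:
    """MAP labeling result: per-cell labels, the final objective
    (Potts energy plus negative log-likelihood), and sweeps used."""

    labels: np.ndarray
    energy: float
    n_sweeps: int


def build_neighbor_graph(spots: SpotDataset, radius: float,
                         z_link: bool = False) -> NeighborGraph:
    """Cells sharing a spot are mutually adjacent; cells in spots whose
    centers are within ``radius`` (same slice) are adjacent; with ``z_link``,
    cells in the nearest spot of each adjacent slice are adjacent."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    M = spots.cell_counts
    offsets = np.concatenate([[0], np.cumsum(M)])
    n_cells = int(offsets[-1])
    spot_cells = [np.arange(offsets[i], offsets[i + 1]) for i in range(spots.n_spots)]
    cell_spot = np.repeat(np.arange(spots.n_spots), M)

    edges: list[tuple[int, int]] = []
    for cells in spot_cells:
        for a, b in combinations(cells.tolist(), 2):
            edges.append((a, b))

    xy = spots.coords[["x", "y"]].to_numpy(dtype=float)
    sl = spots.coords["slice"].to_numpy()
    for s in np.unique(sl):
        idx = np.flatnonzero(sl == s)
        pts = xy[idx]
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        ii, jj = np.nonzero((d2 <= radius ** 2) & np.triu(np.ones_like(d2, bool), 1))
        for a, b in zip(idx[ii], idx[jj]):
            for u in spot_cells[a]:
                for v in spot_cells[b]:
                    edges.append((min(u, v), max(u, v)))

    if z_link:
        slices = np.sort(np.unique(sl))
        for s0, s1 in zip(slices[:-1], slices[1:]):
            i0 = np.flatnonzero(sl == s0)
            i1 = np.flatnonzero(sl == s1)
            d2 = ((xy[i0][:, None, :] - xy[i1][None, :, :]) ** 2).sum(-1)
            nearest = d2.argmin(axis=1)
            for a, j in zip(i0, nearest):
                b = i1[j]
                for u in spot_cells[a]:
                    for v in spot_cells[b]:
                        edges.append((min(u, v), max(u, v)))

    uniq = sorted(set(edges))
    return NeighborGraph(n_cells=n_cells,
                         edges=np.asarray(uniq, dtype=int).reshape(-1, 2),
                         cell_spot=cell_spot, spot_cells=spot_cells)


def potts_energy(labels: np.ndarray, graph: NeighborGraph, nu: float) -> float:
    """U(K): nu per discordant unordered neighbor pair."""
    labels = np.asarray(labels)
    if labels.shape[0] != graph.n_cells:
        raise ValueError("labels must cover every cell in the graph")
    if nu < 0:
        raise ValueError("nu must be >= 0")
    if graph.n_edges == 0:
        return 0.0
    u, v = graph.edges[:, 0], graph.edges[:, 1]
    return float(nu * np.sum(labels[u] != labels[v]))


def _poisson_loglik_rows(y: np.ndarray, rates: np.ndarray, N: float,
                         sigma_eps: float) -> np.ndarray:
    """Log-likelihood of one spot's counts for each candidate rate row.

    rates : (C, G) relative rates lambda (already including alpha and gamma).
    Marginalizes the extra-Poisson noise eps ~ N(0, sigma_eps^2) by
    Gauss-Hermite quadrature; the sigma_eps = 0 path is the exact Poisson
    log pmf.
    """
    rates = np.maximum(rates, _RATE_FLOOR)
    mean = N * rates  # (C, G)
    const = gammaln(y + 1.0).sum()
    if sigma_eps <= 0:
        return (y[None, :] * np.log(mean) - mean).sum(axis=1) - const
    t, w = np.polynomial.hermite.hermgauss(_GH_NODES)
    shift = np.sqrt(2.0) * sigma_eps * t            # (J,)
    logmean = np.log(mean)
    # (C, G, J): y*(log mean + shift) - mean*exp(shift)
    a = (y[None, :, None] * (logmean[:, :, None] + shift[None, None, :])
         - mean[:, :, None] * np.exp(shift)[None, None, :])
    per_gene = logsumexp(a + np.log(w / np.sqrt(np.pi))[None, None, :], axis=2)
    return per_gene.sum(axis=1) - const


def spot_log_likelihood(y_i: np.ndarray, N_i: float, labels_i: np.ndarray,
                        profile: ReferenceProfile, effects: PlatformEffects,
                        alpha_i: float = 0.0) -> float:
    """eps-marginalized log-likelihood of one spot under labels ``labels_i``.

    The rate is lambda_g = exp(alpha_i) * mean_m mu_{k_m, g} * exp(gamma_g);
    genes where every candidate rate is zero but the count is positive are
    floored at 1e-12 (with a warning) to keep the value finite.
    """
    y_i = np.asarray(y_i, dtype=float)
    labels_i = np.asarray(labels_i, dtype=int)
    rho = profile.count_mean[labels_i].mean(axis=0)
    if np.any((rho <= 0) & (y_i > 0)):
        warnings.warn("gene(s) with positive count but zero profile rate; "
                      "rate floored at 1e-12")
    lam = np.exp(alpha_i) * rho * np.exp(effects.gamma)
    return float(_poisson_loglik_rows(y_i, lam[None, :], N_i, effects.sigma_eps)[0])


class _SpotLikelihood:
    """Cached per-spot candidate evaluation for the ICM sweeps."""

    def __init__(self, spots: SpotDataset, profile: ReferenceProfile,
                 effects: PlatformEffects):
        self.y = spots.counts
        self.N = spots.umi_totals
        self.M = spots.cell_counts
        self.mu = profile.count_mean            # K x G
        self.K = profile.n_types
        self.expg = np.exp(effects.gamma)
        self.alpha = effects.alpha
        self.sigma_eps = effects.sigma_eps

    def loglik_sums(self, i: int, sums: np.ndarray) -> np.ndarray:
        """Log-likelihood of spot i for candidate profile sums (C, G),
        where each row is sum_m mu_{k_m} over the spot's cells."""
        lam = np.exp(self.alpha[i]) * (sums / self.M[i]) * self.expg[None, :]
        return _poisson_loglik_rows(self.y[i], lam, self.N[i], self.sigma_eps)


def _independent_ml_init(lik: _SpotLikelihood, graph: NeighborGraph) -> np.ndarray:
    """Per-spot maximum-likelihood labels, ignoring the Potts prior:
    best single-type fill followed by within-spot coordinate ascent."""
    K, mu = lik.K, lik.mu
    labels = np.zeros(graph.n_cells, dtype=int)
    for i, cells in enumerate(graph.spot_cells):
        M = len(cells)
        ll = lik.loglik_sums(i, mu * M)
        best = int(np.argmax(ll))
        lab = np.full(M, best)
        S = mu[best] * M
        if M > 1:
            for _ in range(5):
                changed = False
                for m in range(M):
                    base = S - mu[lab[m]]
                    cand = base[None, :] + mu
                    ll = lik.loglik_sums(i, cand)
                    b = int(np.argmax(ll))
                    if b != lab[m] and ll[b] > ll[lab[m]] + 1e-12:
                        lab[m] = b
                        S = base + mu[b]
                        changed = True
                if not changed:
                    break
        labels[cells] = lab
    return labels


def icm_map_labels(spots: SpotDataset, graph: NeighborGraph,
                   profile: ReferenceProfile, effects: PlatformEffects,
                   nu: float = 10.0, n_restarts: int = 5, seed: int = 0,
                   max_sweeps: int = 100) -> LabelField:
    """MAP labels by pairwise iterated conditional modes.

    Sweeps visit spots in seed-shuffled order; within each spot every
    unordered pair of cells is updated jointly over K^2 candidates (single
    cells for M_i = 1). Accepted moves strictly decrease the objective
    -log p(Y|K) + U(K); a sweep with no change (or ``max_sweeps``) ends a
    run. Runs start from the independent-ML assignment, ``n_restarts - 1``
    perturbations of it (10 % random flips, at least one), and the K
    uniform-label fields — the homogeneous starts dominate at large nu,
    where the MAP is a single shared label. The best field over all starts
    is returned.
    """
    if nu < 0:
        raise ValueError("nu must be >= 0")
    lik = _SpotLikelihood(spots, profile, effects)
    mu, K = lik.mu, lik.K
    rng = np.random.default_rng(seed)
    init0 = _independent_ml_init(lik, graph)

    jj, kk = np.meshgrid(np.arange(K), np.arange(K), indexing="ij")
    jj, kk = jj.ravel(), kk.ravel()
    pair_mu = mu[jj] + mu[kk]          # (K^2, G)
    discord_jk = (jj != kk).astype(float)

    inits = [init0.copy()]
    for _ in range(max(1, n_restarts) - 1):
        labels = init0.copy()
        flip = rng.random(graph.n_cells) < 0.10
        if not flip.any():
            flip[rng.integers(0, graph.n_cells)] = True
        labels[flip] = rng.integers(0, K, size=int(flip.sum()))
        inits.append(labels)
    inits.extend(np.full(graph.n_cells, k, dtype=int) for k in range(K))

    best_labels, best_obj, best_sweeps = None, np.inf, 0
    for labels in inits:
        spot_sums = np.stack([mu[labels[c]].sum(axis=0) for c in graph.spot_cells])

        n_sweeps = 0
        for sweep in range(max_sweeps):
            n_sweeps = sweep + 1
            changed = False
            for i in rng.permutation(spots.n_spots):
                cells = graph.spot_cells[i]
                M = len(cells)
                if M == 1:
                    c = cells[0]
                    nbr = graph.adjacency[c]
                    disc = np.full(K, float(len(nbr)))
                    for n in nbr:
                        disc[labels[n]] -= 1.0
                    cand = (spot_sums[i] - mu[labels[c]])[None, :] + mu
                    obj = -lik.loglik_sums(i, cand) + nu * disc
                    b = int(np.argmin(obj))
                    if obj[b] < obj[labels[c]] - 1e-9:
                        spot_sums[i] += mu[b] - mu[labels[c]]
                        labels[c] = b
                        changed = True
                    continue
                for a_loc, b_loc in combinations(range(M), 2):
                    ca, cb = cells[a_loc], cells[b_loc]
                    base = spot_sums[i] - mu[labels[ca]] - mu[labels[cb]]
                    # discordance with fixed outside neighbors (pair edge handled apart)
                    disc_a = np.zeros(K)
                    deg_a = 0
                    for n in graph.adjacency[ca]:
                        if n == cb:
                            continue
                        deg_a += 1
                        disc_a[labels[n]] -= 1.0
                    disc_a += deg_a
                    disc_b = np.zeros(K)
                    deg_b = 0
                    for n in graph.adjacency[cb]:
                        if n == ca:
                            continue
                        deg_b += 1
                        disc_b[labels[n]] -= 1.0
                    disc_b += deg_b
                    prior = nu * (disc_a[jj] + disc_b[kk] + discord_jk)
                    obj = -lik.loglik_sums(i, base[None, :] + pair_mu) + prior
                    cur = labels[ca] * K + labels[cb]
                    b = int(np.argmin(obj))
                    if obj[b] < obj[cur] - 1e-9:
                        labels[ca], labels[cb] = jj[b], kk[b]
                        spot_sums[i] = base + pair_mu[b]
                        changed = True
            if not changed:
                break

        obj = potts_energy(labels, graph, nu) - sum(
            lik.loglik_sums(i, spot_sums[i][None, :])[0]
            for i in range(spots.n_spots))
        if obj < best_obj:
            best_obj, best_labels, best_sweeps = obj, labels.copy(), n_sweeps

    return LabelField(labels=best_labels, energy=float(best_obj),
                      n_sweeps=best_sweeps)


def classify_spot_multiplicity(y_i: np.ndarray, profile: ReferenceProfile,
                               effects: PlatformEffects, threshold: float = 2.0
                               ) -> tuple[int, tuple[int, ...]]:
    """Singlet/doublet classification for high-resolution spots.

    Compares the best single-type likelihood with the best two-type
    likelihood (pair-averaged rate, M_i = 2); the spot-level scalar alpha is
    profiled out per candidate so the decision depends only on composition.
    Declares a doublet only if the log-likelihood gain exceeds ``threshold``
    (ties, including identical profiles, resolve to singlet).
    """
    y_i = np.asarray(y_i, dtype=float)
    N_i = y_i.sum()
    mu = profile.count_mean * np.exp(effects.gamma)[None, :]
    K = profile.n_types

    def _ll(rows: np.ndarray) -> np.ndarray:
        # profile out alpha: normalize each candidate rate to sum to 1
        lam = rows / np.maximum(rows.sum(axis=1, keepdims=True), _RATE_FLOOR)
        return _poisson_loglik_rows(y_i, lam, N_i, effects.sigma_eps)

    ll1 = _ll(mu)
    best1 = int(np.argmax(ll1))
    pairs = list(combinations(range(K), 2))
    if not pairs:
        return 1, (best1,)
    rows2 = np.stack([(mu[a] + mu[b]) / 2.0 for a, b in pairs])
    ll2 = _ll(rows2)
    bi = int(np.argmax(ll2))
    if ll2[bi] - ll1[best1] > threshold:
        return 2, pairs[bi]
    return 1, (best1,)
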