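"""Synthetic reference and spatial datasets with known ground truth.

The generator emulates the standard benchmarking construction for spot-level
spatial transcriptomics: single cells with known per-type expression
distributions are placed on a grid of spots and aggregated, after which
gene-level platform effects, per-spot depth effects, and binomial UMI
thinning can be applied. Every downstream stage of the package (profile
estimation, platform-effect recovery, cell typing, decomposition) is
testable against the ground truth recorded here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import SpotDataset

__all__ = [
    "SimulationSpec",
    "GroundTruthBundle",
    "simulate_reference",
    "simulate_spots",
    "downsample_counts",
    "sample_potts_field",
]


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    Attributes
    ----------
    n_types, n_genes
        Number of cell types K and genes G.
    cells_per_type
        Number of reference cells drawn per type (length K).
    expression_model
        ``negative_binomial`` (default; per-gene NB with per-type means),
        ``poisson`` (NB dispersion -> infinity limit) or ``gaussian_log``
        (log-normal rounded to counts; enables analytic oracles).
    means
        K x G per-type mean expression on the count scale. If None, random
        means are drawn (see :func:`default_type_means`).
    dispersion
        NB size parameter r (var = m + m^2/r). Larger = closer to Poisson.
    grid_shape
        rows x cols of the spot grid.
    cells_per_spot
        Inclusive (lo, hi) range of cells per spot; within [1, 20].
    label_coherence
        Potts interaction strength of the true type field on the spot grid;
        0 = independent labels.
    gamma_sd
        Standard deviation of the true gene-level platform effects gamma_g
        (log scale); 0 disables them.
    depth_sd
        SD of the log-normal per-spot depth factor; 0 disables it.
    seed
        Base seed; identical spec + seed gives bit-identical output.
    """

    n_types: int
    n_genes: int
    cells_per_type: list[int] | tuple[int, ...]
    expression_model: str = "negative_binomial"
    means: np.ndarray | None = None
    dispersion: float = 2.0
    gaussian_log_sd: float = 0.3
    grid_shape: tuple[int, int] = (8, 8)
    cells_per_spot: tuple[int, int] = (1, 2)
    label_coherence: float = 0.0
    gamma_sd: float = 0.0
    depth_sd: float = 0.0
    potts_sweeps: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1 or self.n_genes < 1:
            raise ValueError("n_types and n_genes must be positive")
        if len(self.cells_per_type) != self.n_types:
            raise ValueError("cells_per_type must have n_types entries")
        if any(c < 1 for c in self.cells_per_type):
            raise ValueError("cells_per_type entries must be positive")
        if self.expression_model not in ("negative_binomial", "poisson", "gaussian_log"):
            raise ValueError(f"unknown expression_model {self.expression_model!r}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.cells_per_spot
        if not (1 <= lo <= hi <= 20):
            raise ValueError("cells_per_spot range must lie within [1, 20]")
        if self.gamma_sd < 0 or self.depth_sd < 0:
            raise ValueError("gamma_sd and depth_sd must be >= 0")
        if self.label_coherence < 0:
            raise ValueError("label_coherence must be >= 0")
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("grid_shape must be positive")
        if self.means is not None:
            self.means = np.asarray(self.means, dtype=float)
            if self.means.shape != (self.n_types, self.n_genes):
                raise ValueError("means must have shape (n_types, n_genes)")
            if np.any(self.means < 0):
                raise ValueError("means must be nonnegative")


@dataclass
class GroundTruthBundle:
    """Everything the generator knows that an analysis must recover."""

    cell_counts: np.ndarray        # n_cells x G true per-cell counts
    cell_types: np.ndarray         # n_cells, int labels in [0, K)
    cell_spot: np.ndarray          # n_cells, spot index of each cell
    spot_types: np.ndarray         # per-spot type of the label field
    gamma: np.ndarray              # G true gene platform effects (log scale)
    depth_factors: np.ndarray      # per-spot multiplicative depth scalars
    label_coherence: float = 0.0
    meta: dict = field(default_factory=dict)


def default_type_means(n_types: int, n_genes: int, rng: np.random.Generator,
                       base_mean: float = 2.0, marker_fold: float = 8.0,
                       markers_per_type: int | None = None) -> np.ndarray:
    """Random per-type mean matrix: a shared log-normal baseline plus a block
    of up-regulated marker genes per type (fold change ``marker_fold``)."""
    base = rng.lognormal(mean=np.log(base_mean), sigma=0.6, size=n_genes)
    means = np.tile(base, (n_types, 1))
    if markers_per_type is None:
        markers_per_type = max(1, n_genes // (2 * n_types))
    for k in range(n_types):
        lo = (k * markers_per_type) % n_genes
        idx = (lo + np.arange(markers_per_type)) % n_genes
        means[k, idx] *= marker_fold
    return means


def simulate_reference(spec: SimulationSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw an annotated single-cell reference.

    Returns
    -------
    counts : (G, n_cells) integer array, genes x cells.
    labels : DataFrame with columns ``cell_id`` and ``cell_type``.
    """
    rng = np.random.default_rng(spec.seed)
    means = spec.means
    if means is None:
        means = default_type_means(spec.n_types, spec.n_genes, rng)
    cols = []
    types = []
    for k, n_k in enumerate(spec.cells_per_type):
        m = means[k]
        if spec.expression_model == "poisson":
            block = rng.poisson(m, size=(n_k, spec.n_genes))
        elif spec.expression_model == "negative_binomial":
            r = spec.dispersion
            # NB as Gamma-Poisson mixture: lam ~ Gamma(r, m/r)
            lam = rng.gamma(shape=r, scale=m / r, size=(n_k, spec.n_genes))
            block = rng.poisson(lam)
        else:  # gaussian_log
            logm = np.log1p(m)
            x = rng.normal(logm, spec.gaussian_log_sd, size=(n_k, spec.n_genes))
            block = np.rint(np.clip(np.expm1(x), 0, None)).astype(np.int64)
        cols.append(block)
        types.extend([k] * n_k)
    counts = np.concatenate(cols, axis=0).T.astype(np.int64)  # G x cells
    n_cells = counts.shape[1]
    labels = pd.DataFrame({
        "cell_id": [f"cell_{j}" for j in range(n_cells)],
        "cell_type": [f"type_{k}" for k in types],
    })
    return counts, labels


def sample_potts_field(shape: tuple[int, int], n_types: int, coherence: float,
                       rng: np.random.Generator, n_sweeps: int = 50) -> np.ndarray:
    """Gibbs-sample a Potts label field on a rows x cols grid (4-neighborhood).

    ``coherence`` is the interaction strength beta:
    p(k_i = k | neighbors) proportional to exp(beta * #{neighbors with label k}).
    coherence=0 gives i.i.d. uniform labels.
    """
    rows, cols = shape
    labels = rng.integers(0, n_types, size=(rows, cols))
    if coherence == 0 or n_sweeps == 0:
        return labels
    for _ in range(n_sweeps):
        for r in range(rows):
            for c in range(cols):
                score = np.zeros(n_types)
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols:
                        score[labels[rr, cc]] += coherence
                p = np.exp(score - score.max())
                p /= p.sum()
                labels[r, c] = rng.choice(n_types, p=p)
    return labels


def simulate_spots(reference: tuple[np.ndarray, pd.DataFrame],
                   spec: SimulationSpec) -> tuple[SpotDataset, GroundTruthBundle]:
    """Grid-and-aggregate cells from the reference pool into spots.

    A spatially coherent per-spot type field is drawn from a Potts model;
    each spot receives M_i cells sampled (without replacement) from the
    reference cells of its type; spot counts are the exact per-cell sums,
    then multiplied gene-wise by exp(gamma_g) and scaled per spot by a
    log-normal depth factor. With ``gamma_sd=0`` and ``depth_sd=0`` the spot
    counts equal the per-cell sums exactly.
    """
    counts, labels = reference
    if counts.size == 0:
        raise ValueError("reference is empty")
    rng = np.random.default_rng(spec.seed + 1)
    G = counts.shape[0]
    rows, cols = spec.grid_shape
    n_spots = rows * cols

    type_codes = labels["cell_type"].astype("category").cat.codes.to_numpy()
    pools = [np.flatnonzero(type_codes == k) for k in range(spec.n_types)]
    for k, p in enumerate(pools):
        rng.shuffle(p)
    cursor = [0] * spec.n_types

    field_labels = sample_potts_field((rows, cols), spec.n_types,
                                      spec.label_coherence, rng,
                                      n_sweeps=spec.potts_sweeps)
    spot_types = field_labels.ravel()

    lo, hi = spec.cells_per_spot
    M = rng.integers(lo, hi + 1, size=n_spots)

    cell_idx, cell_spot, cell_types = [], [], []
    pre_effect = np.zeros((n_spots, G))
    for i in range(n_spots):
        k = spot_types[i]
        need = M[i]
        if cursor[k] + need > len(pools[k]):
            raise ValueError(
                f"reference pool exhausted for type {k}: need {need} more cells, "
                f"{len(pools[k]) - cursor[k]} left")
        chosen = pools[k][cursor[k]:cursor[k] + need]
        cursor[k] += need
        cell_idx.extend(chosen)
        cell_spot.extend([i] * need)
        cell_types.extend([k] * need)
        pre_effect[i] = counts[:, chosen].sum(axis=1)

    gamma = rng.normal(0.0, spec.gamma_sd, size=G) if spec.gamma_sd > 0 else np.zeros(G)
    depth = (rng.lognormal(0.0, spec.depth_sd, size=n_spots)
             if spec.depth_sd > 0 else np.ones(n_spots))
    y = pre_effect * np.exp(gamma)[None, :] * depth[:, None]

    xs, ys = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    coords = pd.DataFrame({
        "spot_id": [f"spot_{i}" for i in range(n_spots)],
        "x": xs.ravel(), "y": ys.ravel(), "slice": 0,
    })
    spots = SpotDataset(counts=y, coords=coords, cell_counts=M.astype(int))

    truth = GroundTruthBundle(
        cell_counts=counts[:, cell_idx].T.astype(np.int64),
        cell_types=np.asarray(cell_types, dtype=int),
        cell_spot=np.asarray(cell_spot, dtype=int),
        spot_types=spot_types,
        gamma=gamma,
        depth_factors=depth,
        label_coherence=spec.label_coherence,
        meta={"reference_cell_index": np.asarray(cell_idx, dtype=int)},
    )
    return spots, truth


def downsample_counts(matrix: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """Binomial thinning of integer counts: each entry y is replaced by a
    Binomial(y, rate) draw, simulating a UMI capture rate. rate=1 is identity.
    """
    m = np.asarray(matrix)
    if not (0 < rate <= 1):
        raise ValueError("rate must be in (0, 1]")
    if not np.issubdtype(m.dtype, np.integer):
        if not np.allclose(m, np.rint(m)):
            raise ValueError("downsample_counts requires integer counts")
        m = np.rint(m).astype(np.int64)
    if rate == 1.0:
        return m.copy()
    rng = np.random.default_rng(seed)
    return rng.binomial(m, rate)
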