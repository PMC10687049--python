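"""Reference expression profiles and cross-platform effect estimation.

The observation model for a spot i and gene g is

    y_ig | lambda_ig ~ Poisson(N_i * lambda_ig)
    log(lambda_ig) = alpha_i + log( (1/M_i) sum_m mu_{k_im, g} ) + gamma_g + eps_ig

where mu_{k,g} is the relative expression of gene g in cell type k estimated
from an annotated single-cell reference, gamma_g ~ N(0, sigma_gamma^2) is a
gene-level platform effect, alpha_i a spot-level effect, and
eps_ig ~ N(0, sigma_eps^2) extra-Poisson noise. This module estimates the
per-type profiles mu (in both the count-rate and log1p conventions), the
platform effects linking reference and spatial platforms, and applies the
two-step spot-level batch correction (divide by exp(gamma_g), rescale depth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "ReferenceProfile",
    "PlatformEffects",
    "SpotDataset",
    "estimate_type_profiles",
    "estimate_platform_effects",
    "correct_spot_expression",
    "select_genes",
]


@dataclass
class ReferenceProfile:
    """Per-type mean expression in the two conventions the model needs.

    ``count_mean`` (K x G) holds relative expression rates mu_{k,g}: per-cell
    counts are normalized to sum to one before averaging, so that the Poisson
    rate N_i * lambda is a rate and exp(alpha_i) absorbs depth. ``log_mean``
    (K x G) holds the per-type mean of log1p raw counts — the centering
    vector mu_k of the score model. ``cell_total_mean`` is the mean per-cell
    UMI total, used as the depth-normalization target in spot correction.
    """

    count_mean: np.ndarray
    log_mean: np.ndarray
    type_names: list[str]
    gene_names: list[str]
    cell_total_mean: float = 0.0

    def __post_init__(self) -> None:
        self.count_mean = np.asarray(self.count_mean, dtype=float)
        self.log_mean = np.asarray(self.log_mean, dtype=float)
        if self.count_mean.shape != self.log_mean.shape:
            raise ValueError("count_mean and log_mean must share shape")
        if np.any(self.count_mean < 0):
            raise ValueError("count_mean must be nonnegative")
        if not np.all(np.isfinite(self.log_mean)):
            raise ValueError("log_mean must be finite")

    @property
    def n_types(self) -> int:
        return self.count_mean.shape[0]

    @property
    def n_genes(self) -> int:
        return self.count_mean.shape[1]

    def type_index(self, name: str) -> int:
        return self.type_names.index(name)


@dataclass
class PlatformEffects:
    """Estimated cross-platform effects: gene effects gamma_g (log scale),
    spot effects alpha_i, and the noise scales sigma_eps, sigma_gamma."""

    gamma: np.ndarray
    alpha: np.ndarray
    sigma_eps: float = 0.0
    sigma_gamma: float = 0.0
    flagged_genes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("gamma must be finite")
        if self.sigma_eps < 0 or self.sigma_gamma < 0:
            raise ValueError("noise scales must be >= 0")

    @classmethod
    def null(cls, n_genes: int, n_spots: int) -> "PlatformEffects":
        """No-op effects (gamma = 0, alpha = 0, sigma = 0)."""
        return cls(gamma=np.zeros(n_genes), alpha=np.zeros(n_spots))


@dataclass
class SpotDataset:
    """Spot-level spatial expression: counts (I x G), coordinates with slice
    ids, and the externally supplied per-spot cell counts M_i."""

    counts: np.ndarray
    coords: pd.DataFrame
    cell_counts: np.ndarray
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.cell_counts = np.asarray(self.cell_counts, dtype=int)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (spots x genes)")
        I = self.counts.shape[0]
        if len(self.coords) != I or len(self.cell_counts) != I:
            raise ValueError("coords and cell_counts must match the spot count")
        if np.any(self.cell_counts < 1):
            raise ValueError("every spot must contain at least one cell (M_i >= 1)")
        for col in ("x", "y"):
            if col not in self.coords.columns:
                raise ValueError(f"coords must contain column {col!r}")
        if "slice" not in self.coords.columns:
            self.coords = self.coords.assign(slice=0)
        dup = self.coords.duplicated(subset=["x", "y", "slice"])
        if dup.any():
            raise ValueError("duplicate spot coordinates within a slice")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def umi_totals(self) -> np.ndarray:
        """N_i: per-spot total UMIs."""
        return self.counts.sum(axis=1)


def estimate_type_profiles(ref_counts: np.ndarray, labels: pd.DataFrame | pd.Series,
                           gene_names: list[str] | None = None) -> ReferenceProfile:
    """Average the annotated reference per type.

    Parameters
    ----------
    ref_counts : (G, n_cells) count matrix, genes x cells.
    labels : per-cell type labels (``cell_type`` column if a DataFrame).

    count_mean rows are means of per-cell relative expression (cell counts
    normalized to sum to 1); log_mean rows are means of log1p raw counts.
    """
    X = np.asarray(ref_counts, dtype=float)
    if isinstance(labels, pd.DataFrame):
        lab = labels["cell_type"]
    else:
        lab = pd.Series(labels)
    lab = lab.reset_index(drop=True)
    if len(lab) != X.shape[1]:
        raise ValueError("labels length must equal the number of cells")
    type_names = sorted(lab.unique())
    G = X.shape[0]
    count_mean = np.zeros((len(type_names), G))
    log_mean = np.zeros((len(type_names), G))
    totals = X.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("reference contains all-zero cells")
    rel = X / totals[None, :]
    logx = np.log1p(X)
    for k, name in enumerate(type_names):
        idx = np.flatnonzero((lab == name).to_numpy())
        if idx.size == 0:
            raise ValueError(f"cell type {name!r} has no cells")
        count_mean[k] = rel[:, idx].mean(axis=1)
        log_mean[k] = logx[:, idx].mean(axis=1)
    if gene_names is None:
        gene_names = [f"gene_{g}" for g in range(G)]
    return ReferenceProfile(count_mean=count_mean, log_mean=log_mean,
                            type_names=list(type_names), gene_names=list(gene_names),
                            cell_total_mean=float(totals.mean()))


def select_genes(ref_counts: np.ndarray, labels: pd.DataFrame | pd.Series,
                 n_hvg: int = 1000, n_markers_per_type: int = 50) -> np.ndarray:
    """Indices of top highly-variable genes (variance of log1p after depth
    normalization) plus per-type marker genes (largest mean fold change vs
    the other types). Returns the sorted union."""
    X = np.asarray(ref_counts, dtype=float)
    totals = X.sum(axis=0)
    norm = X / np.maximum(totals[None, :], 1.0) * np.median(totals)
    logn = np.log1p(norm)
    var = logn.var(axis=1)
    hvg = np.argsort(var)[::-1][:n_hvg]
    prof = estimate_type_profiles(ref_counts, labels)
    markers = []
    cm = prof.count_mean + 1e-12
    for k in range(prof.n_types):
        other = np.delete(cm, k, axis=0).mean(axis=0)
        fold = cm[k] / other
        markers.append(np.argsort(fold)[::-1][:n_markers_per_type])
    keep = np.union1d(hvg, np.concatenate(markers))
    return np.sort(keep)


def estimate_platform_effects(spots: SpotDataset, profile: ReferenceProfile,
                              max_iter_nnls: int | None = None) -> PlatformEffects:
    """Estimate gene effects gamma_g from a pseudo-bulk fit.

    All spots are summed into one bulk vector; overall type weights are
    estimated by nonnegative least squares of the bulk on the count_mean
    rows; gamma_hat is the centered log-residual log(bulk_g / fitted_g),
    shrunk toward 0 by the factor sigma_gamma^2 / (sigma_gamma^2 + 1/fitted_g)
    with sigma_gamma estimated by method of moments (log of a Poisson total
    has variance ~ 1/mean). alpha_i is the per-spot scalar MLE given the
    pseudo-bulk composition; sigma_eps matches the excess variance of
    log residuals beyond the Poisson level.
    """
    y = spots.counts
    bulk = y.sum(axis=0)
    A = profile.count_mean.T  # G x K
    total = bulk.sum()
    if total <= 0:
        raise ValueError("spot dataset is empty")
    # NNLS on proportions for conditioning; weights then absorb total depth
    w, _ = nnls(A, bulk / total)
    fitted = A @ w * total
    both_zero = (bulk == 0) & (fitted <= 0)
    if both_zero.any():
        warnings.warn(f"{both_zero.sum()} genes have zero counts in both "
                      "pseudo-bulk and profiles; gamma set to 0 for them")
    ok = ~both_zero & (fitted > 0) & (bulk > 0)
    resid = np.zeros_like(bulk, dtype=float)
    resid[ok] = np.log(bulk[ok] / fitted[ok])
    resid[ok] -= resid[ok].mean()  # alpha absorbs the overall scale
    # method-of-moments sigma_gamma: Var(log bulk_g) ~ sigma_gamma^2 + 1/fitted_g
    poisson_var = np.zeros_like(resid)
    poisson_var[ok] = 1.0 / fitted[ok]
    sigma_gamma_sq = max(float(resid[ok].var() - poisson_var[ok].mean()), 0.0) if ok.any() else 0.0
    shrink = np.zeros_like(resid)
    if sigma_gamma_sq > 0:
        shrink[ok] = sigma_gamma_sq / (sigma_gamma_sq + poisson_var[ok])
    gamma = resid * shrink

    # alpha_i: per-spot scalar MLE under the bulk composition base rate
    base = (A @ (w / max(w.sum(), 1e-300))) * np.exp(gamma)  # G, relative rate
    N = spots.umi_totals
    denom = base.sum()
    with np.errstate(divide="ignore"):
        alpha = np.where(N > 0, np.log(np.maximum(y.sum(axis=1), 1e-300) /
                                       np.maximum(N * denom, 1e-300)), 0.0)

    # sigma_eps: excess variance of per-spot log residuals beyond Poisson
    mu_ig = N[:, None] * np.exp(alpha)[:, None] * base[None, :]
    pos = (y > 0) & (mu_ig > 0)
    if pos.any():
        r = np.log(y[pos] / mu_ig[pos])
        r = r - r.mean()
        sigma_eps_sq = max(float(r.var() - (1.0 / mu_ig[pos]).mean()), 0.0)
    else:
        sigma_eps_sq = 0.0

    return PlatformEffects(gamma=gamma, alpha=alpha,
                           sigma_eps=float(np.sqrt(sigma_eps_sq)),
                           sigma_gamma=float(np.sqrt(sigma_gamma_sq)),
                           flagged_genes=np.flatnonzero(both_zero))


def correct_spot_expression(y_i: np.ndarray, effects: PlatformEffects,
                            target_depth: float) -> np.ndarray:
    """Two-step batch correction of one spot's expression vector: divide
    gene g by exp(gamma_g), then rescale so the total equals target_depth
    (the reference mean per-cell total times M_i)."""
    y_i = np.asarray(y_i, dtype=float)
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    out = y_i / np.exp(effects.gamma)
    s = out.sum()
    if s <= 0:
        raise ValueError("all-zero spot cannot be corrected (filter it first)")
    return out * (target_depth / s)
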