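"""Readers and writers for the package's on-disk formats.

Expression matrices travel as Matrix Market (.mtx) with gene/sample name
sidecars, dense CSV/TSV, or HDF5 containers; metadata tables as TSV.
Round-trip write -> read is the identity for integer counts.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .reference import PlatformEffects, ReferenceProfile, SpotDataset

__all__ = [
    "load_expression_matrix",
    "save_expression_matrix",
    "load_spot_dataset",
    "save_spot_dataset",
    "save_profile",
    "load_profile",
    "save_effects",
    "load_effects",
]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    return {".mtx": "mtx", ".csv": "csv", ".tsv": "csv",
            ".h5": "hdf5", ".hdf5": "hdf5"}.get(suffix, "csv")


def save_expression_matrix(path: str | Path, matrix: np.ndarray,
                           row_names: list[str], col_names: list[str],
                           fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    m = np.asarray(matrix)
    if m.shape != (len(row_names), len(col_names)):
        raise ValueError(f"matrix is {m.shape} but names imply "
                         f"({len(row_names)}, {len(col_names)})")
    if fmt == "mtx":
        scipy.io.mmwrite(path, sp.coo_matrix(m))
        path.with_suffix(".rows.tsv").write_text("\n".join(row_names) + "\n")
        path.with_suffix(".cols.tsv").write_text("\n".join(col_names) + "\n")
    elif fmt == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        pd.DataFrame(m, index=row_names, columns=col_names).to_csv(path, sep=sep)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("matrix", data=m)
            f.create_dataset("row_names", data=np.array(row_names, dtype="S"))
            f.create_dataset("col_names", data=np.array(col_names, dtype="S"))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_expression_matrix(path: str | Path, fmt: str | None = None
                           ) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a matrix plus row/column names; integer counts are preserved
    exactly. Raises on any dimension/name-count mismatch."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        m = np.asarray(scipy.io.mmread(path).todense())
        rows = path.with_suffix(".rows.tsv").read_text().splitlines()
        cols = path.with_suffix(".cols.tsv").read_text().splitlines()
    elif fmt == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.index.isnull().any() or df.columns.isnull().any():
            raise ValueError("missing header cell in CSV")
        m = df.to_numpy()
        rows, cols = list(df.index.astype(str)), list(df.columns.astype(str))
    elif fmt == "hdf5":
        with h5py.File(path, "r") as f:
            m = f["matrix"][:]
            rows = [s.decode() for s in f["row_names"][:]]
            cols = [s.decode() for s in f["col_names"][:]]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if m.shape != (len(rows), len(cols)):
        raise ValueError(f"matrix is {m.shape} but sidecars list "
                         f"{len(rows)} rows and {len(cols)} columns")
    if np.allclose(m, np.rint(m)):
        m = np.rint(m).astype(np.int64)
    return m, rows, cols


def save_spot_dataset(prefix: str | Path, spots: SpotDataset,
                      gene_names: list[str] | None = None) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    genes = gene_names or spots.gene_names or \
        [f"gene_{g}" for g in range(spots.n_genes)]
    spot_ids = list(spots.coords["spot_id"].astype(str)) \
        if "spot_id" in spots.coords else [f"spot_{i}" for i in range(spots.n_spots)]
    save_expression_matrix(prefix.with_suffix(".mtx"), spots.counts.T,
                           genes, spot_ids, fmt="mtx")
    meta = spots.coords.copy()
    meta["spot_id"] = spot_ids
    meta["n_cells"] = spots.cell_counts
    meta["total_umi"] = spots.umi_totals
    meta.to_csv(prefix.parent / (prefix.name + ".spots.tsv"), sep="\t", index=False)


def load_spot_dataset(prefix: str | Path) -> SpotDataset:
    prefix = Path(prefix)
    m, genes, spot_ids = load_expression_matrix(prefix.with_suffix(".mtx"))
    meta = pd.read_csv(prefix.parent / (prefix.name + ".spots.tsv"), sep="\t")
    return SpotDataset(counts=np.asarray(m, dtype=float).T,
                       coords=meta[["spot_id", "x", "y", "slice"]],
                       cell_counts=meta["n_cells"].to_numpy(),
                       gene_names=genes)


def save_profile(path: str | Path, profile: ReferenceProfile) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("count_mean", data=profile.count_mean)
        f.create_dataset("log_mean", data=profile.log_mean)
        f.create_dataset("type_names", data=np.array(profile.type_names, dtype="S"))
        f.create_dataset("gene_names", data=np.array(profile.gene_names, dtype="S"))
        f.attrs["cell_total_mean"] = profile.cell_total_mean


def load_profile(path: str | Path) -> ReferenceProfile:
    with h5py.File(path, "r") as f:
        return ReferenceProfile(
            count_mean=f["count_mean"][:], log_mean=f["log_mean"][:],
            type_names=[s.decode() for s in f["type_names"][:]],
            gene_names=[s.decode() for s in f["gene_names"][:]],
            cell_total_mean=float(f.attrs["cell_total_mean"]))


def save_effects(path: str | Path, effects: PlatformEffects) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gamma", data=effects.gamma)
        f.create_dataset("alpha", data=effects.alpha)
        f.create_dataset("flagged_genes", data=effects.flagged_genes)
        f.attrs["sigma_eps"] = effects.sigma_eps
        f.attrs["sigma_gamma"] = effects.sigma_gamma


def load_effects(path: str | Path) -> PlatformEffects:
    with h5py.File(path, "r") as f:
        return PlatformEffects(
            gamma=f["gamma"][:], alpha=f["alpha"][:],
            sigma_eps=float(f.attrs["sigma_eps"]),
            sigma_gamma=float(f.attrs["sigma_gamma"]),
            flagged_genes=f["flagged_genes"][:])
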