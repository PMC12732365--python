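"""Count-matrix I/O, gene filtering, expression binning and donor-aware
splitting/subsampling.

The cell-by-gene substrate is an AnnData with raw counts and obs columns
``donor_id``, ``age_group`` (exactly "mid" or "old") and ``tissue``.
Expression is discretized per cell into ``n_bins`` tokens (default 51):
zeros map to token 0, a cell's nonzero values are ranked against quantile
edges computed from that cell's own nonzero values, and the cell's maximum
always lands in the top bin. This per-cell scheme is depth-invariant, so
raw counts are binned without library-size normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "AGE_GROUPS",
    "BinnedMatrix",
    "SplitSpec",
    "read_counts",
    "validate_cell_matrix",
    "filter_genes",
    "bin_expression",
    "split_by_donor",
    "balanced_subsample",
    "subset_genes",
]

AGE_GROUPS = ("mid", "old")
META_COLUMNS = ("donor_id", "age_group", "tissue")
DEFAULT_N_BINS = 51


def validate_cell_matrix(adata: ad.AnnData) -> ad.AnnData:
    """Check the CellMatrix contract; returns the input on success."""
    missing = [c for c in META_COLUMNS if c not in adata.obs.columns]
    if missing:
        raise ValueError(f"missing per-cell metadata column(s): {missing}")
    symbols = pd.Index(adata.var_names)
    if symbols.has_duplicates:
        dups = sorted(symbols[symbols.duplicated()].unique())
        raise ValueError(f"duplicate gene symbols: {dups}")
    if pd.Index(adata.obs_names).has_duplicates:
        raise ValueError("cell ids are not unique")
    bad = set(adata.obs["age_group"].astype(str)) - set(AGE_GROUPS)
    if bad:
        raise ValueError(f"age_group must be one of {AGE_GROUPS}; found {sorted(bad)}")
    if (adata.obs["donor_id"].astype(str) == "").any():
        raise ValueError("empty donor_id found")
    x = adata.X
    mn = x.min() if sp.issparse(x) else np.min(x)
    if mn < 0:
        raise ValueError("counts must be non-negative")
    return adata


def read_counts(path, dialect: str = "mtx_tsv") -> ad.AnnData:
    """Read a cohort into an AnnData.

    ``mtx_tsv``: directory with ``matrix.mtx`` (cells as rows),
    ``genes.tsv`` (one symbol per line) and ``cells.tsv`` (TSV with header
    cell_id, donor_id, age_group, tissue). ``h5_container``: an
    h5ad file with the same obs/var annotations. Cell order follows file
    order.
    """
    from pathlib import Path

    path = Path(path)
    if dialect == "h5_container":
        adata = ad.read_h5ad(path)
        return validate_cell_matrix(adata)
    if dialect != "mtx_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    for name in ("matrix.mtx", "genes.tsv", "cells.tsv"):
        if not (path / name).exists():
            raise FileNotFoundError(f"missing sidecar file {name} in {path}")
    from scipy.io import mmread

    x = sp.csr_matrix(mmread(str(path / "matrix.mtx")))
    genes = [line.strip() for line in (path / "genes.tsv").read_text().splitlines() if line.strip()]
    cells = pd.read_csv(path / "cells.tsv", sep="\t", dtype=str)
    missing = [c for c in ("cell_id", *META_COLUMNS) if c not in cells.columns]
    if missing:
        raise ValueError(f"cells.tsv lacks required column(s): {missing}")
    if x.shape != (len(cells), len(genes)):
        raise ValueError(
            f"dimension mismatch: matrix is {x.shape}, metadata describes "
            f"{len(cells)} cells x {len(genes)} genes"
        )
    obs = cells.set_index("cell_id")[list(META_COLUMNS)]
    adata = ad.AnnData(X=x, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene_symbol")))
    return validate_cell_matrix(adata)


def filter_genes(adata: ad.AnnData, min_cell_fraction: float = 0.01) -> ad.AnnData:
    """Keep genes expressed (count > 0) in at least ``min_cell_fraction``
    of cells; gene order is preserved."""
    if not 0 <= min_cell_fraction <= 1:
        raise ValueError("min_cell_fraction must be in [0, 1]")
    x = adata.X
    n_expressed = (
        np.asarray((x > 0).sum(axis=0)).ravel() if sp.issparse(x) else (x > 0).sum(axis=0)
    )
    keep = n_expressed / adata.n_obs >= min_cell_fraction
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    return adata[:, keep].copy()


@dataclass
class BinnedMatrix:
    """Per-cell quantile-discretized expression tokens in [0, n_bins-1]."""

    tokens: np.ndarray  # cells x genes, small integers
    n_bins: int
    gene_symbols: pd.Index
    cell_ids: pd.Index
    obs: pd.DataFrame = field(repr=False)

    @property
    def n_cells(self) -> int:
        return self.tokens.shape[0]

    def subset_cells(self, idx) -> "BinnedMatrix":
        idx = np.asarray(idx)
        return BinnedMatrix(
            tokens=self.tokens[idx],
            n_bins=self.n_bins,
            gene_symbols=self.gene_symbols,
            cell_ids=self.cell_ids[idx],
            obs=self.obs.iloc[idx],
        )


def _bin_cell(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Tokenize one cell's count vector.

    Zeros take token 0. Quantile edges of the nonzero values are placed at
    probabilities k/(n_bins-1), k = 1..n_bins-2, and a nonzero value gets
    token 1 + (number of edges strictly below it), i.e. right-closed bins.
    Entries equal to the cell's maximum are forced into the top bin so the
    empirical maximum always maps to token n_bins - 1 (this keeps the
    overexpression perturbation, which writes the top token, inside the
    observed range even for cells with few distinct values).
    """
    tokens = np.zeros(values.shape, dtype=np.int16)
    nz = values > 0
    if not nz.any():
        return tokens
    nz_values = values[nz]
    probs = np.arange(1, n_bins - 1) / (n_bins - 1)
    edges = np.quantile(nz_values, probs)
    t = 1 + np.searchsorted(edges, nz_values, side="left")
    t[nz_values == nz_values.max()] = n_bins - 1
    tokens[nz] = t.astype(np.int16)
    return tokens


def bin_expression(adata: ad.AnnData, n_bins: int = DEFAULT_N_BINS) -> BinnedMatrix:
    """Discretize each cell's counts into ``n_bins`` tokens (see module
    docstring for the dialect)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = adata.X
    dense = x.toarray() if sp.issparse(x) else np.asarray(x)
    tokens = np.empty(dense.shape, dtype=np.int16)
    for i in range(dense.shape[0]):
        tokens[i] = _bin_cell(dense[i], n_bins)
    return BinnedMatrix(
        tokens=tokens,
        n_bins=n_bins,
        gene_symbols=pd.Index(adata.var_names),
        cell_ids=pd.Index(adata.obs_names),
        obs=adata.obs.copy(),
    )


@dataclass(frozen=True)
class SplitSpec:
    """Donor-level train/test partition; no donor appears on both sides."""

    train_donors: frozenset
    test_donors: frozenset
    seed: int

    def __post_init__(self):
        if self.train_donors & self.test_donors:
            raise ValueError("train and test donor sets overlap")

    def train_mask(self, adata: ad.AnnData) -> np.ndarray:
        return adata.obs["donor_id"].isin(self.train_donors).to_numpy()

    def test_mask(self, adata: ad.AnnData) -> np.ndarray:
        return adata.obs["donor_id"].isin(self.test_donors).to_numpy()


def split_by_donor(adata: ad.AnnData, test_donor_fraction: float = 0.25, seed: int = 0) -> SplitSpec:
    """Stratified donor-level split: per age group, about
    ``test_donor_fraction`` of donors (at least one, and leaving at least
    one in train) go to the test side. Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    train, test = set(), set()
    for group in AGE_GROUPS:
        donors = np.array(sorted(adata.obs.loc[adata.obs["age_group"] == group, "donor_id"].unique()))
        if len(donors) < 2:
            raise ValueError(
                f"age group {group!r} has {len(donors)} donor(s); "
                "need at least 2 for a donor-wise split"
            )
        n_test = int(np.clip(round(len(donors) * test_donor_fraction), 1, len(donors) - 1))
        chosen = rng.choice(donors, size=n_test, replace=False)
        test.update(chosen)
        train.update(set(donors) - set(chosen))
    return SplitSpec(train_donors=frozenset(train), test_donors=frozenset(test), seed=seed)


def balanced_subsample(adata: ad.AnnData, n_per_group: int = 150, seed: int = 0) -> np.ndarray:
    """Indices of ``n_per_group`` cells per age group, sampled without
    replacement; deterministic given the seed. Mid-group indices come
    first; within a group, original cell order is kept."""
    rng = np.random.default_rng(seed)
    picks = []
    ages = adata.obs["age_group"].to_numpy()
    for group in AGE_GROUPS:
        pool = np.flatnonzero(ages == group)
        if len(pool) < n_per_group:
            raise ValueError(
                f"age group {group!r} has only {len(pool)} cells; "
                f"{n_per_group} requested per group"
            )
        picks.append(np.sort(rng.choice(pool, size=n_per_group, replace=False)))
    return np.concatenate(picks)


def subset_genes(adata: ad.AnnData, keep) -> tuple[ad.AnnData, list[str]]:
    """Subset to the genes in ``keep`` (in the matrix's own gene order).

    Returns the subset plus the list of requested symbols absent from the
    matrix. Raises if the intersection is empty.
    """
    keep = set(keep)
    mask = np.array([g in keep for g in adata.var_names])
    if not mask.any():
        raise ValueError("no requested gene is present in the matrix")
    missing = sorted(keep - set(adata.var_names))
    return adata[:, mask].copy(), missing
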