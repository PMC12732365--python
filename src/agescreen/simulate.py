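"""Donor-structured negative-binomial scRNA-seq cohort simulator.

Emulates the structure of a two-age-group single-cell atlas: several donors
per age group within one tissue, overdispersed counts, a per-donor scalar
depth/quality shift, per-cell library-size variation, and a minority of
"causal" genes whose mean expression differs between the mid (20-59 y) and
old (60-100 y) groups by a known fold change. Each causal gene carries a
ground-truth screen label: a gene up-regulated in old cells is a pro-aging
candidate (raising its expression pushes the classifier toward "old"), a
gene down-regulated in old cells is an anti-aging candidate.

Counts for cell c of donor d in age group a:

    mu[c, g]  = exp(log_mu[g] + delta[d] + ell[c] + 1[a=old] * s[g] * log(FC[g]))
    K[c, g] ~ NB(mean=mu, dispersion=theta),  Var = mu + mu^2 / theta

with delta ~ N(0, donor_effect_sd), ell ~ N(0, libsize_log_sd), s = +1 for
up_in_old and -1 for down_in_old. Generation is bit-reproducible for a
fixed spec (the seed is part of the spec).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

__all__ = [
    "CausalGene",
    "SyntheticSpec",
    "GroundTruth",
    "generate_cohort",
    "write_cohort",
    "load_spec",
    "PRO_AGING",
    "ANTI_AGING",
]

PRO_AGING = "pro-aging"
ANTI_AGING = "anti-aging"

_DIRECTIONS = ("up_in_old", "down_in_old")


@dataclass(frozen=True)
class CausalGene:
    """A planted age-associated gene: index, direction of the shift in the
    old group, and multiplicative fold change (> 1) of its mean."""

    index: int
    direction: str
    fold_change: float

    def __post_init__(self):
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}, got {self.direction!r}")
        if not self.fold_change > 1:
            raise ValueError("fold_change must be > 1")

    @property
    def expected_label(self) -> str:
        # higher expression pushes P(old) up, so overexpression of an
        # up-in-old gene raises P(old): knockout/overexpression ratio < 1,
        # i.e. a pro-aging candidate; the down-in-old case mirrors it.
        return PRO_AGING if self.direction == "up_in_old" else ANTI_AGING


@dataclass
class SyntheticSpec:
    """Parameters of one simulated tissue cohort.

    Defaults describe the reference study cohort used throughout the test
    suite: 6 donors per age group, 200 cells per donor, 200 genes of which
    10 are up- and 10 down-regulated in the old group at fold change 4,
    moderate overdispersion (theta = 5) and mild donor structure.
    """

    n_donors_per_group: int = 6
    cells_per_donor: int = 200
    n_genes: int = 200
    causal_genes: list[CausalGene] = field(default_factory=list)
    baseline_mean_log_mu: float = 0.0
    baseline_mean_log_sigma: float = 1.0
    nb_dispersion: float = 5.0
    donor_effect_sd: float = 0.1
    libsize_log_sd: float = 0.3
    tissue_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        self.causal_genes = [
            g if isinstance(g, CausalGene) else CausalGene(**g) for g in self.causal_genes
        ]
        if self.n_donors_per_group <= 0 or self.cells_per_donor <= 0 or self.n_genes <= 0:
            raise ValueError("n_donors_per_group, cells_per_donor and n_genes must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.donor_effect_sd < 0 or self.libsize_log_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        idx = [g.index for g in self.causal_genes]
        if len(set(idx)) != len(idx):
            raise ValueError("causal gene indices must be unique")
        bad = [i for i in idx if not 0 <= i < self.n_genes]
        if bad:
            raise ValueError(f"causal gene indices out of range: {bad}")


def default_planted_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The reference planted cohort: genes 0-9 up-in-old and 10-19
    down-in-old, each at fold change 4."""
    causal = [CausalGene(i, "up_in_old", 4.0) for i in range(10)] + [
        CausalGene(i, "down_in_old", 4.0) for i in range(10, 20)
    ]
    return SyntheticSpec(causal_genes=causal, seed=seed, **overrides)


def default_null_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """A cohort with no planted genes (for error-control experiments)."""
    overrides.setdefault("n_genes", 100)
    overrides.setdefault("cells_per_donor", 200)
    return SyntheticSpec(causal_genes=[], seed=seed, **overrides)


class GroundTruth(dict):
    """Mapping gene symbol -> expected candidate label for causal genes;
    non-causal genes map to None."""

    @property
    def causal_symbols(self) -> list[str]:
        return [g for g, lab in self.items() if lab is not None]

    @property
    def null_symbols(self) -> list[str]:
        return [g for g, lab in self.items() if lab is None]


def _gene_symbols(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def generate_cohort(spec: SyntheticSpec) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate one tissue cohort.

    Returns an AnnData with raw counts (CSR, int64), obs columns
    ``donor_id``, ``age_group`` ("mid"/"old"), ``tissue``, and the
    ground-truth label map. Cells are ordered donor by donor, mid-group
    donors first.
    """
    rng = np.random.default_rng(spec.seed)
    n_d, n_c, n_g = spec.n_donors_per_group, spec.cells_per_donor, spec.n_genes
    n_cells = 2 * n_d * n_c

    log_mu = rng.normal(spec.baseline_mean_log_mu, spec.baseline_mean_log_sigma, size=n_g)
    # Causal genes draw their baseline abundance from the upper half of the
    # panel distribution (half-normal above the mean): a curated panel of
    # age-associated genes only contains genes whose association was
    # detectable upstream, which conditions on adequate expression.
    causal_idx = [g.index for g in spec.causal_genes]
    if causal_idx:
        log_mu[causal_idx] = spec.baseline_mean_log_mu + np.abs(
            rng.normal(0.0, spec.baseline_mean_log_sigma, size=len(causal_idx))
        )
    donor_ids = [f"donor_mid_{i}" for i in range(n_d)] + [f"donor_old_{i}" for i in range(n_d)]
    delta = rng.normal(0.0, spec.donor_effect_sd, size=2 * n_d)
    ell = rng.normal(0.0, spec.libsize_log_sd, size=n_cells)

    effect = np.zeros(n_g)
    for g in spec.causal_genes:
        sign = 1.0 if g.direction == "up_in_old" else -1.0
        effect[g.index] = sign * np.log(g.fold_change)

    donor_of_cell = np.repeat(np.arange(2 * n_d), n_c)
    is_old = (donor_of_cell >= n_d).astype(float)

    log_mean = (
        log_mu[None, :]
        + delta[donor_of_cell, None]
        + ell[:, None]
        + is_old[:, None] * effect[None, :]
    )
    mu = np.exp(log_mean)
    theta = spec.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))

    obs = pd.DataFrame(
        {
            "donor_id": np.array(donor_ids)[donor_of_cell],
            "age_group": np.where(is_old.astype(bool), "old", "mid"),
            "tissue": spec.tissue_label,
        },
        index=pd.Index([f"cell_{i:06d}" for i in range(n_cells)], name="cell_id"),
    )
    var = pd.DataFrame(index=pd.Index(_gene_symbols(n_g), name="gene_symbol"))
    adata = ad.AnnData(X=sp.csr_matrix(counts.astype(np.int64)), obs=obs, var=var)

    truth = GroundTruth({s: None for s in var.index})
    for g in spec.causal_genes:
        truth[var.index[g.index]] = g.expected_label
    return adata, truth


def write_cohort(adata: ad.AnnData, truth: GroundTruth | None, outdir) -> Path:
    """Write the MTX + TSV sidecar layout the pipeline reads.

    Emits ``matrix.mtx`` (cells as rows), ``genes.tsv`` (one symbol per
    line), ``cells.tsv`` (cell_id, donor_id, age_group, tissue) and, when a
    ground truth is given, ``ground_truth.tsv`` (gene, expected_label).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from scipy.io import mmwrite

    mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(adata.X))
    (outdir / "genes.tsv").write_text("\n".join(adata.var_names) + "\n")
    cells = adata.obs.reset_index()
    cells.columns = ["cell_id", "donor_id", "age_group", "tissue"]
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    if truth is not None:
        rows = [(g, lab if lab is not None else "") for g, lab in truth.items()]
        pd.DataFrame(rows, columns=["gene", "expected_label"]).to_csv(
            outdir / "ground_truth.tsv", sep="\t", index=False
        )
    return outdir


def load_spec(path) -> SyntheticSpec:
    """Read a SyntheticSpec from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SyntheticSpec(**data)


def spec_to_dict(spec: SyntheticSpec) -> dict:
    return asdict(spec)
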