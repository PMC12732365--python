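"""In silico knockout / overexpression screen over a fitted age classifier.

For each gene the screen predicts P(old) for a balanced subsample of cells
under two token-space perturbations — knockout (token 0) and strong
overexpression (top token, the cell-wise empirical maximum bin) — and
summarizes the contrast as

    effect = log2( mean P(old | knockout) / mean P(old | overexpression) )

A two-sided Mann-Whitney U test compares the two probability samples and
Holm's step-down correction is applied across all genes screened together.
Significant genes with effect > 0 (knockout looks older than
overexpression, i.e. raising the gene rejuvenates the prediction) are
anti-aging candidates; significant genes with effect < 0 are pro-aging
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .classifier import AgeClassifier
from .preprocess import BinnedMatrix, balanced_subsample, bin_expression, subset_genes
from .stats import holm_adjust, mann_whitney_u

__all__ = [
    "ScreenConfig",
    "GenePerturbationResult",
    "perturb_tokens",
    "screen_gene",
    "classify_candidates",
    "run_screen",
    "results_to_frame",
    "LABEL_ANTI",
    "LABEL_PRO",
    "LABEL_NS",
]

LABEL_ANTI = "anti-aging"
LABEL_PRO = "pro-aging"
LABEL_NS = "not significant"

KNOCKOUT = "knockout"
OVEREXPRESSION = "overexpression"


@dataclass
class ScreenConfig:
    n_per_group: int = 150
    alpha: float = 0.05
    prob_floor: float = 1e-12
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


@dataclass
class GenePerturbationResult:
    gene: str
    effect_log2_ratio: float
    p_raw: float
    p_adjusted: float
    label: str
    n_cells: int


def perturb_tokens(cells: BinnedMatrix, gene: str, mode: str) -> BinnedMatrix:
    """Copy of ``cells`` with one gene's token forced to 0 (knockout) or
    to the top bin ``n_bins - 1`` (overexpression); input is not mutated."""
    if mode not in (KNOCKOUT, OVEREXPRESSION):
        raise ValueError(f"mode must be {KNOCKOUT!r} or {OVEREXPRESSION!r}")
    matches = np.flatnonzero(cells.gene_symbols == gene)
    if len(matches) == 0:
        raise KeyError(f"gene {gene!r} not present")
    tokens = cells.tokens.copy()
    tokens[:, matches[0]] = 0 if mode == KNOCKOUT else cells.n_bins - 1
    return BinnedMatrix(tokens=tokens, n_bins=cells.n_bins, gene_symbols=cells.gene_symbols,
                        cell_ids=cells.cell_ids, obs=cells.obs)


def _effect_and_p(p_ko: np.ndarray, p_oe: np.ndarray, prob_floor: float) -> tuple[float, float]:
    effect = float(np.log2(max(p_ko.mean(), prob_floor) / max(p_oe.mean(), prob_floor)))
    _, p_raw = mann_whitney_u(p_ko, p_oe)
    return effect, p_raw


def screen_gene(model: AgeClassifier, cells: BinnedMatrix, gene: str,
                cfg: ScreenConfig) -> tuple[float, float]:
    """Effect size and raw Mann-Whitney p for one gene on an already
    balanced-subsampled token matrix."""
    if cells.n_cells < 2:
        raise ValueError("need at least 2 cells")
    p_ko = model.predict_old_prob(perturb_tokens(cells, gene, KNOCKOUT))
    p_oe = model.predict_old_prob(perturb_tokens(cells, gene, OVEREXPRESSION))
    return _effect_and_p(p_ko, p_oe, cfg.prob_floor)


def classify_candidates(effect: float, p_adjusted: float, alpha: float) -> str:
    """Direction + significance rule: significant positive effect (knockout
    prediction older than overexpression) is anti-aging, significant
    negative effect is pro-aging; zero effect carries no direction."""
    if p_adjusted < alpha and effect > 0:
        return LABEL_ANTI
    if p_adjusted < alpha and effect < 0:
        return LABEL_PRO
    return LABEL_NS


def run_screen(model: AgeClassifier, cells: ad.AnnData, genes=None,
               cfg: ScreenConfig | None = None) -> tuple[list[GenePerturbationResult], list[str]]:
    """Run the full screen on one tissue.

    Draws one balanced subsample of ``cfg.n_per_group`` cells per age
    group, bins the model's gene set, screens every requested gene, Holm-
    adjusts across all screened genes jointly and labels candidates.
    Genes absent from the model's input space are skipped and returned in
    the second element.
    """
    cfg = cfg or ScreenConfig()
    requested = list(genes) if genes is not None else list(model.gene_symbols)
    model_genes = set(model.gene_symbols)
    skipped = [g for g in requested if g not in model_genes]
    screened = [g for g in requested if g in model_genes]
    if not screened:
        raise ValueError("no requested gene is in the model's input space")

    subset, _ = subset_genes(cells, list(model.gene_symbols))
    if list(subset.var_names) != list(model.gene_symbols):
        subset = subset[:, list(model.gene_symbols)].copy()
    idx = balanced_subsample(subset, cfg.n_per_group, cfg.seed)
    binned = bin_expression(subset[idx].copy(), model.n_bins)

    col_of = {g: j for j, g in enumerate(binned.gene_symbols)}
    gene_idx = np.array([col_of[g] for g in screened])
    p_ko = model.perturbation_probs(binned.tokens, gene_idx, 0)
    p_oe = model.perturbation_probs(binned.tokens, gene_idx, model.n_bins - 1)

    effects = np.empty(len(screened))
    p_raw = np.empty(len(screened))
    for j in range(len(screened)):
        effects[j], p_raw[j] = _effect_and_p(p_ko[j], p_oe[j], cfg.prob_floor)
    p_adj = holm_adjust(p_raw)
    n_cells = binned.n_cells
    results = [
        GenePerturbationResult(
            gene=g,
            effect_log2_ratio=float(effects[j]),
            p_raw=float(p_raw[j]),
            p_adjusted=float(p_adj[j]),
            label=classify_candidates(effects[j], p_adj[j], cfg.alpha),
            n_cells=n_cells,
        )
        for j, g in enumerate(screened)
    ]
    return results, skipped


def results_to_frame(results: list[GenePerturbationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene, r.effect_log2_ratio, r.p_raw, r.p_adjusted, r.label, r.n_cells) for r in results],
        columns=["gene", "effect_log2_ratio", "p_raw", "p_adjusted", "label", "n_cells"],
    )
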