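"""Stability of candidate calls under repeated balanced subsampling.

The screen is repeated ``n_iterations`` times (default 10), each time on a
fresh independent balanced subsample of cells, with the fitted model held
fixed. Per gene, stability is the fraction of iterations in which it was
called with a given direction; the effect mean/SD and the worst-case
(maximal) adjusted p-value across iterations summarize robustness.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .classifier import AgeClassifier
from .screen import LABEL_ANTI, LABEL_PRO, ScreenConfig, run_screen

__all__ = ["StabilitySummary", "run_stability", "rank_by_stability", "summaries_to_frame"]

_P_FLOOR = 1e-300  # keeps log10 finite for vanishingly small adjusted p


@dataclass
class StabilitySummary:
    gene: str
    stability_anti: float
    stability_pro: float
    effect_mean: float
    effect_sd: float
    max_log10_p_adj: float
    n_iterations: int

    @property
    def stability(self) -> float:
        return max(self.stability_anti, self.stability_pro)


def run_stability(model: AgeClassifier, cells: ad.AnnData, genes=None,
                  cfg: ScreenConfig | None = None, n_iterations: int = 10,
                  base_seed: int = 0) -> list[StabilitySummary]:
    """Repeat the screen on independent subsamples (seeds ``base_seed + i``)
    and aggregate per-gene stability fractions, effect mean/SD (over all
    iterations, significant or not) and the maximal log10 adjusted p."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    cfg = cfg or ScreenConfig()
    per_gene: dict[str, dict] = {}
    for i in range(n_iterations):
        it_cfg = ScreenConfig(n_per_group=cfg.n_per_group, alpha=cfg.alpha,
                              prob_floor=cfg.prob_floor, seed=base_seed + i)
        results, _ = run_screen(model, cells, genes, it_cfg)
        for r in results:
            rec = per_gene.setdefault(r.gene, {"anti": 0, "pro": 0, "effects": [], "p_adj": []})
            rec["anti"] += r.label == LABEL_ANTI
            rec["pro"] += r.label == LABEL_PRO
            rec["effects"].append(r.effect_log2_ratio)
            rec["p_adj"].append(max(r.p_adjusted, _P_FLOOR))
    out = []
    for gene, rec in per_gene.items():
        effects = np.array(rec["effects"])
        out.append(StabilitySummary(
            gene=gene,
            stability_anti=rec["anti"] / n_iterations,
            stability_pro=rec["pro"] / n_iterations,
            effect_mean=float(effects.mean()),
            effect_sd=float(effects.std(ddof=0)),
            max_log10_p_adj=float(np.log10(max(rec["p_adj"]))),
            n_iterations=n_iterations,
        ))
    return out


def rank_by_stability(summaries: list[StabilitySummary]) -> list[StabilitySummary]:
    """Descending by stability, ties by |effect mean| descending, then by
    gene symbol."""
    return sorted(summaries, key=lambda s: (-s.stability, -abs(s.effect_mean), s.gene))


def summaries_to_frame(summaries: list[StabilitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.gene, s.stability_anti, s.stability_pro, s.effect_mean, s.effect_sd,
          s.max_log10_p_adj, s.n_iterations) for s in summaries],
        columns=["gene", "stability_anti", "stability_pro", "effect_mean", "effect_sd",
                 "max_log10_p_adj", "n_iterations"],
    )
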