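"""Overlap of stable candidates with a curated aging-gene table and the
plot-ready volcano table.

The curated table follows the Open Genes convention: one row per gene
symbol with an evidence confidence level from a fixed five-step vocabulary
("highest" ... "lowest"). Mitochondrial (``MT-``) and heat-shock (``HSP``
family) genes are dropped from reported tables because their expression
often reflects technical artifacts of droplet scRNA-seq rather than
biology.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stability import StabilitySummary

__all__ = [
    "CONFIDENCE_LEVELS",
    "AgingGeneDB",
    "read_aging_gene_db",
    "overlap_fraction",
    "filter_artifact_genes",
    "volcano_table",
]

CONFIDENCE_LEVELS = ("highest", "high", "moderate", "low", "lowest")

_SYMBOL_COLUMNS = ("symbol", "gene", "gene_symbol", "hgnc")
_CONFIDENCE_COLUMNS = ("confidence", "confidence_level", "confidence level")

# mitochondrial-encoded genes, and the HSP chaperone families
_ARTIFACT_RE = re.compile(r"^(MT-|HSP(A|B|D|E|H|90))", re.IGNORECASE)


@dataclass
class AgingGeneDB:
    """Curated aging-gene table: symbol -> confidence level."""

    entries: dict[str, str]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def restrict(self, confidence_filter) -> "AgingGeneDB":
        keep = set(confidence_filter)
        bad = keep - set(CONFIDENCE_LEVELS)
        if bad:
            raise ValueError(f"unknown confidence level(s): {sorted(bad)}")
        return AgingGeneDB({g: c for g, c in self.entries.items() if c in keep})


def read_aging_gene_db(path) -> AgingGeneDB:
    """Parse a tab-separated aging-gene table with symbol and confidence
    columns; rejects duplicate symbols and out-of-vocabulary confidence
    strings."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    sym_col = next((cols[c] for c in _SYMBOL_COLUMNS if c in cols), None)
    conf_col = next((cols[c] for c in _CONFIDENCE_COLUMNS if c in cols), None)
    if sym_col is None or conf_col is None:
        raise ValueError(
            f"table must have a symbol column (one of {_SYMBOL_COLUMNS}) and a "
            f"confidence column (one of {_CONFIDENCE_COLUMNS}); found {list(df.columns)}"
        )
    symbols = df[sym_col].astype(str).str.strip()
    conf = df[conf_col].astype(str).str.strip().str.lower()
    dup = sorted(symbols[symbols.duplicated()].unique())
    if dup:
        raise ValueError(f"duplicate gene symbols in table: {dup}")
    bad = sorted(set(conf) - set(CONFIDENCE_LEVELS))
    if bad:
        raise ValueError(f"unknown confidence level(s): {bad}")
    return AgingGeneDB(dict(zip(symbols, conf)))


def overlap_fraction(summaries: list[StabilitySummary], db: AgingGeneDB,
                     stability_threshold: float = 1.0,
                     confidence_filter=None) -> tuple[float | None, dict[str, bool]]:
    """Fraction of stable candidates present in the curated table.

    Candidates are genes whose best-direction stability reaches the
    threshold. Returns ``(fraction, flags)``; the fraction is ``None``
    (not 0) when there is no candidate, and ``flags`` marks each
    candidate's table membership.
    """
    if not 0 < stability_threshold <= 1:
        raise ValueError("stability_threshold must be in (0, 1]")
    if confidence_filter is not None:
        db = db.restrict(confidence_filter)
    candidates = [s.gene for s in summaries if s.stability >= stability_threshold]
    if not candidates:
        return None, {}
    flags = {g: g in db for g in candidates}
    return sum(flags.values()) / len(candidates), flags


def filter_artifact_genes(summaries: list[StabilitySummary]) -> list[StabilitySummary]:
    """Drop mitochondrial (``MT-`` prefixed) and heat-shock
    (HSPA/HSPB/HSPD/HSPE/HSPH/HSP90 family) genes."""
    return [s for s in summaries if not _ARTIFACT_RE.match(s.gene)]


def volcano_table(summaries: list[StabilitySummary], db: AgingGeneDB | None = None) -> pd.DataFrame:
    """Plot-ready table: x = mean effect (log2 knockout/overexpression
    probability ratio), y = -log10 of the maximal (least significant)
    adjusted p across iterations, error-bar half-width = effect SD,
    direction of the more frequent call, and curated-table membership.
    Artifact genes are removed."""
    rows = []
    for s in filter_artifact_genes(summaries):
        if s.stability_anti > s.stability_pro:
            direction = "anti-aging"
        elif s.stability_pro > s.stability_anti:
            direction = "pro-aging"
        else:
            direction = "none" if s.stability == 0 else "mixed"
        in_db = db is not None and s.gene in db
        rows.append((
            s.gene,
            s.effect_mean,
            s.effect_sd,
            float(-s.max_log10_p_adj),
            direction,
            bool(in_db),
            db.entries.get(s.gene, "") if db is not None else "",
        ))
    return pd.DataFrame(
        rows,
        columns=["gene", "x_effect_mean", "sd", "y_neglog10_maxp", "direction", "in_db", "confidence"],
    )
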