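"""End-to-end orchestration: simulate -> preprocess -> train -> screen ->
stability -> report, per tissue, from one YAML-configurable RunConfig.

Each stage writes a plain TSV (inspectable, resumable) under the output
directory, and a ``manifest.json`` records the config echo, derived seeds,
package version and per-stage row counts. A second run with the same
config reproduces all stage tables bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import read_aging_gene_db, volcano_table
from .classifier import (TrainConfig, evaluate_auc, fit_logistic_baseline,
                         fit_mlp_head, save_model)
from .preprocess import bin_expression, filter_genes, read_counts, split_by_donor
from .screen import ScreenConfig, results_to_frame, run_screen
from .simulate import SyntheticSpec, generate_cohort, write_cohort
from .stability import run_stability, summaries_to_frame

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

log = logging.getLogger("agescreen")


@dataclass
class RunConfig:
    output_dir: str = "agescreen_out"
    input_dir: str | None = None
    simulate: SyntheticSpec | None = None
    db_path: str | None = None
    backend: str = "mlp"
    min_cell_fraction: float = 0.01
    n_bins: int = 51
    test_donor_fraction: float = 0.25
    train: TrainConfig = field(default_factory=TrainConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    n_iterations: int = 10
    confidence_filter: list[str] | None = None
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.simulate, dict):
            self.simulate = SyntheticSpec(**self.simulate)
        if isinstance(self.train, dict):
            self.train = TrainConfig(**self.train)
        if isinstance(self.screen, dict):
            self.screen = ScreenConfig(**self.screen)
        if self.backend not in ("mlp", "logistic"):
            raise ValueError("backend must be 'mlp' or 'logistic'")
        if self.input_dir is None and self.simulate is None:
            raise ValueError("either input_dir or a simulate block is required")
        if self.confidence_filter and not self.db_path:
            raise ValueError("db_path is required when confidence_filter is set "
                             "(the report stage needs a curated gene table)")


def load_run_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name, manifest, fn, *args, **kwargs):
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
        raise StageError(name, exc) from exc
    dt = time.perf_counter() - t0
    log.info("stage %s: done in %.1fs", name, dt)
    manifest["stages"].append({"name": name, "seconds": round(dt, 2)})
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages for every tissue in the data; returns
    the manifest (also written to ``<output_dir>/manifest.json``)."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.seed)
    manifest: dict = {
        "version": __version__,
        "config": _config_echo(cfg),
        "seed": seed,
        "stages": [],
        "tissues": {},
    }

    if cfg.simulate is not None:
        def _simulate():
            spec = cfg.simulate
            adata, truth = generate_cohort(spec)
            write_cohort(adata, truth, outdir / "simulated")
            return adata
        adata = _stage("simulate", manifest, _simulate)
    else:
        adata = _stage("read", manifest, read_counts, cfg.input_dir)

    db = read_aging_gene_db(cfg.db_path) if cfg.db_path else None
    if cfg.confidence_filter and db is not None:
        db = db.restrict(cfg.confidence_filter)

    for tissue in sorted(adata.obs["tissue"].unique()):
        tdir = outdir / str(tissue)
        tdir.mkdir(exist_ok=True)
        tis = adata[adata.obs["tissue"] == tissue].copy()
        info: dict = {"n_cells": int(tis.n_obs)}
        manifest["tissues"][str(tissue)] = info

        def _preprocess():
            filtered = filter_genes(tis, cfg.min_cell_fraction)
            split = split_by_donor(filtered, cfg.test_donor_fraction, seed=seed + 1)
            return filtered, split
        filtered, split = _stage(f"preprocess[{tissue}]", manifest, _preprocess)
        info["n_genes_kept"] = int(filtered.n_vars)
        info["test_donors"] = sorted(split.test_donors)

        def _train():
            train_cells = filtered[split.train_mask(filtered)].copy()
            test_cells = filtered[split.test_mask(filtered)].copy()
            binned_train = bin_expression(train_cells, cfg.n_bins)
            binned_test = bin_expression(test_cells, cfg.n_bins)
            labels_train = train_cells.obs["age_group"].to_numpy()
            labels_test = test_cells.obs["age_group"].to_numpy()
            if cfg.backend == "mlp":
                tc = TrainConfig(**{**asdict(cfg.train), "seed": seed + 2})
                model = fit_mlp_head(binned_train, labels_train, tc)
            else:
                model = fit_logistic_baseline(binned_train, labels_train, seed=seed + 2)
            auc = evaluate_auc(model, binned_test, labels_test)
            save_model(model, tdir / "model.pkl")
            return model, auc
        model, auc = _stage(f"train[{tissue}]", manifest, _train)
        info["heldout_auc"] = round(float(auc), 4)

        def _screen():
            scfg = ScreenConfig(n_per_group=cfg.screen.n_per_group, alpha=cfg.screen.alpha,
                                prob_floor=cfg.screen.prob_floor, seed=seed + 3)
            results, skipped = run_screen(model, tis, None, scfg)
            frame = results_to_frame(results)
            frame.to_csv(tdir / "screen.tsv", sep="\t", index=False)
            return frame, skipped
        screen_frame, _ = _stage(f"screen[{tissue}]", manifest, _screen)
        info["n_screened"] = int(len(screen_frame))

        def _stability():
            scfg = ScreenConfig(n_per_group=cfg.screen.n_per_group, alpha=cfg.screen.alpha,
                                prob_floor=cfg.screen.prob_floor, seed=0)
            summaries = run_stability(model, tis, None, scfg,
                                      n_iterations=cfg.n_iterations, base_seed=seed + 10)
            frame = summaries_to_frame(summaries).sort_values("gene").reset_index(drop=True)
            frame.to_csv(tdir / "stability.tsv", sep="\t", index=False)
            return summaries
        summaries = _stage(f"stability[{tissue}]", manifest, _stability)
        info["n_stable_full"] = int(sum(s.stability >= 1.0 for s in summaries))

        def _report():
            table = volcano_table(summaries, db).sort_values("gene").reset_index(drop=True)
            table.to_csv(tdir / "volcano.tsv", sep="\t", index=False)
            return table
        if db is not None:
            _stage(f"report[{tissue}]", manifest, _report)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_echo(cfg: RunConfig) -> dict:
    echo = {k: v for k, v in vars(cfg).items()}
    echo["train"] = asdict(cfg.train)
    echo["screen"] = asdict(cfg.screen)
    echo["simulate"] = asdict(cfg.simulate) if cfg.simulate is not None else None
    return echo
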