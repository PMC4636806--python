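"""Stage orchestration: simulate/ingest -> preprocess -> correlate -> enrich/topology.

A run is driven by a small YAML config (the single source of truth; CLI flags
override it) and leaves behind a manifest recording the package version, the
seed, SHA-256 digests of inputs and outputs, and per-stage parameters, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, generate_cohort
from .enrichment import bin_pairs, gsea_permutation_p
from .preprocess import batch_adjust, quantile_normalize
from .screen import TargetScreen
from .sequence_io import (
    read_bed_loci,
    read_expression_tsv,
    read_metadata_tsv,
    read_predictions,
    predictions_frame,
    write_bed_loci,
    write_expression_tsv,
    write_metadata_tsv,
    write_predictions,
)

log = logging.getLogger("mirdecoy")


def screen_cohort(data, alpha: float = 0.05, use_bh: bool = False, qnorm: bool = True,
                  adjust_batch: bool = True):
    """Preprocess a generated cohort and fit the target screen in memory.

    Mirrors the preprocess and correlate stages without touching disk;
    returns the fitted :class:`~mirdecoy.screen.TargetScreenResults`.
    """
    expr = data.expression
    if qnorm:
        expr = quantile_normalize(expr)
    if adjust_batch:
        expr = batch_adjust(expr, data.metadata)
    dct = data.mirna_measurements.pivot(
        index="sample_id", columns="mirna_id", values="delta_ct"
    )
    screen = TargetScreen.from_delta_ct(expr, dct, data.predictions, alpha=alpha, use_bh=use_bh)
    return screen.fit()

STAGE_ORDER = ["simulate", "preprocess", "correlate", "enrich", "topology"]


@dataclass
class RunConfig:
    """Configuration envelope for a pipeline run."""

    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    outdir: Path = Path("mirdecoy_run")
    seed: int = 0
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            stages=raw.get("stages", list(STAGE_ORDER)),
            outdir=Path(raw.get("outdir", "mirdecoy_run")),
            seed=int(raw.get("seed", 0)),
            params={k: dict(v) for k, v in raw.get("params", {}).items()},
        )

    def stage_params(self, stage: str) -> dict[str, Any]:
        return dict(self.params.get(stage, {}))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage dependency: {needed_by!r} needs {path.name} from stage {stage!r}"
        )
    return path


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run the configured stages in dependency order; returns the manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "mirdecoy",
        "version": __version__,
        "seed": cfg.seed,
        "stages": [],
        "files": {},
    }
    stages = [s for s in STAGE_ORDER if s in cfg.stages]

    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "mirna": outdir / "mirna_dct.tsv",
        "predictions": outdir / "predictions.tsv",
        "loci": outdir / "loci.bed",
        "normalized": outdir / "normalized.tsv",
        "pairs": outdir / "pairs.tsv",
        "ranked": outdir / "ranked.tsv",
        "enrichment": outdir / "enrichment.tsv",
        "track": outdir / "topology_track.tsv",
    }

    for stage in stages:
        params = cfg.stage_params(stage)
        log.info("stage %s (seed %d) params=%s", stage, cfg.seed, params)
        if stage == "simulate":
            cohort_cfg = CohortConfig(seed=cfg.seed, **params)
            data = generate_cohort(cohort_cfg)
            write_expression_tsv(data.expression, paths["expression"])
            write_metadata_tsv(data.metadata, paths["metadata"])
            data.mirna_measurements.to_csv(paths["mirna"], sep="\t", index=False)
            write_predictions(data.predictions, paths["predictions"])
            write_bed_loci(data.loci, paths["loci"])
        elif stage == "preprocess":
            expr = read_expression_tsv(_require(paths["expression"], "simulate", stage))
            meta = read_metadata_tsv(_require(paths["metadata"], "simulate", stage))
            if params.get("qnorm", True):
                expr = quantile_normalize(expr)
            if params.get("batch_adjust", True):
                expr = batch_adjust(expr, meta)
            write_expression_tsv(expr, paths["normalized"])
        elif stage == "correlate":
            expr = read_expression_tsv(_require(paths["normalized"], "preprocess", stage))
            meas = pd.read_csv(_require(paths["mirna"], "simulate", stage), sep="\t")
            dct = meas.pivot(index="sample_id", columns="mirna_id", values="delta_ct")
            preds = read_predictions(_require(paths["predictions"], "simulate", stage))
            screen = TargetScreen.from_delta_ct(
                expr,
                dct,
                preds,
                correlate_raw_dct=params.get("correlate_raw_dct", False),
                alpha=params.get("alpha", 0.05),
                use_bh=params.get("bh", False),
            )
            results = screen.fit()
            results.pairs.to_csv(paths["pairs"], sep="\t", index=False)
            results.candidates.to_csv(paths["ranked"], sep="\t", index=False)
            (outdir / "summary.txt").write_text(results.summary() + "\n")
        elif stage == "enrich":
            pairs = pd.read_csv(_require(paths["pairs"], "correlate", stage), sep="\t")
            preds = predictions_frame(
                read_predictions(_require(paths["predictions"], "simulate", stage))
            )
            rows = []
            for mirna_id, sub in pairs.groupby("mirna"):
                metric = sub.set_index("gene")["r"]
                gene_set = set(preds.loc[preds["mirna"] == mirna_id, "gene"])
                res = gsea_permutation_p(
                    metric,
                    gene_set,
                    nperm=int(params.get("nperm", 1000)),
                    seed=cfg.seed,
                    set_name=f"predicted_targets_{mirna_id}",
                )
                rows.append(
                    {
                        "set": res.set_name,
                        "es": res.es,
                        "nperm": res.nperm,
                        "p_perm": res.p_perm,
                        "n_leading_edge": len(res.leading_edge),
                    }
                )
            pd.DataFrame(rows).to_csv(paths["enrichment"], sep="\t", index=False)
        elif stage == "topology":
            ranked = pd.read_csv(_require(paths["ranked"], "correlate", stage), sep="\t")
            loci = read_bed_loci(_require(paths["loci"], "simulate", stage))
            bins, n_unlocated = bin_pairs(
                ranked, loci, bin_size=int(params.get("bin_size", 1_000_000))
            )
            bins.to_csv(paths["track"], sep="\t", index=False)
            log.info("topology: %d pairs without loci", n_unlocated)
        manifest["stages"].append({"stage": stage, "params": params})

    for name, path in paths.items():
        if path.exists():
            manifest["files"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
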