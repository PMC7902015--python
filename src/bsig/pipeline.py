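"""End-to-end pipeline: simulate -> normalize -> DEG -> ORA -> score ->
similar entities -> proliferation/apoptosis, with a run manifest.

One top-level seed is fanned out to per-stage sub-seeds through a
counter-based SeedSequence derivation, so a single integer reproduces the
whole run; the manifest records SHA-256 checksums of every output so
determinism is assertable as checksum equality.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import find_similar_entities
from .degs import call_degs, moderated_t_test, normalize_percentile, ora_fisher
from .errors import ConfigError
from .io import (
    write_expression,
    write_flow_events,
    write_gmt,
    write_metadata,
    write_table,
)
from .proliferation import (
    ApoptosisGate,
    apoptosis_fractions,
    assign_generations,
    proliferation_index,
)
from .signatures import compare_scores, signature_score
from .synthetic import (
    config_from_dict,
    config_to_dict,
    simulate_division_experiment,
    simulate_expression_study,
)

log = logging.getLogger("bsig")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int
    out_dir: str
    expression_sim: dict = field(default_factory=dict)
    division_sim: dict = field(default_factory=dict)
    percentile: float = 75.0
    p_thresh: float = 0.05
    fc_thresh: float = 2.0
    ora_p_thresh: float = 0.01
    anchor_gene: str = "FOXM1"
    r_min: float = 0.6
    r_max: float = 1.0
    annexin_threshold: float = 700.0
    viability_threshold: float = 700.0
    run_deg: bool = True
    run_score: bool = True
    run_similar: bool = True
    run_flow: bool = True

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        if not (0 < self.p_thresh <= 1):
            raise ConfigError(f"p_thresh must lie in (0, 1], got {self.p_thresh}")
        if not (0 < self.ora_p_thresh <= 1):
            raise ConfigError(f"ora_p_thresh must lie in (0, 1], got {self.ora_p_thresh}")
        if self.fc_thresh < 1:
            raise ConfigError(f"fc_thresh must be >= 1, got {self.fc_thresh}")
        if not (0 < self.percentile <= 100):
            raise ConfigError(f"percentile must lie in (0, 100], got {self.percentile}")
        if not (-1 <= self.r_min <= self.r_max <= 1):
            raise ConfigError("need -1 <= r_min <= r_max <= 1")
        if self.run_similar and not self.run_deg:
            raise ConfigError("the similar-entities stage needs the DEG stage enabled")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        if "seed" not in payload:
            raise ConfigError("config must set a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**payload)
        config.validate()
        return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages in dependency order; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    stage_seeds = [int(s) for s in np.random.SeedSequence(config.seed).generate_state(2) % (2**31)]
    outputs: list[Path] = []

    log.info("stage simulate: expression study (seed %d)", stage_seeds[0])
    expr_cfg = config_from_dict({**config.expression_sim, "seed": stage_seeds[0]}, "expression")
    matrix, sheet, truth = simulate_expression_study(expr_cfg)
    write_expression(matrix, out / "matrix.tsv")
    write_metadata(sheet, out / "metadata.tsv")
    truth.to_json(out / "truth.json")
    write_gmt(truth.gene_sets(), out / "sets.gmt")
    outputs += [out / "matrix.tsv", out / "metadata.tsv", out / "truth.json", out / "sets.gmt"]

    log.info("stage normalize: percentile %.1f", config.percentile)
    normalized = normalize_percentile(matrix, config.percentile)
    write_expression(normalized, out / "normalized.tsv")
    outputs.append(out / "normalized.tsv")

    deg_results = {}
    if config.run_deg:
        for subset in expr_cfg.subsets:
            stats_table = moderated_t_test(normalized, sheet, subset, prior="fit")
            result = call_degs(
                stats_table,
                p_thresh=config.p_thresh,
                fc_thresh=config.fc_thresh,
                contrast=f"{subset}:SLE_vs_HC",
            )
            deg_results[subset] = result
            table = result.stats.reset_index(names="gene_id").rename(
                columns={"mean_a": "mean_HC", "mean_b": "mean_SLE"}
            )[["gene_id", "mean_HC", "mean_SLE", "fc_signed", "t_mod", "df_total", "p", "call"]]
            write_table(table, out / f"deg_{subset}.tsv")
            outputs.append(out / f"deg_{subset}.tsv")
            log.info(
                "stage deg[%s]: %d up, %d down",
                subset, len(result.up_genes), len(result.down_genes),
            )
        pb = deg_results["plasmablast"]
        ora = ora_fisher(
            pb.deg_genes, matrix.gene_ids, truth.gene_sets(), p_thresh=config.ora_p_thresh
        )
        write_table(ora, out / "ora.tsv")
        outputs.append(out / "ora.tsv")

    if config.run_score:
        frames = []
        comparisons = []
        for gs in truth.gene_sets():
            table = signature_score(normalized, gs)
            frames.append(table.to_frame(sheet))
            comp = compare_scores(table, sheet)
            comparisons.append(comp["subset_contrasts"])
        write_table(pd.concat(frames, ignore_index=True), out / "scores.tsv")
        write_table(pd.concat(comparisons, ignore_index=True), out / "compare.tsv")
        outputs += [out / "scores.tsv", out / "compare.tsv"]

    if config.run_similar:
        candidates = deg_results["plasmablast"].deg_genes
        if config.anchor_gene not in candidates:
            candidates = [config.anchor_gene] + candidates
        sim = find_similar_entities(
            normalized, config.anchor_gene, candidates, r_min=config.r_min, r_max=config.r_max
        )
        table = sim.r.reset_index()
        table.columns = ["gene_id", "r"]
        table["selected"] = table["gene_id"].isin(set(sim.selected))
        write_table(table, out / "similar.tsv")
        outputs.append(out / "similar.tsv")
        log.info("stage similar: %d of %d candidates selected", len(sim.selected), len(table))

    if config.run_flow:
        div_cfg = config_from_dict({**config.division_sim, "seed": stage_seeds[1]}, "division")
        events, founders = simulate_division_experiment(div_cfg)
        write_flow_events(events, out / "events.csv")
        dist = assign_generations(events, div_cfg.dye_gen0_mean, div_cfg.max_generation)
        pi = proliferation_index(dist)
        pi_table = pd.DataFrame(
            {
                "generation": np.arange(dist.i_max + 1),
                "count": dist.counts.astype(int),
                "percent": dist.percentages,
            }
        )
        pi_table["pi"] = pi.pi
        pi_table["founders_equivalent"] = pi.founders_equivalent
        write_table(pi_table, out / "pi.tsv")
        gate = ApoptosisGate(config.annexin_threshold, config.viability_threshold)
        fractions = apoptosis_fractions(events, gate)
        write_table(
            pd.DataFrame([{"class": k, "fraction": v} for k, v in fractions.items()]),
            out / "apoptosis.tsv",
        )
        outputs += [out / "events.csv", out / "pi.tsv", out / "apoptosis.tsv"]
        log.info("stage flow: %d events from %d founders, PI = %.3f",
                 len(events), founders, pi.pi)

    manifest = {
        "version": __version__,
        "config": {
            **{k: getattr(config, k) for k in RunConfig.__dataclass_fields__
               if k not in ("expression_sim", "division_sim")},
            "expression_sim": config_to_dict(expr_cfg),
            "division_sim": config_to_dict(div_cfg) if config.run_flow else {},
        },
        "started": started,
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "checksums": {p.name: _sha256(p) for p in outputs},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
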