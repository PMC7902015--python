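"""Synthetic data generators with planted ground truth.

Two generators mirror the study design the analysis modules target:

* :func:`simulate_expression_study` emulates a 3-subset x 2-group x
  4-donor expression array study on the log2 scale, planting (i) an
  interferon-stimulated-gene effect in SLE samples of every subset,
  (ii) a cell-cycle effect in SLE plasmablasts only, and (iii) a
  FOXM1-anchored coexpression module driven by a latent factor that is
  elevated only in SLE plasmablasts.

* :func:`simulate_division_experiment` emulates a proliferation-dye
  dilution culture: founders progress through a per-generation Bernoulli
  division chain, a founder stopping at generation i contributes 2**i
  events whose dye intensity is lognormal around gen0_mean / 2**i, and
  apoptosis channels are drawn per gated class (live / early / late).

Per-gene residual variances are drawn from a scaled-inverse-chi-square
prior, so the moderated t-test's empirical-Bayes prior is well specified
and recoverable. Identical (config, seed) reproduces outputs exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, FlowEventTable, GeneSet, SampleSheet, SUBSETS
from .errors import ConfigError


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the expression-study generator.

    noise_sd is the prior scale s0 of per-gene residual SDs; the actual
    per-gene variance is s0^2 * d0 / chi2(d0) with d0 = noise_prior_df.
    Effect sizes are log2 fold changes added to SLE samples.
    foxm1_module_loading is the target correlation of each module gene to
    the anchor's latent factor across samples.
    """

    n_genes: int = 5000
    n_donors_per_group: int = 4
    subsets: tuple[str, ...] = SUBSETS
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    subset_offset_sd: float = 1.0
    donor_sd: float = 0.0
    noise_sd: float = 0.5
    noise_prior_df: float = 4.0
    ifn_set_size: int = 23
    ifn_log2fc: float = 1.0
    cc_set_size: int = 231
    cc_log2fc: float = 1.0
    foxm1_module_size: int = 100
    foxm1_module_loading: float = 0.8
    foxm1_anchor_log2fc: float = 2.0
    factor_within_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        n_planted = self.ifn_set_size + self.cc_set_size + self.foxm1_module_size + 1
        if n_planted > self.n_genes:
            raise ConfigError(
                f"planted sets need {n_planted} genes but n_genes = {self.n_genes}"
            )
        if self.n_donors_per_group < 1:
            raise ConfigError("n_donors_per_group must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.noise_prior_df <= 0:
            raise ConfigError("noise_prior_df must be > 0")
        if not (0 < self.foxm1_module_loading <= 1):
            raise ConfigError("foxm1_module_loading must be in (0, 1]")
        if self.ifn_set_size < 0 or self.cc_set_size < 0 or self.foxm1_module_size < 0:
            raise ConfigError("set sizes must be >= 0")
        if self.baseline_mean_range[0] > self.baseline_mean_range[1]:
            raise ConfigError("baseline_mean_range must be an interval (lo, hi)")
        if self.subset_offset_sd < 0 or self.donor_sd < 0 or self.factor_within_sd < 0:
            raise ConfigError("standard deviations must be >= 0")


@dataclass
class GroundTruth:
    """Planted effects: the acceptance surface for recovery tests.

    `effects` is a long-format table (gene_id, subset, effect_log2) of the
    true SLE-minus-HC log2 mean shift; genes/subsets absent from it have
    zero effect.
    """

    ifn_genes: list[str]
    cc_genes: list[str]
    foxm1_anchor: str
    foxm1_module_genes: list[str]
    effects: pd.DataFrame

    def effect(self, gene_id: str, subset: str) -> float:
        m = (self.effects["gene_id"] == gene_id) & (self.effects["subset"] == subset)
        sel = self.effects.loc[m, "effect_log2"]
        return float(sel.iloc[0]) if len(sel) else 0.0

    def gene_sets(self) -> list[GeneSet]:
        out = []
        if self.ifn_genes:
            out.append(GeneSet("IFN_SIGNATURE", "planted type I IFN signature",
                               tuple(self.ifn_genes)))
        if self.cc_genes:
            out.append(GeneSet("CELL_CYCLE_SIGNATURE", "planted cell-cycle signature",
                               tuple(self.cc_genes)))
        return out

    def to_json(self, path) -> None:
        payload = {
            "ifn_genes": self.ifn_genes,
            "cc_genes": self.cc_genes,
            "foxm1_anchor": self.foxm1_anchor,
            "foxm1_module_genes": self.foxm1_module_genes,
            "effects": self.effects.to_dict(orient="list"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            ifn_genes=payload["ifn_genes"],
            cc_genes=payload["cc_genes"],
            foxm1_anchor=payload["foxm1_anchor"],
            foxm1_module_genes=payload["foxm1_module_genes"],
            effects=pd.DataFrame(payload["effects"],
                                 columns=["gene_id", "subset", "effect_log2"]),
        )


def _gene_names(config: SimulationConfig) -> tuple[list[str], dict[str, list[str]]]:
    ifn = [f"ISG{i:03d}" for i in range(1, config.ifn_set_size + 1)]
    cc = [f"CCG{i:03d}" for i in range(1, config.cc_set_size + 1)]
    module = [f"FXM{i:03d}" for i in range(1, config.foxm1_module_size + 1)]
    n_rest = config.n_genes - len(ifn) - len(cc) - len(module) - 1
    rest = [f"G{i:05d}" for i in range(1, n_rest + 1)]
    genes = ["FOXM1", *ifn, *cc, *module, *rest]
    return genes, {"ifn": ifn, "cc": cc, "module": module, "rest": rest}


def simulate_expression_study(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleSheet, GroundTruth]:
    """Generate one expression study with planted ground truth.

    Each observation is gene baseline + per-gene subset offset + optional
    donor random effect + planted effect + N(0, sigma_g) on the log2
    scale. The FOXM1 anchor carries the latent module factor without
    residual noise, so the configured loading equals the population
    correlation between a module gene and the anchor.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, groupsmap = _gene_names(config)
    n_sub = len(config.subsets)
    n_don = config.n_donors_per_group

    rows = []
    for subset in config.subsets:
        for group in ("HC", "SLE"):
            for d in range(1, n_don + 1):
                donor = f"{group}{d}"
                rows.append((f"{donor}_{subset}", donor, group, subset))
    sheet = SampleSheet(pd.DataFrame(rows, columns=["sample_id", "donor_id", "group", "subset"]))
    n_samples = len(rows)
    sample_subset = np.array([r[3] for r in rows])
    sample_group = np.array([r[2] for r in rows])
    sample_donor = np.array([r[1] for r in rows])

    n_genes = config.n_genes
    lo, hi = config.baseline_mean_range
    baseline = rng.uniform(lo, hi, size=n_genes)
    # Per-gene residual variance from a scaled-inverse-chi-square prior.
    d0 = config.noise_prior_df
    sigma_sq = config.noise_sd**2 * d0 / rng.chisquare(d0, size=n_genes)
    sigma = np.sqrt(sigma_sq)

    gene_index = {g: i for i, g in enumerate(genes)}
    anchor_i = gene_index["FOXM1"]
    ifn_i = np.array([gene_index[g] for g in groupsmap["ifn"]], dtype=int)
    cc_i = np.array([gene_index[g] for g in groupsmap["cc"]], dtype=int)
    mod_i = np.array([gene_index[g] for g in groupsmap["module"]], dtype=int)
    factor_driven = np.zeros(n_genes, dtype=bool)
    factor_driven[anchor_i] = True
    factor_driven[mod_i] = True

    values = np.tile(baseline[:, None], (1, n_samples))

    # Per-gene subset offsets (biological subset structure); the anchor and
    # module genes get their cross-subset structure from the latent factor
    # alone so the configured loading stays exact.
    if config.subset_offset_sd > 0:
        offsets = rng.normal(0.0, config.subset_offset_sd, size=(n_genes, n_sub))
        offsets[factor_driven, :] = 0.0
        for j, subset in enumerate(config.subsets):
            values[:, sample_subset == subset] += offsets[:, [j]]

    # Optional donor random effect (within-donor correlation across subsets).
    if config.donor_sd > 0:
        donors = sorted(set(sample_donor))
        donor_eff = rng.normal(0.0, config.donor_sd, size=(n_genes, len(donors)))
        for j, donor in enumerate(donors):
            values[:, sample_donor == donor] += donor_eff[:, [j]]

    is_sle = sample_group == "SLE"
    is_pb = sample_subset == "plasmablast"

    # Planted group effects.
    if len(ifn_i):
        values[np.ix_(ifn_i, np.where(is_sle)[0])] += config.ifn_log2fc
    if len(cc_i):
        values[np.ix_(cc_i, np.where(is_sle & is_pb)[0])] += config.cc_log2fc

    # Latent factor: shifted in SLE plasmablasts, noisy everywhere.
    delta = config.foxm1_anchor_log2fc
    tau = config.factor_within_sd
    factor = delta * (is_sle & is_pb).astype(float) + rng.normal(0.0, tau, size=n_samples)
    p_on = (is_sle & is_pb).mean()
    var_f = p_on * (1 - p_on) * delta**2 + tau**2
    sd_f = math.sqrt(var_f) if var_f > 0 else 1.0

    values[anchor_i, :] = baseline[anchor_i] + factor
    rho = config.foxm1_module_loading
    if len(mod_i):
        if rho >= 1.0:
            b = sigma[mod_i] / sd_f
            values[mod_i, :] = baseline[mod_i, None] + b[:, None] * factor[None, :]
        else:
            b = (rho / math.sqrt(1 - rho**2)) * sigma[mod_i] / sd_f
            values[mod_i, :] = baseline[mod_i, None] + b[:, None] * factor[None, :]

    # Residual noise for every gene except the anchor (exact factor readout)
    # and, at loading 1, the module genes.
    noise = rng.normal(0.0, 1.0, size=(n_genes, n_samples)) * sigma[:, None]
    noise[anchor_i, :] = 0.0
    if rho >= 1.0:
        noise[mod_i, :] = 0.0
    values += noise

    matrix = ExpressionMatrix(pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                                           columns=[r[0] for r in rows]))

    eff_rows: list[tuple[str, str, float]] = []
    if config.ifn_log2fc != 0:
        for g in groupsmap["ifn"]:
            for subset in config.subsets:
                eff_rows.append((g, subset, config.ifn_log2fc))
    if config.cc_log2fc != 0 and "plasmablast" in config.subsets:
        for g in groupsmap["cc"]:
            eff_rows.append((g, "plasmablast", config.cc_log2fc))
    if delta != 0 and "plasmablast" in config.subsets:
        eff_rows.append(("FOXM1", "plasmablast", delta))
        if len(mod_i):
            if rho >= 1.0:
                b_eff = sigma[mod_i] / sd_f
            else:
                b_eff = (rho / math.sqrt(1 - rho**2)) * sigma[mod_i] / sd_f
            for g, bg in zip(groupsmap["module"], b_eff):
                eff_rows.append((g, "plasmablast", float(bg * delta)))
    truth = GroundTruth(
        ifn_genes=groupsmap["ifn"],
        cc_genes=groupsmap["cc"],
        foxm1_anchor="FOXM1",
        foxm1_module_genes=groupsmap["module"],
        effects=pd.DataFrame(eff_rows, columns=["gene_id", "subset", "effect_log2"]),
    )
    return matrix, sheet, truth


@dataclass(frozen=True)
class ApoptosisParams:
    """Class fractions and channel distributions for (live, early, late)."""

    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    annexin_mean: tuple[float, float, float] = (200.0, 1500.0, 1500.0)
    annexin_sd: tuple[float, float, float] = (60.0, 150.0, 150.0)
    viability_mean: tuple[float, float, float] = (150.0, 150.0, 1500.0)
    viability_sd: tuple[float, float, float] = (50.0, 50.0, 150.0)


@dataclass(frozen=True)
class DivisionSimConfig:
    """Parameters of the dye-dilution proliferation generator.

    progression_probs[i] is the probability that a founder which has
    completed i divisions divides again; the chain stops at the first
    failure or at max_generation. dye_cv is the lognormal coefficient of
    variation of each generation's dye peak.
    """

    n_founders: int = 2000
    max_generation: int = 5
    progression_probs: tuple[float, ...] = (0.9, 0.8, 0.7, 0.5, 0.3)
    dye_gen0_mean: float = 10000.0
    dye_cv: float = 0.15
    apoptosis: ApoptosisParams = field(default_factory=ApoptosisParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_founders < 1:
            raise ConfigError("n_founders must be >= 1")
        if self.max_generation < 0:
            raise ConfigError("max_generation must be >= 0")
        if len(self.progression_probs) != self.max_generation:
            raise ConfigError(
                f"progression_probs needs {self.max_generation} entries, "
                f"got {len(self.progression_probs)}"
            )
        if any(not (0 <= p <= 1) for p in self.progression_probs):
            raise ConfigError("progression probabilities must lie in [0, 1]")
        if self.dye_gen0_mean <= 0:
            raise ConfigError("dye_gen0_mean must be > 0")
        if self.dye_cv < 0:
            raise ConfigError("dye_cv must be >= 0")
        if abs(sum(self.apoptosis.fractions) - 1.0) > 1e-9:
            raise ConfigError("apoptosis class fractions must sum to 1")


def simulate_division_experiment(
    config: DivisionSimConfig,
) -> tuple[FlowEventTable, int]:
    """Simulate one dye-dilution culture; returns (events, founder count).

    A founder whose chain stops at generation g contributes 2**g events,
    all with true_generation = g, so the branching identity
    founders = sum_i count_i / 2**i holds exactly on true generations.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_founders
    gen = np.zeros(n, dtype=int)
    active = np.ones(n, dtype=bool)
    for i, p in enumerate(config.progression_probs):
        advance = active & (rng.random(n) < p)
        gen[advance] += 1
        active = advance

    event_gen = np.repeat(gen, 2 ** gen)
    n_events = event_gen.size
    sigma_log = math.sqrt(math.log(1.0 + config.dye_cv**2))
    mu_log = np.log(config.dye_gen0_mean) - event_gen * math.log(2.0)
    if sigma_log > 0:
        dye = rng.lognormal(mean=mu_log, sigma=sigma_log)
    else:
        dye = np.exp(mu_log)

    ap = config.apoptosis
    cls = rng.choice(3, size=n_events, p=np.asarray(ap.fractions, dtype=float))
    annexin = rng.normal(np.take(ap.annexin_mean, cls), np.take(ap.annexin_sd, cls))
    viability = rng.normal(np.take(ap.viability_mean, cls), np.take(ap.viability_sd, cls))

    table = pd.DataFrame(
        {
            "cell_id": np.arange(n_events),
            "dye_intensity": dye,
            "annexin": annexin,
            "viability": viability,
            "true_generation": event_gen,
        }
    )
    return FlowEventTable(table), n


def config_from_dict(payload: dict, kind: str):
    """Build a simulation config from a YAML-style dict (field names 1:1)."""
    payload = dict(payload or {})
    try:
        if kind == "expression":
            for key in ("subsets", "baseline_mean_range"):
                if key in payload:
                    payload[key] = tuple(payload[key])
            return SimulationConfig(**payload)
        if kind == "division":
            if "progression_probs" in payload:
                payload["progression_probs"] = tuple(payload["progression_probs"])
            if "apoptosis" in payload:
                ap = {k: tuple(v) if isinstance(v, (list, tuple)) else v
                      for k, v in payload["apoptosis"].items()}
                payload["apoptosis"] = ApoptosisParams(**ap)
            return DivisionSimConfig(**payload)
    except TypeError as exc:
        raise ConfigError(f"invalid {kind} simulation config: {exc}") from None
    raise ConfigError(f"unknown simulation kind {kind!r}")


def config_to_dict(config) -> dict:
    return asdict(config)
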