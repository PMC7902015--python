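"""Recovery and calibration benchmarks run against planted ground truth.

Each function regenerates synthetic data from scratch, runs the relevant
analysis path, and measures agreement with the generative truth or with an
independent oracle (classical t-test, exhaustive hypergeometric
enumeration, per-founder bookkeeping). They back both the test suite and
the reproduction script.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import find_similar_entities
from .datamodel import ExpressionMatrix, GeneSet, SampleSheet
from .degs import VariancePrior, fit_variance_prior, moderated_t_test, ora_fisher
from .proliferation import (
    distribution_from_counts,
    generation_labels,
    proliferation_index,
)
from .signatures import compare_scores, signature_score
from .synthetic import (
    DivisionSimConfig,
    SimulationConfig,
    simulate_division_experiment,
    simulate_expression_study,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible sub-seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _null_config(n_genes: int, seed: int, **overrides) -> SimulationConfig:
    return SimulationConfig(
        n_genes=n_genes,
        ifn_log2fc=0.0,
        cc_log2fc=0.0,
        foxm1_anchor_log2fc=0.0,
        seed=seed,
        **overrides,
    )


def classical_t_agreement(n_instances: int = 100, seed: int = 0) -> dict:
    """Max |difference| between the moderated t at d0 = 0 and the classical
    pooled two-sample t-test (scipy oracle) on random 4v4 instances."""
    rng = np.random.default_rng(seed)
    max_t = 0.0
    max_p = 0.0
    for _ in range(n_instances):
        n_genes = int(rng.integers(5, 30))
        xa = rng.normal(rng.normal(8, 1), rng.uniform(0.2, 1.5), size=(n_genes, 4))
        xb = rng.normal(rng.normal(8, 1), rng.uniform(0.2, 1.5), size=(n_genes, 4))
        genes = [f"g{i}" for i in range(n_genes)]
        cols = [f"HC{i}_naive" for i in range(1, 5)] + [f"SLE{i}_naive" for i in range(1, 5)]
        matrix = ExpressionMatrix(
            pd.DataFrame(np.hstack([xa, xb]), index=genes, columns=cols)
        )
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": cols,
                    "donor_id": [c.split("_")[0] for c in cols],
                    "group": ["HC"] * 4 + ["SLE"] * 4,
                    "subset": ["naive"] * 8,
                }
            )
        )
        res = moderated_t_test(
            matrix, sheet, "naive", prior=VariancePrior(d0=0.0, s0_sq=1.0)
        )
        t_ref, p_ref = stats.ttest_ind(xb, xa, axis=1, equal_var=True)
        max_t = max(max_t, float(np.max(np.abs(res["t_mod"].to_numpy() - t_ref))))
        max_p = max(max_p, float(np.max(np.abs(res["p"].to_numpy() - p_ref))))
    return {"max_abs_t_diff": max_t, "max_abs_p_diff": max_p, "n": n_instances}


def type_i_error_rate(n_seeds: int = 20, n_genes: int = 5000, seed: int = 0) -> dict:
    """Empirical p < 0.05 rate of the moderated t-test on null simulations
    (all planted effects zero), pooled over seeds."""
    hits = 0
    total = 0
    for s in _child_seeds(seed, n_seeds):
        matrix, sheet, _ = simulate_expression_study(_null_config(n_genes, s))
        res = moderated_t_test(matrix, sheet, "naive", prior="fit")
        hits += int((res["p"].to_numpy() < 0.05).sum())
        total += n_genes
    se = math.sqrt(0.05 * 0.95 / total)
    return {"rate": hits / total, "mc_se": se, "n": total}


def prior_recovery(
    n_reps: int = 100,
    n_genes: int = 5000,
    d0: float = 4.0,
    s0_sq: float = 0.05,
    df_resid: int = 6,
    rel_tol: float = 0.15,
    seed: int = 0,
) -> dict:
    """Fraction of replicates in which moment matching recovers both prior
    parameters within rel_tol, with variances simulated from the prior."""
    ok = 0
    for s in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        sigma_sq = s0_sq * d0 / rng.chisquare(d0, size=n_genes)
        s_sq = sigma_sq * rng.chisquare(df_resid, size=n_genes) / df_resid
        prior = fit_variance_prior(s_sq, df_resid)
        if (
            math.isfinite(prior.d0)
            and abs(prior.d0 - d0) / d0 <= rel_tol
            and abs(prior.s0_sq - s0_sq) / s0_sq <= rel_tol
        ):
            ok += 1
    return {"fraction_within_tol": ok / n_reps, "n": n_reps}


def pattern_recovery_rate(n_reps: int = 100, seed: int = 0, alpha: float = 0.05) -> dict:
    """Rate of replicates reproducing the study's signature-score pattern:
    IFN score elevated in SLE for all three subsets AND cell-cycle score
    elevated only in plasmablasts (Tukey-adjusted within-subset contrasts
    at the given alpha), under the generator's default conditions."""
    ok = 0
    for s in _child_seeds(seed, n_reps):
        matrix, sheet, truth = simulate_expression_study(SimulationConfig(seed=s))
        ifn_set, cc_set = truth.gene_sets()
        hit = True
        for gs, active_subsets in ((ifn_set, {"naive", "memory", "plasmablast"}),
                                   (cc_set, {"plasmablast"})):
            table = signature_score(matrix, gs)
            contrasts = compare_scores(table, sheet)["subset_contrasts"]
            for _, row in contrasts.iterrows():
                sig = row["tukey_p"] < alpha and row["mean_SLE"] > row["mean_HC"]
                if sig != (row["subset"] in active_subsets):
                    hit = False
        ok += hit
    return {"rate": ok / n_reps, "n": n_reps}


def similar_entities_benchmark(
    n_seeds: int = 50,
    module_size: int = 100,
    n_decoys: int = 200,
    loading: float = 0.8,
    seed: int = 0,
) -> dict:
    """Planted-module recovery of the similar-entities screen.

    Module genes at the given loading plus uncorrelated decoy genes
    (no subset structure, no other planted sets); candidates are the
    module plus the decoys, selection at the default [0.6, 1.0] band.
    """
    sens = []
    decoy_hits = 0
    for s in _child_seeds(seed, n_seeds):
        config = SimulationConfig(
            n_genes=module_size + n_decoys + 1,
            ifn_set_size=0,
            cc_set_size=0,
            foxm1_module_size=module_size,
            foxm1_module_loading=loading,
            subset_offset_sd=0.0,
            seed=s,
        )
        matrix, sheet, truth = simulate_expression_study(config)
        decoys = [g for g in matrix.gene_ids
                  if g not in set(truth.foxm1_module_genes) and g != truth.foxm1_anchor]
        candidates = truth.foxm1_module_genes + decoys
        result = find_similar_entities(matrix, truth.foxm1_anchor, candidates)
        selected = set(result.selected)
        sens.append(len(selected & set(truth.foxm1_module_genes)) / module_size)
        decoy_hits += len(selected & set(decoys))
    return {
        "median_sensitivity": float(np.median(sens)),
        "decoy_selection_rate": decoy_hits / (n_seeds * n_decoys),
        "n": n_seeds,
    }


def pi_bookkeeping_check(n_configs: int = 20, seed: int = 0) -> dict:
    """Max |PI - total_events/founders| on random simulated cohorts, with
    PI computed from true generations and founders from the generator."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for s in _child_seeds(seed, n_configs):
        g = int(rng.integers(1, 7))
        config = DivisionSimConfig(
            n_founders=int(rng.integers(50, 500)),
            max_generation=g,
            progression_probs=tuple(rng.uniform(0.1, 0.95, size=g)),
            dye_cv=float(rng.uniform(0.0, 0.3)),
            seed=s,
        )
        events, founders = simulate_division_experiment(config)
        counts = np.bincount(
            events.table["true_generation"].to_numpy(), minlength=g + 1
        )
        res = proliferation_index(distribution_from_counts(counts))
        max_err = max(max_err, abs(res.pi - len(events) / founders))
        # per-founder bookkeeping: founders == sum_i count_i / 2**i exactly
        max_err = max(
            max_err, abs(float((counts / 2.0 ** np.arange(g + 1)).sum()) - founders)
        )
    return {"max_abs_error": max_err, "n": n_configs}


def generation_assignment_accuracy(
    n_seeds: int = 20, dye_cv: float = 0.05, seed: int = 0
) -> dict:
    """Mean agreement of dye-based generation assignment with the planted
    true generation."""
    correct = 0
    total = 0
    for s in _child_seeds(seed, n_seeds):
        config = DivisionSimConfig(dye_cv=dye_cv, seed=s)
        events, _ = simulate_division_experiment(config)
        assigned = generation_labels(events, config.dye_gen0_mean, config.max_generation)
        correct += int((assigned == events.table["true_generation"].to_numpy()).sum())
        total += len(events)
    return {"accuracy": correct / total, "n": total}


def exhaustive_hypergeometric_p(n_bg: int, k_set: int, n_deg: int, overlap: int) -> float:
    """One-sided enrichment p by exhaustive enumeration over the
    hypergeometric support (independent oracle for small universes)."""
    total = math.comb(n_bg, n_deg)
    favorable = 0
    for k in range(overlap, min(k_set, n_deg) + 1):
        favorable += math.comb(k_set, k) * math.comb(n_bg - k_set, n_deg - k)
    return favorable / total


def ora_enumeration_check(n_cases: int = 200, seed: int = 0) -> dict:
    """Max |p difference| between ora_fisher and exhaustive hypergeometric
    enumeration on random universes of size <= 20."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_cases):
        n_bg = int(rng.integers(5, 21))
        bg = [f"g{i}" for i in range(n_bg)]
        k_set = int(rng.integers(1, n_bg + 1))
        n_deg = int(rng.integers(0, n_bg + 1))
        members = list(rng.choice(bg, size=k_set, replace=False))
        deg = list(rng.choice(bg, size=n_deg, replace=False))
        table = ora_fisher(deg, bg, [GeneSet("S", "d", tuple(members))])
        overlap = len(set(deg) & set(members))
        p_ref = exhaustive_hypergeometric_p(n_bg, k_set, n_deg, overlap)
        max_diff = max(max_diff, abs(float(table["p"].iloc[0]) - p_ref))
    return {"max_abs_p_diff": max_diff, "n": n_cases}
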