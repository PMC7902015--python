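# bsig

Analysis toolkit for B-cell subset expression and proliferation studies in
systemic lupus erythematosus (SLE), built around the comparison of three
sorted B-cell subsets — naive, memory, and plasmablasts (CD38+CD43+ B
cells) — between healthy controls (HC) and SLE patients.

It is aimed at researchers who want the complete computational path of such
a study as tested, reusable code: differential expression with an
empirical-Bayes moderated t-test, gene-set signature scoring, an anchor-gene
coexpression screen, over-representation testing, and flow-cytometry
proliferation/apoptosis metrics — plus a synthetic-data generator with
planted ground truth so every stage can be validated without any microarray
or FCS download.

## Methods at a glance

**Moderated t-test.** For gene *g* with pooled two-sample variance
*s²_g* on *d_g* residual degrees of freedom, a scaled-inverse-χ² prior
(*d₀*, *s₀²*) is fitted across genes by matching the mean and variance of
log *s²_g* to their digamma/trigamma expressions (trigamma inverted by
monotone Newton iteration). The posterior variance

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)

replaces *s²_g* in the t statistic, referred to Student-t with *d_g + d₀*
degrees of freedom. DEGs are genes with p < 0.05 and signed linear fold
change beyond ±2 (down-regulation with ratio r < 1 is reported as −1/r).

**Signature score.** On the linear intensity scale, each set gene's row is
divided by its maximum across samples (maximum → 1) and each sample's score
is the sum of its normalized values; group differences are tested by
one-way ANOVA with Tukey's HSD across the six subset × group cells.

**Similar entities.** Pearson correlation of each candidate gene's
cross-sample profile to an anchor gene (FOXM1), selecting candidates with
0.6 ≤ r ≤ 1.0.

**Proliferation index.** From dye-dilution generation percentages *N_i*
(generation *i* cells carry 1/2^i of the founders' dye),

    PI = Σ N_i / Σ (N_i / 2^i)

i.e. total cells over inferred founders. Apoptosis gating: annexin-negative
= live, annexin+/viability-dye− = early apoptotic, double-positive = late
apoptotic.

## Worked example

```python
import bsig
from bsig.proliferation import distribution_from_counts

config = bsig.SimulationConfig(n_genes=1000, cc_set_size=100,
                               foxm1_module_size=50, seed=42)
matrix, sheet, truth = bsig.simulate_expression_study(config)

stats = bsig.moderated_t_test(matrix, sheet, "plasmablast", prior="fit")
result = bsig.call_degs(stats, p_thresh=0.05, fc_thresh=2.0)
print(f"plasmablast DEGs: {len(result.up_genes)} up, {len(result.down_genes)} down")
print(f"FOXM1 signed fold change: {stats.loc['FOXM1', 'fc_signed']:.3f} "
      f"(p = {stats.loc['FOXM1', 'p']:.2e})")

ifn_set, cc_set = truth.gene_sets()
table = bsig.signature_score(matrix, ifn_set)
contrasts = bsig.compare_scores(table, sheet)["subset_contrasts"]
print(contrasts[["subset", "mean_HC", "mean_SLE", "tukey_p"]].to_string(index=False))

sim = bsig.find_similar_entities(matrix, "FOXM1", result.deg_genes)
hits = len(set(sim.selected) & set(truth.foxm1_module_genes))
print(f"similar entities: {len(sim.selected)} selected; "
      f"{hits}/{len(truth.foxm1_module_genes)} planted module genes recovered")

events, founders = bsig.simulate_division_experiment(bsig.DivisionSimConfig(seed=42))
dist = bsig.assign_generations(events, 10000.0, 5)
print(f"proliferation index: {bsig.proliferation_index(dist).pi:.3f} "
      f"from {len(events)} events ({founders} founders)")
```

prints

```
plasmablast DEGs: 102 up, 7 down
FOXM1 signed fold change: 3.664 (p = 4.91e-04)
     subset  mean_HC  mean_SLE  tukey_p
      naive 5.655518 10.648471      0.0
     memory 4.651698  8.996531      0.0
plasmablast 5.351731 10.315921      0.0
similar entities: 53 selected; 39/50 planted module genes recovered
proliferation index: 8.709 from 17533 events (2000 founders)
```

The simulator planted a 1 log2 interferon-signature shift in all SLE
subsets, a cell-cycle shift only in SLE plasmablasts, and a FOXM1-driven
coexpression module: the DEG caller flags the plasmablast signal (FOXM1's
fold change of 3.66 means ~3.7× higher in SLE), the IFN score separates
SLE from HC in every subset (Tukey-adjusted p rounds to 0), and the
correlation screen recovers most of the planted module from the DEG list.
The proliferation index of 8.7 says each founder produced on average ~8.7
descendants, consistent with the simulated division chain.

The same stages are scriptable: `bsig simulate expr`, `bsig deg`,
`bsig ora`, `bsig score`, `bsig compare`, `bsig similar`,
`bsig proliferation`, `bsig apoptosis`, or end-to-end with a manifest via
`bsig run --config run.yaml`.

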