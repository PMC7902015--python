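# Methods

## Study design and scope

The package models a cross-sectional B-cell subset study: three sorted
subsets (naive, memory, plasmablast — the latter operationalized as
CD38+CD43+ B cells) from two groups (HC, SLE), with four donors per group
by default, profiled as log2 expression intensities; and, separately,
dye-dilution proliferation cultures read out by flow cytometry. All
statistics operate on these two shapes of data. Raw-array preprocessing
(probe summarization, background correction, batch correction) and FCS
parsing are out of scope: the expression input is assumed already on the
log2 scale, and flow events arrive as plain per-cell channel tables.

## Differential expression

**Normalization.** Per-array percentile shift: each sample's 75th
percentile of log2 values (linear interpolation between order statistics)
is subtracted, the standard location normalization for one-color arrays.
It is shift-equivariant and leaves within-sample contrasts untouched.

**Moderated t-test.** The test is the empirical-Bayes moderated t: the
per-gene pooled variance s²_g (df d_g = n_a + n_b − 2) is shrunk toward a
prior scale through the posterior mean

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g),

and t_g = (mean_b − mean_a) / (s̃_g·√(1/n_a + 1/n_b)) is referred to
Student-t with d_g + d0 df. Under a scaled-inverse-χ²(d0, s0²) prior the
sample variances are marginally s0²·F(d_g, d0), so the prior is estimated
by moment matching on z_g = log s²_g:

* E[z] and Var[z] involve digamma/trigamma terms of d_g/2 and d0/2;
* the excess of the empirical Var(z) (ddof = 1) over the mean
  trigamma(d_g/2) is inverted through the trigamma function
  (monotone Newton iteration from the asymptotic start 0.5 + 1/y,
  relative tolerance 1e−8) to give d0;
* a non-positive excess means underdispersion relative to any finite d0:
  d0 = ∞ is returned with s0² the geometric mean of the variances, so
  identical input variances come back unchanged. (This degenerate branch
  intentionally skips the χ²-sampling bias correction: with no observed
  dispersion there is no sampling noise to correct.)
* fitting requires at least 10 genes with positive variance and df ≥ 1;
  fewer genes is an error advising an ordinary t-test.

d0 = 0 is admitted as the explicit no-shrinkage limit and reduces the test
exactly to the classical pooled two-sample t-test; d0 = ∞ uses the Normal
reference distribution. The finite-d0 path reproduces Bioconductor limma's
`lmFit`/`eBayes` t- and p-values to ~1e−14 on shared input (checked in the
test suite as an independent cross-validation; limma is never called by
the package itself). A pooled (not Welch) variance is used because the
shrinkage construction is defined on a single pooled variance.

**DEG rule.** Up: p < 0.05 and signed fold change ≥ 2; down: p < 0.05 and
signed fold change ≤ −2. Fold changes use the signed linear convention
fc = r if r = 2^(Δlog2) ≥ 1, else −1/r, so |fc| ≥ 1 always and
down-regulation is a negative magnitude. No multiple-testing correction is
applied by default (an optional Benjamini-Hochberg flag exists but is
off), matching the threshold-on-raw-p convention of the GeneSpring-style
analysis this package re-implements.

**Over-representation.** One-sided (enrichment) Fisher's exact test of
each gene set against the DEG list within a declared background universe,
significance flagged at p < 0.01. Set members outside the background are
dropped; sets left empty are skipped with a warning. The activation
z-scores produced by commercial pathway tools have no published formula
and are not implemented.

## Signature scoring

The score is a normalized sum: restrict the matrix to the set's genes that
are present (missing members are reported, never imputed), map log2 values
to linear intensities (2^x), divide each gene row by its maximum across
samples, and sum per sample. Two conventions are deliberate defaults, both
exposed as flags:

* **linear scale** — a ratio-to-max on log2 values would be sensitive to
  the log offset and can be negative; the recipe presupposes nonnegative
  magnitudes;
* **row maximum across all samples jointly** — all six subset × group
  cells then share one comparable score axis; a per-subset span is
  available.

Score invariants asserted at run time: 0 ≤ score ≤ number of usable genes,
and each usable gene's normalized maximum is exactly 1.

Group comparison follows the source study's test: one-way ANOVA over the
six cells followed by Tukey's HSD; the per-subset HC-vs-SLE contrast is
read from the Tukey-adjusted pair, with an unadjusted pooled t-test also
reported. The benchmark "pattern recovery" criterion (IFN score elevated
in all subsets, cell-cycle score only in plasmablasts) is evaluated on the
Tukey-adjusted contrasts: the family-wise adjustment is the study's own
test and keeps the joint false-positive rate of the two must-be-null cells
controlled, which a battery of six unadjusted 4v4 t-tests would not.

A single-gene display convention is also provided: values divided by their
minimum across samples (minimum → 1).

## Coexpression screen

Pearson correlation (Spearman by flag) of each candidate's profile against
the anchor gene across all samples jointly, with closed-interval selection
r_min ≤ r ≤ r_max (defaults 0.6 and 1.0). Zero-variance profiles have
undefined correlation and are excluded with a warning rather than given a
value. Correlating across all 24 samples (rather than within a subset) is
what lets a module expressed only in SLE plasmablasts stand out: the
shared on/off pattern dominates the correlation.

## Proliferation and apoptosis

**Generation assignment.** Generation-i events peak at gen0_mean/2^i;
assignment is nearest-center on the log scale, with boundaries at the
geometric means of adjacent centers. Events dimmer than the last boundary
go to the terminal generation, brighter than the first to generation 0.
Fixed geometric boundaries were chosen over mixture-model fitting: they
are deterministic, exactly testable, and at realistic peak widths (CV
≤ 0.2, peaks ln 2 apart in log space) essentially lossless.

**Proliferation index.** PI = Σ N_i / Σ(N_i/2^i) over generations
0..i_max, with N_i the generation percentages (counts give the identical
PI; a test asserts this). The sum includes the undivided peak; an
`exclude_gen0` flag exposes the alternative convention without asserting
it. PI ∈ [1, 2^i_max], with PI = 1 iff nothing divided.

**Apoptosis gating.** Events partition into live (annexin ≤ t_a), early
apoptotic (annexin > t_a, viability ≤ t_v) and late apoptotic (both
above); fractions sum to 1 by construction.

## Synthetic data generator

**Expression.** Each observation is

    x_gs = baseline_g + subset_offset_{g,subset(s)} + donor_effect
           + planted_effect_{g,s} + N(0, sigma_g)

with baseline_g ~ U(6, 12) log2 units, per-gene subset offsets
N(0, 1) (biological subset structure), an optional donor random effect
(default SD 0 — real donor-to-donor variance structure is unknown, so it
is exposed rather than asserted), and per-gene variances
sigma_g² ~ s0²·d0/χ²_d0 with defaults s0 = 0.5 log2 units and d0 = 4, so
the moderated-t prior is well specified and recoverable by construction.

Planted structure, encoding the biological pattern the analysis should
find: a 23-gene IFN signature shifted +1 log2 in SLE samples of every
subset; a 231-gene cell-cycle signature shifted +1 log2 in SLE
plasmablasts only; and a 100-gene FOXM1 module driven by a latent factor
f_s = Δ·1[SLE plasmablast] + N(0, 0.5), Δ = 2 log2 units by default (a
4-fold anchor shift, the magnitude scale of the motivating study's top
upstream regulators). The anchor gene reads out the factor without
residual noise, and each module gene loads on it with coefficient chosen
so its population correlation with the anchor equals the configured
loading (default 0.8); anchor and module genes skip the independent subset
offsets so that correlation is exact. Sample counts follow the 3 × 2 × 4
design (24 arrays).

What the generator does **not** emulate: probe-level intensities and array
artifacts, heavy-tailed or correlated residual noise beyond the planted
module, subset-dependent variance, and any donor pairing between groups.
Passing recovery tests therefore demonstrates correctness of the
algorithms under a well-specified generative model, not robustness to
real-array pathologies.

**Division.** Founders traverse a per-generation Bernoulli chain
(probability p_i of dividing again after i divisions, stopping at the
first failure or at max_generation); a founder ending at generation g
contributes 2^g events, so founders = Σ count_g/2^g holds exactly on true
generations. Dye intensities are lognormal with median gen0_mean/2^g and
configurable CV (default 0.15); apoptosis channels are Gaussian per class
with class fractions (0.70, 0.20, 0.10) and means separated from the gate
thresholds by > 4 SDs at the defaults. Defaults (2000 founders, 5
generations, progression probabilities 0.9/0.8/0.7/0.5/0.3) describe a
well-stimulated culture with PI ≈ 8.6 expected; a timed branching process
is not modeled because only the terminal generation distribution enters
the PI.

Both generators are bit-for-bit reproducible from (config, seed).

## Benchmark problem sizes

The reproduction script and the recovery tests use: 100 random 4v4
instances for the classical-t reduction; 20 seeds × 5000 genes for null
calibration; 100 replicates of 5000 genes (d0 = 4, s0² = 0.05, df 6) for
prior recovery; 100 replicates of the default 5000 × 24 study for score
pattern recovery; 50 seeds of a 301-gene study (100-gene module, 200
decoys, loading 0.8) for the similar-entities screen; 20 random cohorts
for the PI identity and 20 seeds at dye CV 0.05 for assignment accuracy;
and 200 random universes of size ≤ 20 for the ORA-vs-enumeration check.
Unit tests use 400-gene studies for speed; the statistics are size-free.

## Known limitations

* The DEG caller tests normalized log2 values directly; no per-gene
  baseline transformation is applied before testing.
* The Fisher-ORA background must be supplied explicitly; there is no
  annotation-aware universe construction.
* Generation assignment assumes a known, accurate gen0 intensity; it does
  not refit the undivided peak from the data.
* The latent-factor module model gives exact control of loadings at the
  cost of a noiseless anchor readout — realistic anchors would carry
  measurement noise and slightly attenuate the gene-anchor correlations.
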