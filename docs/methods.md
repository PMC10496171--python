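# Methods

This note documents the models and procedures ebcomp implements, the
defaults and why, what the synthetic generator does and does not emulate,
the numerical choices, and known limitations.

## Synthetic study generator

The generator emulates a two-species (human, chimpanzee) single-cell
differentiation experiment with 3 individuals per species x 3 shared
replicate batches x C cell types, plus tetraploid hybrid cells, a TF ->
target promoter-motif network, and an alignment-hit fixture for the
ortho-exon filters. Every generator is a pure function of (config, seed);
per-stage seeds derive from named substreams of the master seed.

**Truth model.** Gene g draws a motif z_g ~ Categorical(π); DE indicators
δ_gc ~ Bernoulli(q[z_g, c]); effects β_gc ~ Normal(0, τ²) where δ = 1 and 0
otherwise (β is the chimp-vs-human log2 fold change); cis fractions
ρ_g ~ Beta(a, b); baselines λ_g log10-uniform over the configured range.

**Diploid counts.** Per cell of species s (coded −1/2 human, +1/2 chimp),
individual i, replicate r, cell type c:
count ~ NB(mean = λ_g · 2^(s·β_gc + u_gi + v_gr), dispersion φ) with
variance μ + φμ², u_gi ~ N(0, σ_ind²) per gene x individual and
v_gr ~ N(0, σ_rep²) per gene x replicate (replicate batches are shared
across species). QC metadata (genome read counts, mitochondrial fraction,
genes detected) is drawn to pass the default filters; QC failures are
injected only when `inject_qc_failures` is set, with truth flags.

**Hybrid counts.** Totals ~ NB(λ_g · 2^(v_gr), φ); the human-allele count
is Binomial(total, p_gc) with p_gc = 1 / (1 + 2^(ρ_g β_gc)), chosen so the
expected allelic log2 ratio (chimp/human) is exactly ρ_g·β_gc — the
quantity the cis-proportion estimator assumes. Both alleles share every
cell-level effect, which is the defining property of the hybrid design.

**TF network.** Driver TFs receive a DE pattern across all cell types;
each driver's targets get β = α·(TF pattern) + Normal(0, σ_noise²), carry
the TF's promoter motif, and get small cis fractions (Beta(1, 9): the
divergence is trans-driven). Non-driver TFs get motifs whose targets keep
their independent base-truth effects. TF and driver-target baselines are
floored at 0.5 UMI/cell — a driver must be expressed to be discoverable.

**Defaults and rationale.**

| parameter | default | rationale |
|---|---|---|
| effect_sd (τ) | 1.75 log2 units | gives mean \|β\| ≈ 1.4 among DE genes, the typical magnitude in this system |
| nb_dispersion (φ) | 0.2 | common single-cell UMI overdispersion scale |
| indiv_sd, rep_sd | 0.15, 0.10 log2 | individual/replicate variance small relative to species divergence, consistent with variance-partition observations in such data |
| cis_alpha, cis_beta | 1.5, 3.5 | mean cis fraction 0.3 — divergence is mostly trans on average |
| baseline range | 10^−3 … 10^1.5 UMI/cell | spans filtered-out to highly expressed |

**What the generator does not emulate**: splicing, ambient RNA, doublets,
cell-cycle structure, realistic embeddings (label transfer uses
well-separated Gaussian blobs), or genotype-based demultiplexing. Passing
tests therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to every artifact of real droplet data.

## Orthologous exons

Filters run in a fixed order and each dropped exon records its first
failing reason: identity -> multimap resolution -> indel -> reciprocity.
Choices the underlying procedure leaves open: identity uses the full query
exon length as denominator (unaligned ends count against identity);
"original location" means same-chromosome interval overlap of >= 1 base;
the 100 kb neighbor window is measured between exon start coordinates,
counting only exons of the same gene, with mixed-strand neighbor support
counting as non-support; ties break by higher identity, then
lexicographically smallest locus, making the cascade order-invariant.
Coordinates are 0-based half-open internally; GTF output is 1-based
inclusive.

## Preprocessing

Species assignment requires strictly > 90% of uniquely mapping reads on
one genome. QC keeps droplets with >= 1000 genes detected (2000 for hybrid
libraries) and mitochondrial fraction within [0.1%, 20%] (strict
more-than/fewer-than, so the boundary values pass). Label transfer is
nearest centroid by Euclidean distance, ties to the lexicographically
smallest label. Pseudobulk sums cells by individual x replicate x cell
type and drops samples with <= 5 cells; the cell-type filter requires
>= 5 cells in >= 2 replicates in each species, evaluated on pre-drop
group sizes pooled across individuals. The expression filter keeps genes
with CPM >= min_count/median(lib)·10^6 in at least as many samples as the
smaller species group, and total count >= 15. Mitochondrial fractions are
computed over UMIs.

## Normalization

TMM with singleton pairing: the reference sample has the upper quartile
(of positive counts over library size) closest to the mean; M/A values
over genes positive in both samples are double-trimmed (30% of M tails,
5% of A tails) and combined by asymptotic precision weights; when fewer
than 50 shared positive genes exist, genes positive in exactly one sample
are paired by decreasing magnitude and contribute pseudo-M values. Factors
are rescaled to geometric mean 1. Cyclic loess runs Jacobi-style: per
cycle every pairwise loess fit of M on A (span 0.7) is computed from the
cycle's starting matrix and the averaged corrections applied together —
this makes the result exactly equivariant under sample reordering (a
sequential pair-by-pair sweep is not), with 3 cycles by default.

## Differential expression

Log-CPM uses pseudocounts 0.5 (counts) and 1 (effective library). Voom
weights come from a lowess trend (span 0.5) of sqrt(residual sd) against
mean log2 count, predictions clipped to the fitted range, weight =
trend^−4.

The per-gene weighted mixed model profiles the residual variance out of
the REML criterion and optimizes the two variance ratios (individual,
replicate) on a log-scale lattice: a coarse shared grid, then per-gene
3x3 zoom refinements to ~0.03 log-unit resolution, all with batched
Cholesky factorizations (a few seconds for 2000 genes on one core). The
floor e^−18 makes a component effectively zero; in that limit the fit
reproduces weighted OLS.

**Degrees of freedom.** The species-contrast df is per-gene Satterthwaite:
delta method on se² over the variance components with the REML expected
information. Components estimated at the zero boundary are excluded from
the df charge. Genes whose *individual* variance ratio collapses to the
boundary are instead tested by the exact individual-collapsed pooled
two-sample t (weighted per-individual means, df = n_individuals − 2),
which is exactly calibrated in the balanced crossed design because
replicate effects cancel in the species contrast; the REML boundary SE
would otherwise understate the contrast variance and inflate extreme
statistics. This fallback engages only in the default model (no fixed
covariates) and is flagged in the output (`collapsed`).

**Moderation.** The variance prior (d0, s0²) is method-of-moments on log
residual variances (digamma/trigamma inversion). When the observed spread
does not exceed the chi-square expectation, shrinkage is complete and the
target is the geometric mean of the observed variances, so identical
variances stay fixed. Moderated tests use the effective df
1/df = 1/(d+d0) + 1/df_satt − 1/d: pooling improves the residual part of
the contrast variance but not the random-effect-ratio part, whose
uncertainty the Satterthwaite df carries. Collapsed-fallback genes keep
their exact inference. Measured on the null study (2000 genes): fraction
p < 0.05 of 0.043–0.053 across seeds, realized BH FDR at nominal 5% of
0.00–0.07.

Two-sided p-values and log base 2 throughout; DE calls default to FDR
< 0.05 per cell type. Moderation is on by default and exposed as a flag.

## Correlation-motif joint DE

Per-condition t-statistics come from voom-weighted fixed-effect fits with
moderation (the same filters and normalizations as the mixed fits). Null
density f0 is the central t with the condition's df; the alternative f1 is
an equal-weight scale mixture over v ∈ {1, 2, 4, 8, 16, 32} of t densities
widened by sqrt(1+v) — a configurable prior on effect magnitude. The EM
works with the density ratio e = f1/f0 (clipped in log space at ±500);
missing t values (genes filtered out in a condition) contribute a neutral
factor and are excluded from the M-step. Initialization:
q ~ Uniform(0.05, 0.95), π uniform; 10 restarts; tolerance 1e-6 on the
log-likelihood; 500 iterations; the log-likelihood is asserted
non-decreasing at every iteration and a final E-step makes the returned
posteriors consistent with the returned parameters. K is selected by BIC
with K−1+K·C parameters. Motif labels are arbitrary; recovery checks match
labels by Hungarian assignment on mean |Δq|.

Conserved genes require zero DE calls plus >= 100 UMIs in >= 10 cell types
in both species (capped at the number of tested cell types in small runs),
and no cell type where P(|β| > 0.5) >= 0.95 (from the t sampling
distribution). Restricted DE requires posterior > 0.95 somewhere and
< 0.05 in a cell type with >= 100 UMIs in each species. Cell-level motif
scores are membership-weighted residual sums, z-scored across cells, with
zero-variance motifs reported as 0 and flagged.

## Cis/trans decomposition

Hybrid log2FC is the allele-library-normalized pseudobulk ratio with
pseudocount 0.5 (shared cells cancel composition effects); its sign
convention matches the diploid fits (chimp vs human). The cis proportion
is |hybrid| / (|hybrid| + |diploid − hybrid|), undefined when both terms
are 0. Classes use the mean over cormotif-called (posterior > 0.95) DE
cell types: cis if > 0.75, trans if < 0.25. The paired Wilcoxon allele
test drops zero differences, uses the exact null below 50 informative
cells without ties and the normal approximation with continuity correction
otherwise, BH within cell type. The lowest-SE subset ranks tests by the
diploid-fit SE (ties by gene then cell type); because measurement error
inflates the trans share, the subset's cis estimates sit closer to truth —
the direction of the source observation that the trans share drops when
restricting to the best-measured tests.

## TF drivers

Trans-DE genes have mean trans proportion strictly > 0.75 over their DE
cell types. Motif enrichment is upper-tail hypergeometric with target sets
intersected with the tested-gene universe, BH across motifs at 5% FDR.
Candidate TFs must be DE in >= 1 cell type and pass the expression filter
in >= 3. Correlations use the fitted log2FC patterns across all cell types
shared by TF and target (>= 3 finite values; targets must be DE
somewhere); Fisher's combination assumes independence across targets — an
approximation under shared cell types, guarded by the null-calibration
study (<= 7% of TFs significant at FDR 5% under a global null). Pearson
p-values are two-sided.

## Validation studies and problem sizes

The studies in `ebcomp.validation` (run by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use desk-scale designs chosen to finish in a few
minutes on one core while leaving the measured properties stable:

- **Cis recovery**: 2000 genes x 5 cell types, cis strata
  {0, .25, .5, .75, 1}; every gene diverges with |β| = 1.4 (random sign) —
  the cis proportion is only meaningfully defined for diverged genes, and
  a Normal effect draw would leave ~22% of genes with |β| < 0.5 whose cis
  ratio is noise-dominated at any depth. Diploid arm 100 cells/sample;
  hybrid arm 300 cells per cell type per replicate x 3 replicates.
  Stratum means are taken over DE-called tests with >= 500 UMIs in each
  species' diploid pseudobulk and the hybrid pseudobulk. The noise-
  attenuation check compares mean per-test |error| between the 1000
  lowest-SE tests and all DE-called tests without the expression gate
  (under the gate the true SE is nearly constant — the individual-variance
  floor — and a lowest-SE subset selects only estimation noise).
- **Cormotif recovery**: G = 3000, C = 8, K = 4, q ∈ {0.01, 0.99}
  (well-separated), planted effects are real location shifts of 3–6
  null-sd analysed with the matching alternative grid v ∈ {8, 16, 32};
  drawing effects from the scale-mixture alternative itself leaves planted
  DE undetectable about half the time and caps the achievable assignment
  accuracy well below what location effects allow. The BIC scan (K = 1–6,
  10 fresh draws) runs at 3 restarts / 200 iterations / tolerance 1e-3;
  BIC gaps between K values are orders of magnitude larger than the
  remaining convergence slack.
- **DE calibration**: 2000 genes, one cell type; a pure null, a 10%
  planted mixture for realized FDR, and a β = +1 recovery planted in a 10%
  minority (a global shift would be removed by TMM/cyclic loess, which
  assume most genes are null).
- **TF drivers**: 50 TFs, 10 drivers, 20 targets each, α = 0.8, noise sd
  0.3, C = 20; fitted log2FCs are the planted patterns plus N(0, 0.1²)
  estimation noise, testing the inference stage; the DE engine itself is
  covered by the other studies.
- **Ortho-exon fidelity**: 500-record fixture spanning every rule
  boundary, exact match to the planted keep/drop labels, order-invariance
  under input reversal.
- **End-to-end demo**: 1000 genes, 5 cell types, 30 cells/sample, K scan
  2–5 with 3 restarts; deterministic under a fixed seed.

## Known limitations

- The mixed model supports two crossed random intercepts (individual,
  replicate); arbitrary random-effect structures are out of scope.
- The collapsed-fallback inference is exact only for the balanced crossed
  design and is skipped when composition PCs are included.
- Fisher's combination treats targets as independent; the null study
  bounds, but does not remove, the resulting optimism.
- Cyclic loess (like all global normalizations) removes genuinely global
  expression shifts between species; planted-effect studies must keep
  effects non-global.
- The hybrid log2FC estimator is pseudobulk-based; a per-cell estimator
  may behave differently for genes with strong cell-to-cell heterogeneity.
- The label-transfer stage assumes a precomputed embedding; batch
  correction itself is not implemented.
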