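# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `sextwas`.

## Analysis models

**Cross-sectional pathology.** Amyloid load and tau tangle density are
percent-area immunohistochemistry measures; they are analyzed on the square
root scale (which approximately normalizes them) and mean-centered. Per
gene, an OLS fit of the centered outcome on centered expression plus age at
death and PMI (plus sex in pooled fits); inference by the t reference with
residual degrees of freedom. The many-gene screen computes the identical
estimates by Frisch–Waugh–Lovell projection (QR of the shared covariate
design, then per-gene slope on residualized vectors); the per-gene route via
statsmodels is kept and the two are cross-checked in the tests.

**Longitudinal cognition.** The global cognition composite is the mean of
available z-scores from up to 17 neuropsychological tests across five
domains; a visit with no available test composes to missing. Trajectories
are modeled with a per-decedent random intercept and random slope on time,
where time is the interval between each visit and the decedent's final
visit (≤ 0 years). With this sign convention a positive gene×time
coefficient means slower decline (protective). Covariates: age at death,
PMI, education, latency to death, plus sex where pooled. Estimation is
maximum likelihood (not REML) so nested-model comparisons remain valid;
inference is a Wald test with a normal reference rather than Satterthwaite
degrees of freedom — a deliberate simplicity/determinism trade whose
deviation from t-based inference is negligible at hundreds of decedents.
The reported association is the gene×time coefficient; a switch
(`report="gene"`) gives the level effect instead.

Optimizers for the mixed likelihood occasionally stall on flat
variance-component surfaces; fits run through an L-BFGS → BFGS-default →
Powell chain, accept the first converged result, and fall back to a
random-intercept-only model (tagged `mixedlm-reduced`) before flagging a
gene inestimable. Designs with a single visit per decedent are inestimable
by construction and flagged, not fitted.

**Fast longitudinal screen.** Fitting the full mixed model per gene is the
bottleneck of a transcriptome-wide screen. `longitudinal_screen` estimates
the variance components once from the gene-free null model, then solves
each gene's fixed effects by generalized least squares with those
components fixed — exact conditional on the variance components, and
vectorizable because expression is constant within a decedent (per-decedent
cross-products are precomputed and rescaled by the gene value). When a
single gene carries a strong slope effect, the null model absorbs some of
it into the random-slope variance and the plug-in standard errors become
mildly conservative (observed ~10–20% inflation for a planted 0.05 effect);
point estimates are unaffected. The full per-gene mixed model
(`fit_longitudinal`) remains the reference implementation and is what the
parameter-recovery benchmark exercises.

**Interactions.** Sex is coded with female as the reference level, so the
sex×gene (cross-sectional) or sex×gene×time (longitudinal) coefficient
reads as the male deviation. The three-way model adds APOE-ε4 positivity
and all nested products, reporting sex×gene×APOE×time, and emits the four
sex×APOE subgroup gene×time slopes for plotting. Sensitivity refits add
APOE-ε4 status (and amyloid/tau when cognition is the outcome) and are
reported uncorrected, never entering the discovery FDR.

**Sex-difference expression test.** Two-sided Wilcoxon rank-sum; exact
enumeration when both groups have n ≤ 10 and no ties, otherwise the normal
approximation with tie correction.

## Discovery framework

BH step-up adjustment is applied within each family defined by the full
cross-product region × outcome × stratum (or interaction term) × chromosome
class. The partition is a deliberate sensitivity choice: small sex-
chromosome families are not dominated by the autosome's multiplicity. The
sex-specificity rule is applied a priori: stratified p_FDR ≤ 0.05 in
exactly one sex, other sex p_FDR > 0.05 (no effect-size criterion), and
nominal interaction p < 0.05; both-sexes significance overrides the
interaction. The stringent tier requires interaction p_FDR ≤ 0.10 within
interaction families mirroring the stratified ones. Cross-region support
counts regions with the same call and the same sign of the significant
stratum's coefficient. Tallies report exact ratios; percentages are
rounded only at presentation (whole percents for region/outcome shares, one
decimal elsewhere).

## Enrichment

Classic weighted Kolmogorov–Smirnov running sum with weight exponent 1
(configurable): hits increment by |β|^w normalized over the set's hits,
misses decrement by 1/(N − N_hits). ES is the running-sum value of maximal
absolute deviation; when the positive and negative extrema tie in magnitude
(possible exactly, because increments are rational) the positive extremum
is taken, in both the implementation and the brute-force oracle. ES is
clipped to [−1, 1] against floating-point overshoot. The null permutes gene
labels preserving set size (the only option for pre-ranked input); p-values
use the matching-sign null tail with a +1 pseudocount, so p ≥ 1/(n_perm+1);
NES divides ES by the mean |null ES| of matching sign; BH runs across sets
within one ranked list. Sets are size-filtered to 15–500 genes of overlap
with the ranked universe (autosomal genes only in the pipeline driver,
which builds one list per sex × region × outcome).

## Preprocessing

Stage order is fixed: sample QC (drop RIN < 4, PMI > 24 h, or missing
required covariates; boundary values kept) → low-expression filter (keep a
gene reaching ≥ 1 CPM in ≥ 50% of samples of at least one diagnosis group;
the "every group" reading is a switch) → normalization → 5-SD winsorization
(offending entries set to 0, single pass on pre-replacement statistics) →
PCA sample QC (drop > 5 SD outliers on PC1/PC2; drop samples whose
2-means cluster on mean Y-linked and XCI-escape expression contradicts
reported sex) → residualization on technical covariates (batch indicators,
age, PMI, RIN, alignment-metric percentages; collinear columns dropped with
a warning) → per-gene mean-centering. Chromosome classes are processed as
separate matrices; the Y matrix uses male samples only.

Normalization is log2-CPM (offset 1) followed by per-sample linear
detrending on centered GC fraction and centered log gene length, preserving
the sample mean. This removes the trends a conditional-quantile spline
normalization targets without reproducing its basis; the contract — no
residual linear GC trend — is what downstream modeling relies on, and is
asserted to 1e-6. Genes lacking GC or length annotation are dropped and
reported. Sex is not residualized by default (within a stratum a sex main
effect is a constant shift); a flag enables it.

## Matching

Propensity scores are fitted male-vs-female probabilities from an
unpenalized logistic model on the six criteria (ridge fallback on
separation). Matching is greedy 1:1 nearest-neighbor on the logit scale,
males processed in descending score order, ties broken by decedent id, no
caliper by default, without replacement; performed per brain region on that
region's available decedents. Balance: two-sample equal-variance t-tests
for continuous criteria, chi-square (Fisher for sparse 2×2) for
categorical; a constant criterion reports p = 1. One caveat documented by
the tests: in-sample fitted probabilities discriminate mechanically by
about k/n even when the criteria carry no sex signal, so a "no difference"
check on fitted scores must allow that overfit margin.

## Synthetic-data generator

The generator's defaults encode the study conditions the pipeline targets:
328 males and 640 females; three brain regions with 35% per-region
missingness (every decedent keeps at least one region, reproducing a
samples-to-decedents ratio near 2); mean age at death 88.3 (SD 6.5); mean
7.4 annual visits; APOE-ε4 allele frequency 0.14 (≈26% carriers under
Hardy–Weinberg); a single race category by default (the cohorts are ~98%
one category; a second category is a switch for exercising categorical
matching); one third of X-linked genes escape inactivation with a 1.4×
female dosage; Y-linked genes are essentially silent in females. The
default gene panel is desk-scale — 500 autosomal, 40 X, 10 Y — rather than
transcriptome-scale; every benchmark states the panel it uses.

Counts are gamma-Poisson (negative binomial, variance m + φm² with φ = 0.2
by default) around a per-sample expected value built from: a gene baseline,
a per-decedent latent standardized deviate shared across regions (the
biological signal on which outcomes are planted), a region shift, planted
per-sample GC and log-length trends (SD 0.3 and 0.1 log2 units) for the
normalization stage, and a uniform library size (5×10⁵–2×10⁶ for the
desk-scale panel). A consequence worth knowing: measured log-CPM correlates
with the latent signal at r ≈ 0.55 under these defaults, so effects planted
on the latent scale attenuate by roughly that factor when estimated from
counts — model-level benchmarks therefore plant effects on expression
directly, while end-to-end runs use larger planted effects.

Pathology is generated directly on the square-root (analysis) scale —
covariate effects, a female tau excess of 0.2, planted sex-specific gene
effects on the latent expression, Gaussian noise of SD 1 — with a flag to
emit squared raw values instead. Cognition visits are annually spaced,
counted Poisson with the configured mean (minimum one), with random
intercept SD 0.6, random slope SD 0.05/yr, residual SD 0.25, mean slope
−0.05/yr: values in the range reported for global cognition composites.
Missing visits are missing-completely-at-random; informative dropout is out
of scope. A fixed seed makes every product bit-identical across runs; the
cohort, counts, and outcome stages draw from independent seeded streams.

What passing tests show — and do not. The generator emulates the *data
structure* (dimensions, dosage, noise anatomy, trajectory shape), not real
biology: no linkage disequilibrium or co-expression among genes, no
cell-type composition, no batch structure beyond a categorical shift, no
informative missingness. Calibration and recovery results on it validate
the machinery, not effect sizes in any real cohort.

## Benchmarks and problem sizes

The seeded benchmark routines (`sextwas.evaluation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use these sizes,
chosen to give stable Monte-Carlo estimates at desk runtimes: tally
arithmetic over the published category counts (exact); BH vs a brute-force
step-up on 1,000 vectors of length ≤ 8; FDR control on 200 null replicates
of 500 genes × 100 decedents/sex (the realized false-discovery proportion
under a global null is 1 with probability ≈ α and 0 otherwise, so its mean
estimates the FDR); classifier operating characteristics over 4 replicates
× 200 genes (30 causal at 0.4 SD female-only, 30 shared, each gene paired
with its own outcome so the standardized effect is exactly as stated);
mixed-model recovery over 100 replicates of 200 decedents × ~8 visits;
enrichment-score equivalence on 500 random instances ≤ 50 genes plus a
planted top-20 set at 1,000 permutations; matching improvement over 100
QC'd shifted cohorts (all four continuous criteria shifted); and one exact
label-swap symmetry check. The matching benchmark applies sample QC before
matching because that is the pipeline's stage order; the planted extreme-PMI
QC failures would otherwise contaminate the SMD denominator.

## Known limitations

- The GLS plug-in screen's standard errors are conservative when single
  genes carry large slope effects (see above); top hits should be refit
  with `fit_longitudinal`.
- Wald-normal mixed-model inference is anti-conservative at small numbers
  of decedents; the framework is intended for hundreds.
- Greedy nearest-neighbor matching is not optimal matching; with heavy
  distribution shift it can leave residual imbalance that the balance table
  will reveal.
- The permutation GSEA uses simple gene-label permutation; no multilevel
  p-value refinement, GO DAG handling, or term-redundancy collapsing.
- r×c categorical balance tables with sparse cells fall back to chi-square
  with a note (exact tests beyond 2×2 are not attempted).
- The winsorization rule sets outliers to 0 — the convention adopted here —
  which is a shrink-to-center only for mean-centered expression.
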