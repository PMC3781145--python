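# Methods

This note documents the statistical content of `snpepi`: the models, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, numerical details, and known limitations.

## Data model and genotype coding

A `Dataset` couples a samples × SNPs genotype matrix (minor-allele counts
0/1/2, −1 for missing) with a sample table (binary phenotype, disease subtype,
age, sex, country) and SNP annotations. The minor allele is defined **once,
from the controls of the full dataset, at load time**: genotype 0 is the
homozygote of the most frequent control allele, which is the reference group
of every odds ratio downstream. Stratified subsets (`stratify`) keep all
controls, keep only the requested case subtypes, and inherit the coding
unchanged, so discovery and replication stages — and different case groups —
remain directly comparable. Frequency ties at 0.5 resolve to the
lexicographically smaller allele character for determinism.

Missingness is handled pairwise: a sample missing the tested SNP (or either
SNP of a pair, or a covariate) is dropped for that test only, never from the
dataset. No call-rate filter is applied by default.

## Single-SNP association

Unconditional logistic regression of case status on a genetic coding of the
minor-allele count g — dominant 1{g≥1}, recessive 1{g=2}, log-additive g,
codominant (two indicators) — plus covariates (age in years, sex, country as
one-hot levels). OR = e^β, CI = e^(β±1.96·SE), p from the Wald statistic.
Fits go through statsmodels' Newton MLE; separation or non-convergence raises
an error rather than returning a spurious finite OR.

**Best-model selection** fits dominant, recessive and log-additive and keeps
the minimum-AIC fit, ties broken in that fixed order. All three codings have
the same parameter count, so this is equivalent to maximum likelihood among
the codings; AIC is used as the stated criterion because it extends naturally
if the codominant coding is added to the candidate set. The selected model's
p-value is *post-selection* and is labelled "model-selected p" everywhere it
is reported; its null calibration is deliberately not asserted anywhere.

**Hardy–Weinberg QC** in controls uses the exact conditional test: given the
allele counts, the p-value is the probability mass of all heterozygote
configurations no more probable than the observed one (relative tie tolerance
1e−12). Implemented directly (log-gamma weights, vectorised over the
configuration range); the test suite checks it exhaustively against integer
enumeration for every table with ≤200 samples.

**Subtype heterogeneity** of the per-allele OR uses a polytomous (multinomial)
logistic model over {control, subtype₁, …, subtype_k}: the LR statistic is
twice the log-likelihood gap between subtype-specific genotype coefficients
and a single shared coefficient, referred to χ²(k−1). The shared-coefficient
model ties one parameter across equations, which standard multinomial
routines do not support, so both likelihoods are maximised by the package's
own optimizer (analytic gradients, BFGS); the unconstrained model is
cross-checked against statsmodels MNLogit in the tests. Measured type-I error
at α=0.05 over 1000 null replicates: within [0.03, 0.07].

## MDR

Classic Multifactor Dimensionality Reduction for two-way scans. Within each
training fold, each of the nine two-SNP genotype cells is labelled high-risk
when cases/controls ≥ T with T the training-fold case:control ratio (a
case-only cell is high; an empty cell is low); the labelling is scored on the
held-out fold by balanced accuracy, BA = (sensitivity + specificity)/2.
Defaults: 10 stratified folds, selection metric within a fold = training BA
(lexicographic tie-break), report metric = mean testing BA and CVC (folds in
which the pair was best). MDR is covariate-naive by construction; in the
pipeline it runs unadjusted while MB-MDR carries the covariates.

For the consensus rule a pair is "flagged by MDR" when CVC ≥ 6/10 **and** its
mean test BA exceeds the 95th percentile of a seeded permutation null of the
*top* mean test BA (default 100 phenotype permutations, full CV scan each).
This is a declared convention — the flagging threshold is not part of the
method's classical definition — and both knobs are configurable.

## MB-MDR

For each pair, every cell with ≥ `min_cell` samples (default 10) is tested by
logistic regression of case status on the cell-membership indicator plus
covariates; with `adjust_marginal` (default on for scans) the log-additive
codings of both SNPs are appended, so purely additive two-SNP signals are
absorbed and do not masquerade as interaction. A cell is H when its
coefficient is positive with p < `alpha_cell` (default 0.1, the conventional
screening level), L when negative, otherwise O; undersized or non-convergent
cells are O.

The association statistic is W = max(W_H, W_L): the squared Wald statistic of
H-membership (H cells vs all others) in a covariate-adjusted logistic fit, and
likewise for L; an absent category contributes −∞, and if all cells are O the
statistic and its p-value are NA. Permutation p-values shuffle the phenotype
only (covariates stay attached to their samples), recompute categorization and
W from scratch per permutation, and use the add-one estimator
(1 + #{W_perm ≥ W_obs})/(B + 1), whose floor is 1/(B+1). Permutation-W ties
are counted with an absolute slack of 1e−9.

Scans are two-tier for tractability: observed W for every pair, permutation
p-values (B_screen, default 999) only for pairs at or above the
`screen_quantile` of the observed-W distribution (default 0.95; every pair is
permuted when ≤20 pairs are scanned). Ranking is by permutation p, then W.
A pair is "flagged by MB-MDR" for the consensus rule when its screening
perm_p < 0.05 — again a declared convention.

### Numerical core

A permutation scan refits millions of small logistic models, so the package
carries its own batched Newton–Raphson solver: one iteration updates the
coefficient vectors of every permutation simultaneously, and when all design
columns are constant within a modest number of sample groups (true whenever
the covariates are discrete — cell membership and marginal codings are
themselves cell-constant) the per-sample Bernoulli likelihood is collapsed
exactly into a grouped binomial likelihood over the unique design rows,
reducing each iteration from O(n) to O(#groups). Convergence tolerance 1e−10
on the step, ridge 1e−10 on the Hessian for numerical safety, |β| > 30
treated as separation (the affected cell becomes O; the affected W component
−∞). Solutions agree with statsmodels to ~1e−10; the tests assert 1e−6.
Continuous covariates (e.g. age) fall back to per-sample batched fits —
identical results, higher cost; large permutation budgets are most economical
with discrete covariates.

## Two-stage pipeline

Per case group (e.g. all cases, PTC overall, cPTC): every configured detector
flags pairs on the discovery series; `consensus_select` keeps pairs flagged by
at least `k_required` detectors (default 2-of-2 built-ins; external detectors
— any callable mapping a Dataset to flagged pairs — raise the pool, e.g. to a
3-of-5 rule). For each selected pair, the discovery H/L/O grid is **frozen**
and forced onto the replication series: membership comes from the fixed grid,
only W and its permutation p are recomputed, and perm_p < 0.05 declares
replication. Replication p-values are not multiplicity-corrected — stage 2 is
a single pre-specified test per pair — but the number of pairs tested is
always reported alongside. Replicated pairs get a combined analysis: both
series pooled, a series indicator added to the covariates, fresh
categorization, and a large permutation budget (default B = 9999; configurable
to 100 000 for confirmatory runs, which stays tractable in the grouped path).
Allele-coding mismatch between stages is a hard error.

## Synthetic data generator

The generator produces the structure the analysis assumes: independent
biallelic SNPs in HWE at configurable MAFs, a logistic penetrance
(baseline logit −2.5 ≈ 7.6% prevalence) with per-SNP coded effects, an
optional 3×3 grid of cell log-OR offsets for one designated pair, covariate
effects, and **exact case/control ascertainment by rejection sampling** (a
draw cap guards against near-impossible configurations). Covariate defaults
echo a European thyroid-cancer case-control design: age ~ Normal(47, 12)
truncated to [18, 90], P(female) = 0.82, two country levels; the default case
subtype mix is cPTC 304/609, fvPTC 146/609, otherPTC 90/609, FTC 69/609
(otherPTC absorbs cases outside the named subtypes so the mix closes).
Subtype-specific aetiology is available by mapping subtypes to their own
penetrance models; controls are then drawn disease-free under the control
model.

**Pure-epistasis models** place a base pattern on the 3×3 grid — `corner`:
an elevated block where both SNPs carry ≥1 minor allele (a dominant×dominant
interaction whose extreme cell is the minor/minor double homozygote);
`checkerboard`: alternating signs (XOR-type) — and then solve row/column
offsets numerically so the HWE-weighted penetrance is constant across each
SNP's genotype classes, making both marginal ORs exactly 1 in the source
population. `cell_log_or` is defined as the **realized** high-vs-low cell
contrast of the final balanced grid: the checkerboard's offsets are exactly
±c by symmetry, and the corner block is normalised (by root-finding on the
base magnitude, with continuation in the solver for strong effects) so the
block sits c above the cross cells after balancing — the same scalar means
the same realized contrast under either pattern. The corner geometry is a
*block* rather than the double-homozygote cell alone because a single cell at
MAF 0.3 holds ~0.8% of samples, too little signal mass for any cell-based
detector at realistic case-control sizes; the block keeps the same
qualitative risk surface with detectable mass. Planted-effect benchmark
defaults (cell log-OR 1.2, MAFs 0.3) are benchmark choices, not estimates of
any real interaction.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (markers are exchangeable tags, not haplotypes), population
stratification or admixture, genotyping error beyond uniform missingness,
covariate–genotype correlation, and quantitative traits. Passing benchmarks
therefore demonstrate correct behaviour of the statistics under their own
assumptions — not robustness to confounding, LD leakage between panel
members, or differential genotyping artefacts in real data.

## Benchmark problem sizes

The statistical acceptance tests run at the study-like sizes they describe:
discovery 609 cases / 525 controls, replication 969 / 1040; 50-SNP panels for
single-stage scans, a 20-SNP panel for the 50 end-to-end two-stage runs;
B = 200 for the 500-replicate type-I check, B_screen = 199 for scan
screening, B = 999 for replication. Two-stage benchmarks use discrete
covariates (sex; sex + country in replication), keeping every fit in the
exact grouped path. These sizes are the package's declared benchmark
conditions; all scale up through configuration.

## Known limitations

* The permutation scheme assumes exchangeability of phenotype given
  covariates; residual-permutation schemes (e.g. Freedman–Lane) are not
  implemented.
* W's null distribution is not chi-square (category selection precedes the
  Wald fit); inference must go through permutations, which is why NA/−∞
  conventions matter.
* The MDR and MB-MDR flagging thresholds for consensus are conventions, and
  consensus behaviour with external detectors depends entirely on the quality
  of the plugged-in callables.
* Post-selection single-SNP p-values (best-model selection) are
  anti-conservative under the null and are only ever reported with the
  "model-selected p" label.
* k-way interactions for k > 2, quantitative traits, binary PLINK and VCF
  input, X-chromosome handling, and imputation dosages are out of scope.
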