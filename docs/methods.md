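# Methods

This note documents the statistical model behind each pipeline stage,
the synthetic data-generating process, the main tunable parameters,
numerical choices, and known limitations.

## Response phenotype

The response is the relative LDL-cholesterol change
`log(mean of two post-treatment visits) − log(mean of two pre-treatment
visits)`, natural log. Averaging duplicate visits first damps
visit-level technical variation; the log ratio removes the strong
dependence of absolute change on baseline LDLC. Any fixed log base only
rescales the response and is irrelevant to ranks, classification and
explained-variance fractions.

Covariate screening regresses the log change on each candidate (sex,
age, BMI) separately and keeps those with slope p < α (default 0.05; no
multiplicity correction, matching the screening character of the step).
The adjusted response is the residual of a joint OLS fit on the keepers
(centered log change if none survive), so it is exactly orthogonal to
the retained covariates. Constant covariates are excluded with a
warning. Smokers can be filtered out before analysis (default on).

## Expression normalization

Four steps: (1) column-wise quantile normalization of each array onto
the mean order-statistic profile across arrays (average ranks for
ties); (2) per-gene rank-based inverse-normal transform with the Blom
offset (r − 3/8)/(n + 1/4) — the target distribution is standard
normal, chosen so the later Φ(z) non-negativization is exact; (3)
per-gene least-squares residualization on the batch covariate design
(categoricals dummy-coded); (4) a second inverse-normal transform.
Step 4 is a monotone function of the step-3 ranks, so downstream
rank-based logic is unaffected by residual scale. All-constant genes
map to zero vectors with a warning. Note that step 1 maps every array
onto one shared value set, so within-gene ties across samples are
possible afterwards; they are handled by average ranks and make the
final per-gene distribution standard normal only up to tie-averaging.

## NMF selection of extreme responders

The normalized submatrix of candidate samples is made non-negative by
replacing each value z with Φ(z) (one minus its upper-tail P value
under normality; one-sided so that within-gene ordering is preserved),
clipped to [1e−12, 1 − 1e−12]. Factorization A ≈ WH uses Lee–Seung
multiplicative updates for the Frobenius objective, random uniform
initializations scaled by mean(A), per-run seeds spawned from a master
seed, and the best of `n_runs` restarts (library default 500).
Convergence: relative error decrease < 1e−6 or 2,000 iterations; the
error trace is retained and is non-increasing by construction of the
updates. Samples are assigned to the cluster of their largest H entry.

Cluster quality against known labels uses purity and normalized
entropy; rank stability uses consensus matrices over repeated runs,
the cophenetic correlation of average-linkage clustering of 1 − C, and
dispersion mean(4(C − ½)²). The tail-selection sweep takes, for each
even N in 20…80, the N/2 top and bottom responders (ties broken by
sample id, stable), preselects the 2,000 genes with the largest
absolute group mean difference, clusters at k = 2 and scores purity
against the true split; the baseline repeats this machinery on random
N-sample sets split into two arbitrary pseudo-groups. The chosen N is
the largest one whose purity meets the cutoff (0.9), operationalizing
"maximize purity while keeping a reasonable sample size"; if none
qualifies the argmax-purity N is returned with a warning.

A caveat the synthetic experiments make explicit: preselecting the
most group-different genes *overfits* small subsets, so the random
baseline is itself near-perfect at these subset sizes when the gene
universe is a few thousand genes. The baseline becomes informative on
larger universes; on synthetic cohorts the true-tails purity should be
read against the cutoff, not only against the baseline.

## Signature statistic

For equal groups of size N, d(i) = (x̄_H − x̄_L)/(s + s₀) with
s(i) = sqrt[(1/(N(N−1)))·(SS_H + SS_L)]; with s₀ = 0 this equals the
classical pooled-variance two-sample t statistic (asserted against an
independent implementation in the tests). The varying fudge factor is
s₀(i) = s₀max·(1 − F̂(s(i))), with F̂ the empirical CDF of the observed
scatters: it starts at a small constant for the least-variable genes
and decays to zero as s grows, which is the qualitative contract of a
variance-stabilizing fudge. s₀max is tuned over a grid of candidates
(0 plus the 0th–20th percentiles of s) by minimizing the coefficient
of variation, across s-deciles, of the median |d| — SAM-style tuning;
ties prefer the smallest s₀max (least shrinkage). The schedule is
pluggable (any object with `s0_of`) so alternative functional forms
can be swapped in.

P values come from balanced permutations of the high/low labels over
the 2N samples (all C(2N, N) assignments enumerated when fewer than
`n_perm`), with d recomputed under the frozen schedule. The default
pools |d| over genes and permutations, p(i) = (1 + #{|d_p| ≥ |d(i)|})
/(1 + P·G): with ~10³ permutations and ~10³–10⁴ genes this gives far
finer resolution than per-gene nulls; a per-gene mode is retained.
Permuting labels over whole sample vectors (rather than independently
per gene) preserves inter-gene correlation, the statistically
conventional choice. The add-one correction avoids zero p values.
Genes are ranked by ascending p, then descending |d|, then id; the top
`n_select` (default 100) form the signature, annotated by direction.
A sweep utility scores alternative signature sizes with a
user-supplied evaluator. Overlap enrichment of a gene set against a
reference within a universe is the upper-tail hypergeometric
probability.

## Feature assembly and SVM evaluation

SNPs are encoded as additive dosages (0–2, fractional allowed — the
GWAS convention, compatible with imputed data). For each signature
gene the most strongly associated eQTL SNP below p < 5e−8 is kept
(ties by lexicographic SNP id). Canned model variants: SG, SG_NO,
eQTL-only, SG+eQTL, substitution, GWAS-only, SG+GWAS, all. Missing
dosages are mean-imputed *inside* the cross-validation loop from
training samples only; per-feature z-scoring likewise uses training
statistics only (asserted by an outlier-injection test).

The learner is a Gaussian-kernel SVM, k(x, y) = exp(−γ‖x − y‖²), with
γ = 1/median pairwise squared distance of the standardized training
rows, C = 1, and for regression an ε-insensitive tube of 0.1 on the
z-scored response (so the tube is scale-free); these stand in for the
default settings of common SVM packages. Other kernels are accepted
untuned for comparison. Evaluation repeats stratified random 90/10
splits (default 1,000; literal Monte-Carlo holdout rather than
rotated 10-fold). Classification feeds signed decision scores to a
rank-based (Mann–Whitney, tie-corrected) AUC, averaged per repeat with
a pooled option. The tail sweep labels the top/bottom f/2 of
responders for f from 10% upward (f = 1 is a median split; tails below
4 samples are skipped).

Explained variance is the squared Pearson correlation between held-out
predictions and observations with predictions *pooled* across repeats
before correlating (default), floored at zero and reported as a
percentage. Pooling was chosen because the per-repeat mean of r²
carries a positive small-sample bias of roughly 1/(n_test − 1) (≈ 3%
at a 37-sample fold), which would report phantom signal on null data;
the per-repeat mean and the pooled 1 − SSE/SST variant remain
available as options.

Two estimator properties matter when reading the numbers. First, on a
single finite cohort the Monte-Carlo-CV mean AUC under the null is
dataset-conditional, wobbling by several points regardless of the
number of repeats; null calibration checks therefore average over an
ensemble of independent cohorts. Second, the cross-validated explained
variance is a *downward-attenuated* estimate of the true predictable
variance fraction (finite-sample estimation loss of the fixed-setting
SVR on ~100 features at n ≈ 372, plus measurement-noise dilution),
while evaluating a signature that was *discovered on a subset of the
same cohort* biases it upward (gene selection is circular). On
synthetic cohorts with a known 15% planted expression share the two
readings bracket it from opposite sides (roughly 5–8% for the true
gene set, ~20–30% for the discovered set); results on real data should
be read with the same brackets in mind.

## Synthetic cohorts

`SimConfig` defaults describe a statin-trial-like cohort: 372
non-smokers, 5,000 genes, a 100-gene signature with 36 strong best
cis-eQTLs (r² = 0.8 of the gene's pre-batch variance; best-SNP
selection from a catalogue justifies a high default), 7 trait SNPs,
response scale log-change mean −0.55 / SD 0.15, ages uniform on
[30, 75] with a −0.002 /year effect (~3% of response variance), four
round-robin batches with N(0, 0.3) offsets, MAFs uniform on
[0.1, 0.5] under Hardy–Weinberg.

Signature genes share a latent module-activity factor
(`signature_module_r2`, default 0.35 of each gene's non-eQTL
variance), emulating the co-regulation of a cholesterol-homeostasis
module. This is essential, not cosmetic: a response trait spread over
100 *independent* genes yields per-gene tail separations of ~0.15 SD,
far too small for expression-based clustering of extreme responders or
for signature recovery to work at all; with the module, per-gene tail
separations land near 1 SD, the regime in which the method operates.
Each gene's variance splits as eQTL share `eqtl_r2` (eQTL genes only),
module share `signature_module_r2·(1 − eqtl_r2)`, and noise. Directions
are 2/3 up in high responders, 1/3 down.

The latent response is a weighted sum of the signature-expression
score (the direction-weighted sum of actual expression values, so eQTL
genotypes carry exactly their expression-variance share of signal),
the GWAS-SNP dosage score, an age term, and residual noise; the
components are empirically orthonormalized (Gram–Schmidt) so realized
latent-scale variance fractions equal `trait_r2_expression` (0.15) and
`trait_r2_snps` (0.04) exactly. LDLC visits are generated from a
lognormal baseline (mean 132 mg/dL, CV 0.20) with multiplicative
per-visit noise (CV 5%, a free parameter — visit-level measurement
error is not pinned down by public summaries); the observed log change
is then the latent response diluted by ~×0.9.

What the generator does **not** emulate: linkage disequilibrium and
population structure; probe-level array artifacts; non-normal
expression distributions; multiple overlapping modules; non-linear
genotype effects. Passing tests therefore demonstrate correctness of
the machinery and its behaviour under the assumed generating model,
not performance on real cohorts.

## Numerical choices and degenerate inputs

Division guards use 1e−12; Φ outputs are clipped to (0, 1).
Zero-scatter genes with s₀ = 0 produce ±inf d with a warning. NMF
stops on relative error change < 1e−6, an absolute floor of
tol·‖A‖ for exactly low-rank inputs, or 2,000 iterations (warning when
unconverged). A degenerate consensus (all pairs equidistant) reports
cophenetic correlation 1. Response ties in tail selection break by
sample id; eQTL p ties by SNP id; signature p ties by |d| then id —
all deterministic. Matrix TSVs are written with `%.17g` and read with
round-trip float parsing, so write/read cycles and reruns under one
seed are bit-identical; the run manifest excludes wall-clock times for
the same reason.

## Problem sizes in tests and the acceptance script

The library defaults keep the full-analysis sizes (500 NMF restarts,
500 random baseline sets, 1,000 permutations, 1,000 CV repeats). The
test suite and `scripts/acceptance.py` use reduced sizes chosen to
keep single-CPU runs in the minutes range while leaving every
assertion's Monte-Carlo error well inside its tolerance: typically
10–20 NMF restarts, a 20–80 step-10 tail grid, 500 permutations,
100–200 CV repeats, and cohort ensembles (24–30 null cohorts for AUC
calibration; 3 cohort draws for variance-recovery checks, since a
single draw's sample r² wobbles by ±3 points at n = 372).

## Known limitations

- The varying-s₀ schedule is one concrete, monotone, percentile-based
  realization of a decaying fudge factor; other forms fitting the same
  contract plug in through `S0Schedule`.
- Explained-variance attenuation (see above) means planted variance
  fractions are not recovered unbiasedly by the fixed-setting SVR at
  n ≈ 372 with ~100 features; comparisons *between* feature sets are
  the robust use of the estimator.
- The random baseline of the tail sweep saturates on few-thousand-gene
  universes (preselection overfitting).
- VCF support covers dosage (DS) input/output only, with placeholder
  alleles on write; no genotype-likelihood handling.
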