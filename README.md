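# statresp

Pipeline for predicting inter-individual LDL-cholesterol (LDLC)
response to statin treatment from transcriptomic and genetic features.

Statins lower LDLC, but the size of the reduction varies widely between
people and known DNA variants explain only a few percent of that
variation. `statresp` implements an analysis strategy that mines
expression profiles of patient-derived cell lines for a *signature* of
the response, then builds prediction models mixing three feature kinds:
signature-gene expression levels, the best cis-eQTL genotype for each
covered signature gene, and GWAS SNPs previously associated with the
response. It is aimed at statistical geneticists and pharmacogenomics
analysts who want a tested, reproducible implementation of each stage —
and a synthetic-cohort generator so every stage can be exercised
without access to controlled clinical data.

## Method

1. **Response phenotype.** Per participant, two pre-treatment and two
   post-treatment LDLC visits are averaged and the response is the
   relative change `log(LDLC_post) − log(LDLC_pre)`. Candidate clinical
   covariates (sex, age, BMI) are screened by linear regression and the
   response is residualized on those with slope *p* < α (typically only
   age survives).
2. **Expression normalization.** Each array is quantile-transformed to
   the mean empirical distribution; each gene is rank inverse-normal
   transformed (Blom offset), residualized on batch covariates, and
   transformed again, leaving every gene ≈ N(0, 1).
3. **Extreme-responder selection.** For subset sizes N = 20…80, the
   N/2 highest and N/2 lowest responders are clustered by non-negative
   matrix factorization (A ≈ WH, multiplicative updates, best of many
   random restarts) on their 2,000 most group-different genes, after
   mapping each normalized value z to Φ(z) ∈ (0, 1). Cluster quality is
   scored by *purity* (1/n)·Σᵢ maxⱼ nᵢʲ and a normalized *entropy*
   against the true high/low split, with a random-subset baseline;
   consensus matrices, cophenetic correlation and dispersion diagnose
   the stable rank.
4. **Signature genes.** For each gene the *relative difference*
   d(i) = (x̄_H(i) − x̄_L(i)) / (s(i) + s₀(i)) is computed, where
   s(i) = sqrt[(1/(N(N−1)))·(SS_H + SS_L)] is the gene-specific scatter
   and the fudge factor s₀(i) = s₀max·(1 − F̂(s(i))) decays from a small
   constant to 0 as the scatter grows, with s₀max tuned to flatten the
   spread of |d| across the scatter distribution. Significance comes
   from balanced label permutations scored under the frozen schedule
   (pooled across genes by default); the top 100 genes form the
   signature (SG).
5. **Prediction.** Radial-basis SVMs (γ from the median pairwise
   squared-distance heuristic, C = 1, ε = 0.1 on the standardized
   response) are evaluated by 1,000 stratified random 90/10 holdouts:
   ROC AUC for classifying high vs low tails as the tail fraction
   grows, and cross-validated explained variance (squared correlation
   of pooled held-out predictions with observations) for the continuous
   response. Model variants: SG expression only, eQTL genotypes only,
   combined, substitution (genotypes replacing expression for covered
   genes), GWAS SNPs, and all features.

## Worked example

Simulate a cohort, run the full pipeline with reduced stage sizes, and
inspect the results:

```python
from statresp import SimConfig, simulate_cohort, write_cohort
from statresp import PipelineConfig, run_pipeline

cohort = simulate_cohort(SimConfig(n_samples=120, n_genes=500, n_signature=40,
                                   n_eqtl_genes=12, n_gwas_snps=5,
                                   trait_r2_expression=0.45, trait_r2_snps=0.08,
                                   age_effect=-0.004, seed=9))
paths = write_cohort(cohort, "data")
config = PipelineConfig(
    expression=str(paths["expression"]), phenotypes=str(paths["phenotypes"]),
    genotypes=str(paths["genotypes"]), eqtl=str(paths["eqtl"]),
    gwas=str(paths["gwas"]), batches=str(paths["batches"]), out_dir="run",
    n_grid=(20, 36, 8), preselect=200, nmf_runs=10, random_sets=8,
    nmf_max_iter=500, n_perm=200, signature_size=40, cv_repeats=30,
    fractions=(0.15, 0.45, 0.15), models=("SG", "substitution"), seed=17)
run_pipeline(config)
```

`run/explained_variance.tsv` then holds (from an actual run):

```
model         explained_variance_pct  n    delta_explained_variance_pct
SG            31.41                   120  0.00
substitution  33.50                   120  2.09
```

and `run/auc_curves.tsv`:

```
model  fraction  auc_mean  auc_se
SG     0.15      1.000     0.000
SG     0.30      0.992     0.008
SG     0.45      0.911     0.017
```

Reading: with 45% of the latent response planted in the signature
genes, the discovered-signature regression model recovers ~31% of the
response variance out of sample; replacing covered genes' expression by
their strong eQTL genotypes changes this by ~2 points; and the
high/low classifier is near-perfect on the extreme 15% tails, decaying
as less extreme responders are included — the qualitative fingerprint
of a tail-concentrated expression signature.

The same stages are scriptable from the shell (`statresp simulate`,
`statresp preprocess`, `statresp select-tails`, `statresp signature`,
`statresp assemble`, `statresp predict`, `statresp run-all --config
config.yaml`).

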