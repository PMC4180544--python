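"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes: a continuous
statin-response trait (log post/pre LDL-cholesterol change) driven
partly by the expression of a planted signature-gene set, cis-eQTL SNPs
explaining a tunable fraction of each signature gene's expression
variance, independent trait-associated (GWAS-style) SNPs, an age
covariate effect, and array batch effects.

Signature genes additionally share a latent "module" activity factor
(``signature_module_r2``), emulating the co-regulation of a cholesterol-
homeostasis pathway: without it, a response trait spread over ~100
independent genes gives per-gene tail separations far too small for any
expression-based clustering of extreme responders to succeed. The
response remains, by construction, a weighted sum of the signature-gene
expression values (plus SNP, age, and residual components), so eQTL
genotypes carry exactly the share of signal their expression variance
fraction implies.

Variance bookkeeping: the response components (signature-expression
score, GWAS-SNP score, age) are empirically orthonormalized before
weighting, so the realized variance fractions equal the configured
``trait_r2_expression`` / ``trait_r2_snps`` exactly on the latent scale;
visit-level measurement noise then dilutes them slightly on the observed
log-change scale.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenotypeMatrix, PhenotypeRecord, records_to_frame


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a statin-trial cohort of 372 non-smoking
    participants profiled on expression arrays: 100 signature genes of
    which 36 carry a strong best cis-eQTL, 7 GWAS SNPs, an age effect
    on the response, and batch structure in the arrays.
    ``trait_r2_expression``/``trait_r2_snps`` are the fractions of
    latent response variance attributable to signature expression and
    to the GWAS SNPs (realistic values ~0.12-0.15 and ~0.04).
    """

    n_samples: int = 372
    n_genes: int = 5000
    n_signature: int = 100
    n_eqtl_genes: int = 36
    eqtl_r2: float = 0.8
    n_gwas_snps: int = 7
    trait_r2_expression: float = 0.15
    trait_r2_snps: float = 0.04
    age_effect: float = -0.002  # response units per year
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_batches: int = 4
    batch_sd: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0
    # shared-module variance fraction of each signature gene (of its
    # non-eQTL variance); induces the co-expression a pathway signature
    # shows in real data
    signature_module_r2: float = 0.35
    # fraction of planted signature genes expressed higher in high
    # responders (the remainder point the other way)
    frac_up: float = 2.0 / 3.0
    # response scale: log(LDLC-change) mean/SD typical of a 40 mg/day
    # statin cohort (~-43% mean reduction)
    response_mean: float = -0.55
    response_sd: float = 0.15
    baseline_ldlc_mean: float = 132.0  # mg/dL
    baseline_ldlc_cv: float = 0.20
    visit_cv: float = 0.05  # per-visit multiplicative LDLC measurement noise
    age_range: tuple[float, float] = (30.0, 75.0)
    smoker_fraction: float = 0.0

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_genes": self.n_genes,
            "n_signature": self.n_signature,
        }
        for name, v in counts.items():
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        for name, v in {
            "n_eqtl_genes": self.n_eqtl_genes,
            "n_gwas_snps": self.n_gwas_snps,
            "n_batches": self.n_batches,
        }.items():
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if not (self.n_eqtl_genes <= self.n_signature <= self.n_genes):
            raise ValueError("need n_eqtl_genes <= n_signature <= n_genes")
        for name in ("eqtl_r2", "trait_r2_expression", "trait_r2_snps", "signature_module_r2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.trait_r2_expression + self.trait_r2_snps + self._age_r2() >= 1.0:
            raise ValueError(
                "infeasible variance fractions: expression + SNP + age "
                "shares must sum to < 1"
            )
        if self.noise_sd < 0 or self.batch_sd < 0 or self.visit_cv < 0:
            raise ValueError("noise/batch/visit SDs must be non-negative")

    def _age_r2(self) -> float:
        # variance share implied by the age slope, for a uniform age draw
        age_var = (self.age_range[1] - self.age_range[0]) ** 2 / 12.0
        return (self.age_effect**2) * age_var / (self.response_sd**2)


@dataclass
class SimCohort:
    expression: ExpressionMatrix
    genotypes: GenotypeMatrix
    phenotypes: list[PhenotypeRecord]
    truth: dict = field(default_factory=dict)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _orthonormalize(components: list[np.ndarray]) -> list[np.ndarray]:
    """Gram-Schmidt over sample vectors; each output has mean 0, SD 1."""
    out: list[np.ndarray] = []
    for comp in components:
        v = comp - comp.mean()
        for u in out:
            v = v - (v @ u) / (u @ u) * u
        sd = v.std()
        if sd == 0:
            raise ValueError("degenerate (constant) response component")
        out.append(v / sd)
    return out


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Draw one synthetic cohort under ``config``.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes

    samples = [f"S{i + 1:04d}" for i in range(n)]
    genes = [f"G{i + 1:05d}" for i in range(g)]

    # --- covariates -------------------------------------------------
    age = rng.uniform(*config.age_range, size=n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    bmi = rng.normal(27.7, 5.3, size=n)
    smoker = rng.random(n) < config.smoker_fraction
    batch = np.arange(n) % config.n_batches  # round-robin assignment

    # --- genotypes --------------------------------------------------
    sig_idx = np.sort(rng.choice(g, size=config.n_signature, replace=False))
    sig_genes = [genes[i] for i in sig_idx]
    eqtl_genes = sig_genes[: config.n_eqtl_genes]

    eqtl_snps = [f"rsE{i + 1:04d}" for i in range(config.n_eqtl_genes)]
    gwas_snps = [f"rsG{i + 1:04d}" for i in range(config.n_gwas_snps)]
    n_snps = len(eqtl_snps) + len(gwas_snps)
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_snps)
    dosages = rng.binomial(2, mafs[:, None], size=(n_snps, n)).astype(float)
    genotypes = GenotypeMatrix(snps=eqtl_snps + gwas_snps, samples=samples, dosages=dosages)
    eqtl_dos = dosages[: config.n_eqtl_genes]
    gwas_dos = dosages[config.n_eqtl_genes :]

    # --- expression -------------------------------------------------
    # batch offsets: one per (batch, gene)
    batch_offsets = rng.normal(0.0, config.batch_sd, size=(config.n_batches, g))
    module = rng.normal(size=n)  # shared signature-module activity

    n_up = int(round(config.frac_up * config.n_signature))
    directions = np.ones(config.n_signature)
    directions[n_up:] = -1.0

    expr = rng.normal(0.0, config.noise_sd, size=(g, n))  # baseline noise
    # signature genes: variance split eQTL / module / noise, on the
    # noise_sd scale, so the eQTL explains eqtl_r2 of the gene's
    # pre-batch variance
    for j, gi in enumerate(sig_idx):
        has_eqtl = j < config.n_eqtl_genes
        v_eqtl = config.eqtl_r2 if has_eqtl else 0.0
        v_mod = config.signature_module_r2 * (1.0 - v_eqtl)
        v_noise = (1.0 - v_eqtl) * (1.0 - config.signature_module_r2)
        core = directions[j] * math.sqrt(v_mod) * module
        if has_eqtl:
            core = core + math.sqrt(v_eqtl) * _standardize(eqtl_dos[j])
        core = core + math.sqrt(v_noise) * rng.normal(size=n)
        expr[gi] = config.noise_sd * core
    expr = expr + batch_offsets[batch].T

    # --- latent response --------------------------------------------
    sig_score = (directions[None, :] @ expr[sig_idx]).ravel()
    snp_score = (
        gwas_dos.sum(axis=0) if config.n_gwas_snps > 0 else np.zeros(n)
    )
    r2e, r2s, r2a = config.trait_r2_expression, config.trait_r2_snps, config._age_r2()
    comps: list[np.ndarray] = []
    weights: list[float] = []
    if r2e > 0:
        comps.append(sig_score)
        weights.append(math.sqrt(r2e))
    if r2s > 0 and config.n_gwas_snps > 0:
        comps.append(snp_score)
        weights.append(math.sqrt(r2s))
    if r2a > 0:
        comps.append(age)
        weights.append(math.copysign(math.sqrt(r2a), config.age_effect))
    comps.append(rng.normal(size=n))  # residual
    weights.append(math.sqrt(max(1.0 - r2e - r2s - r2a, 0.0)))
    ortho = _orthonormalize(comps)
    latent_std = sum(w * u for w, u in zip(weights, ortho))
    latent = config.response_mean + config.response_sd * latent_std

    # --- LDLC visit values ------------------------------------------
    baseline_sigma = math.sqrt(math.log1p(config.baseline_ldlc_cv**2))
    log_base = math.log(config.baseline_ldlc_mean) - baseline_sigma**2 / 2
    baseline = np.exp(rng.normal(log_base, baseline_sigma, size=n))
    visit_noise = np.exp(rng.normal(0.0, config.visit_cv, size=(4, n)))
    pre1, pre2 = baseline * visit_noise[0], baseline * visit_noise[1]
    post = baseline * np.exp(latent)
    post1, post2 = post * visit_noise[2], post * visit_noise[3]

    phenotypes = [
        PhenotypeRecord(
            sample_id=samples[i],
            ldlc_pre=(float(pre1[i]), float(pre2[i])),
            ldlc_post=(float(post1[i]), float(post2[i])),
            age=float(age[i]),
            sex=str(sex[i]),
            bmi=float(bmi[i]),
            smoker=bool(smoker[i]),
        )
        for i in range(n)
    ]

    component_names = []
    if r2e > 0:
        component_names.append("expression")
    if r2s > 0 and config.n_gwas_snps > 0:
        component_names.append("snps")
    if r2a > 0:
        component_names.append("age")
    component_names.append("residual")
    truth = {
        "signature_genes": sig_genes,
        "signature_directions": {
            gid: ("up_in_high" if d > 0 else "up_in_low")
            for gid, d in zip(sig_genes, directions)
        },
        "eqtl_pairs": [
            {
                "gene": eqtl_genes[j],
                "snp": eqtl_snps[j],
                "r2": config.eqtl_r2,
                "effect": math.sqrt(config.eqtl_r2) * config.noise_sd,
            }
            for j in range(config.n_eqtl_genes)
        ],
        "gwas_snps": list(gwas_snps),
        "mafs": dict(zip(eqtl_snps + gwas_snps, mafs.tolist())),
        "variance_fractions": {
            "expression": r2e,
            "snps": r2s if config.n_gwas_snps > 0 else 0.0,
            "age": r2a,
        },
        "latent_response": dict(zip(samples, latent.tolist())),
        "component_scores": {
            name: dict(zip(samples, u.tolist()))
            for name, u in zip(component_names, ortho)
        },
        "batch": dict(zip(samples, (b + 1 for b in batch.tolist()))),
        "config": asdict(config),
    }

    expression = ExpressionMatrix(genes=genes, samples=samples, values=expr, state="raw")
    return SimCohort(expression=expression, genotypes=genotypes, phenotypes=phenotypes, truth=truth)


def batch_table(cohort: SimCohort) -> pd.DataFrame:
    """Batch covariate table (indexed by sample) for normalization."""
    b = cohort.truth["batch"]
    return pd.DataFrame({"batch": [f"B{b[s]}" for s in cohort.expression.samples]},
                        index=cohort.expression.samples)


def eqtl_table(cohort: SimCohort) -> pd.DataFrame:
    """Gene-SNP association table computed from the simulated data.

    P-values come from per-pair simple linear regression of expression
    on dosage, so the table behaves like a real eQTL catalogue (true
    pairs tiny p, strength scaling with ``eqtl_r2``).
    """
    from scipy import stats

    expr = cohort.expression.to_frame()
    rows = []
    for pair in cohort.truth["eqtl_pairs"]:
        gene, snp = pair["gene"], pair["snp"]
        x = cohort.genotypes.to_frame().loc[snp].to_numpy()
        y = expr.loc[gene].to_numpy()
        if np.ptp(x) == 0:
            p = 1.0
        else:
            p = float(stats.linregress(x, y).pvalue)
        rows.append({"gene": gene, "snp": snp, "p_value": max(p, 1e-300), "source": "synthetic"})
    return pd.DataFrame(rows, columns=["gene", "snp", "p_value", "source"])


def gwas_table(cohort: SimCohort) -> pd.DataFrame:
    return pd.DataFrame(
        {"snp": cohort.truth["gwas_snps"],
         "annotation": ["trait_associated"] * len(cohort.truth["gwas_snps"])}
    )


def write_cohort(cohort: SimCohort, directory: str | Path, vcf: bool = False) -> dict[str, Path]:
    """Write the cohort as plain-text files; round-trips losslessly.

    Emits expression TSV, genotype TSV (optionally also VCF 4.2 with a
    DS FORMAT field), phenotype TSV, eQTL and GWAS tables, and a JSON
    truth manifest.
    """
    from . import io as sio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "genotypes": directory / "genotypes.tsv",
        "phenotypes": directory / "phenotypes.tsv",
        "eqtl": directory / "eqtl.tsv",
        "gwas": directory / "gwas.tsv",
        "truth": directory / "truth.json",
        "batches": directory / "batches.tsv",
    }
    sio.write_expression(cohort.expression, paths["expression"])
    sio.write_genotypes(cohort.genotypes, paths["genotypes"])
    sio.write_phenotypes(cohort.phenotypes, paths["phenotypes"])
    eqtl_table(cohort).to_csv(paths["eqtl"], sep="\t", index=False)
    gwas_table(cohort).to_csv(paths["gwas"], sep="\t", index=False)
    batch_table(cohort).rename_axis("sample_id").to_csv(paths["batches"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if vcf:
        paths["vcf"] = directory / "genotypes.vcf"
        sio.write_vcf(cohort.genotypes, paths["vcf"])
    return paths


__all__ = [
    "SimConfig",
    "SimCohort",
    "simulate_cohort",
    "write_cohort",
    "batch_table",
    "eqtl_table",
    "gwas_table",
]
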