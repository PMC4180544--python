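"""End-to-end pipeline orchestration.

Runs preprocess -> tail selection -> signature discovery -> feature
assembly -> prediction on files conforming to the package's formats,
writing each stage's outputs plus a deterministic JSON manifest
(parameters, seeds, input checksums, output checksums) from which a run
can be reproduced bit for bit. Wall-clock timings go to a separate log
file so the manifest itself is reproducible.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import io as sio
from . import nmf, predict, preprocess, signature
from .datatypes import records_to_frame


@dataclass
class PipelineConfig:
    """All stage parameters with full-analysis defaults.

    (2,000 preselected genes; 500 NMF runs and 500 random baseline
    sets; purity cutoff 0.9; N grid 20..80; 1,000 permutations; top 100
    genes; eQTL p < 5e-8; 1,000 CV repeats of 90/10 holdout; tail
    fractions from 10% in 5% steps.)
    """

    # inputs
    expression: str = ""
    phenotypes: str = ""
    genotypes: str = ""
    eqtl: str = ""
    gwas: str = ""
    batches: str = ""  # optional sample x covariate table for normalization
    out_dir: str = "statresp_run"
    # preprocess
    covariates: tuple[str, ...] = ("age", "sex", "bmi")
    alpha: float = 0.05
    exclude_smokers: bool = True
    # tail selection
    n_grid: tuple[int, int, int] = (20, 80, 2)  # start, stop (inclusive), step
    preselect: int = 2000
    nmf_runs: int = 500
    random_sets: int = 500
    nmf_runs_random: int | None = None
    purity_cutoff: float = 0.9
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    # signature
    n_perm: int = 1000
    signature_size: int = 100
    pooling: str = "pooled"
    # features
    eqtl_p: float = 5e-8
    # prediction
    cv_repeats: int = 1000
    holdout_fraction: float = 0.1
    fractions: tuple[float, float, float] = (0.10, 1.00, 0.05)
    models: tuple[str, ...] = ("SG", "eqtl_only", "substitution", "SG_plus_eqtl", "all")
    seed: int = 0

    def validate(self) -> None:
        for name in ("expression", "phenotypes", "genotypes", "eqtl", "gwas"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ValueError(f"input {name!r} missing or not found: {p!r}")
        if self.signature_size < 1:
            raise ValueError("signature_size must be >= 1")
        if self.preselect < 1 or self.nmf_runs < 1 or self.n_perm < 1 or self.cv_repeats < 1:
            raise ValueError("stage sizes must be positive")
        start, stop, step = self.n_grid
        if step <= 0 or start > stop or start % 2 or step % 2:
            raise ValueError("n_grid must be even start/step with start <= stop")
        if not 0 < self.purity_cutoff <= 1:
            raise ValueError("purity_cutoff must lie in (0, 1]")

    @property
    def n_grid_list(self) -> list[int]:
        start, stop, step = self.n_grid
        return list(range(start, stop + 1, step))

    @property
    def fraction_list(self) -> list[float]:
        start, stop, step = self.fractions
        out = []
        f = start
        while f <= stop + 1e-9:
            out.append(round(f, 4))
            f += step
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("n_grid", "fractions", "covariates", "models"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    seed_tails = int(seeds[0].generate_state(1)[0] % 2**31)
    seed_sig = int(seeds[1].generate_state(1)[0] % 2**31)
    seed_cv = int(seeds[2].generate_state(1)[0] % 2**31)
    manifest: dict = {
        "package": "statresp",
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
        "seeds": {"master": config.seed, "tails": seed_tails,
                  "signature": seed_sig, "cv": seed_cv},
        "inputs": {
            name: {"path": str(getattr(config, name)), "sha256": _sha256(Path(getattr(config, name)))}
            for name in ("expression", "phenotypes", "genotypes", "eqtl", "gwas")
            if getattr(config, name)
        },
        "stages": [],
    }
    timings = []

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                outputs = fn()
            except Exception as exc:  # annotate failures with the stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            dt = time.perf_counter() - t0
            timings.append((name, dt))
            manifest["stages"].append(
                {"name": name,
                 "outputs": {key: {"path": str(p), "sha256": _sha256(Path(p))}
                             for key, p in outputs.items()}}
            )
            return outputs

        return deco

    # ---- stage 1: preprocess ---------------------------------------
    records = sio.read_phenotypes(config.phenotypes)
    expr_raw = sio.read_expression(config.expression, state="raw")
    batches = (
        pd.read_csv(config.batches, sep="\t", index_col=0).astype(str)
        if config.batches
        else None
    )

    holder = {}

    @stage("preprocess")
    def _preprocess():
        recs = preprocess.exclude_smokers(records) if config.exclude_smokers else list(records)
        recs = [r for r in recs if r.sample_id in set(expr_raw.samples)]
        recs = preprocess.add_log_change(recs)
        kept, recs = preprocess.screen_and_adjust_covariates(
            recs, config.covariates, config.alpha
        )
        sample_ids = [r.sample_id for r in recs]
        expr = preprocess.normalize_expression(
            expr_raw.subset_samples(sample_ids),
            batches.loc[sample_ids] if batches is not None else None,
        )
        holder["records"] = recs
        holder["kept"] = kept
        holder["expr"] = expr
        p1 = out / "phenotypes_adjusted.tsv"
        records_to_frame(recs).to_csv(p1, sep="\t", index=False)
        p2 = out / "expression_normalized.tsv"
        sio.write_expression(expr, p2)
        p3 = out / "covariates_kept.json"
        with open(p3, "w") as fh:
            json.dump({"kept": kept, "alpha": config.alpha}, fh, indent=1)
            fh.write("\n")
        return {"phenotypes_adjusted": p1, "expression_normalized": p2, "covariates": p3}

    # ---- stage 2: tail selection -----------------------------------
    @stage("select_tails")
    def _tails():
        responses = pd.Series(
            {r.sample_id: r.adjusted_change for r in holder["records"]}
        )
        sel = nmf.select_tail_subset(
            holder["expr"],
            responses,
            N_grid=config.n_grid_list,
            n_genes_preselect=config.preselect,
            n_runs=config.nmf_runs,
            n_random_sets=config.random_sets,
            n_runs_random=config.nmf_runs_random,
            purity_cutoff=config.purity_cutoff,
            max_iter=config.nmf_max_iter,
            tol=config.nmf_tol,
            seed=seed_tails,
        )
        holder["selection"] = sel
        holder["responses"] = responses
        p1 = out / "purity_curve.tsv"
        sel.curve.to_csv(p1, sep="\t", index=False)
        p2 = out / "selected_samples.json"
        with open(p2, "w") as fh:
            json.dump(
                {"chosen_N": sel.chosen_N, "met_cutoff": sel.met_cutoff,
                 "high": sel.high_ids, "low": sel.low_ids},
                fh, indent=1,
            )
            fh.write("\n")
        return {"purity_curve": p1, "selected_samples": p2}

    # ---- stage 3: signature ----------------------------------------
    @stage("signature")
    def _signature():
        sel = holder["selection"]
        expr = holder["expr"]
        high = expr.subset_samples(sel.high_ids).values
        low = expr.subset_samples(sel.low_ids).values
        base = signature.relative_difference(high, low, 0.0, genes=expr.genes)
        schedule = signature.fit_s0_schedule(base["s"].to_numpy(), base["d"].to_numpy())
        stats_frame = signature.permutation_pvalues(
            high, low, schedule, n_perm=config.n_perm, seed=seed_sig,
            pooling=config.pooling, genes=expr.genes,
        )
        genes, ranked = signature.select_signature(stats_frame, config.signature_size)
        holder["signature"] = genes
        holder["ranked"] = ranked
        p1 = out / "signature_table.tsv"
        ranked.to_csv(p1, sep="\t", index=False)
        p2 = out / "signature_genes.txt"
        p2.write_text("\n".join(genes) + "\n")
        return {"signature_table": p1, "signature_genes": p2}

    # ---- stage 4: feature assembly ---------------------------------
    @stage("assemble")
    def _assemble():
        genotypes = sio.read_genotypes(config.genotypes)
        eqtls = sio.read_eqtl_table(config.eqtl)
        gwas = sio.read_gwas_snps(config.gwas)
        eqtl_map = feat.select_best_eqtls(eqtls, holder["signature"], config.eqtl_p)
        specs = feat.canned_specs(holder["signature"], eqtl_map, list(gwas["snp"]))
        sample_ids = [r.sample_id for r in holder["records"]]
        holder["matrices"] = {
            name: feat.assemble_features(specs[name], holder["expr"], genotypes, sample_ids)
            for name in config.models
            if name in specs and specs[name].components
        }
        p1 = out / "eqtl_map.json"
        with open(p1, "w") as fh:
            json.dump(eqtl_map, fh, indent=1, sort_keys=True)
            fh.write("\n")
        outputs = {"eqtl_map": p1}
        for name, mat in holder["matrices"].items():
            p = out / f"features_{name}.tsv"
            mat.rename_axis("sample_id").to_csv(p, sep="\t")
            outputs[f"features_{name}"] = p
        return outputs

    # ---- stage 5: prediction ---------------------------------------
    @stage("predict")
    def _predict():
        responses = holder["responses"]
        scheme = predict.CvScheme(config.cv_repeats, config.holdout_fraction, seed_cv)
        ev_results = []
        sweep_rows = []
        for name, mat in holder["matrices"].items():
            ev = predict.explained_variance(
                mat, responses.loc[mat.index], scheme, model_name=name
            )
            ev_results.append(ev)
            sweep = predict.tail_sweep(
                mat, responses.loc[mat.index], config.fraction_list, scheme, model_name=name
            )
            for r in sweep:
                sweep_rows.append(
                    {"model": name, "fraction": r.tail_fraction,
                     "auc_mean": r.auc, "auc_se": r.auc_se}
                )
        baseline = "SG" if any(r.model == "SG" for r in ev_results) else None
        report = predict.model_comparison_report(ev_results, baseline=baseline)
        p1 = out / "explained_variance.tsv"
        report.to_csv(p1, sep="\t", index=False)
        p2 = out / "auc_curves.tsv"
        pd.DataFrame(sweep_rows).to_csv(p2, sep="\t", index=False)
        return {"explained_variance": p1, "auc_curves": p2}

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w") as fh:
        for name, dt in timings:
            fh.write(f"{name}\t{dt:.2f}s\n")
    return manifest


__all__ = ["PipelineConfig", "run_pipeline"]
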