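"""Orchestration: seeded end-to-end runs with config files and manifests.

Two drivers are provided.  ``run_prioritization`` executes the core
workflow (GWAS summary -> gene Z-scores -> spike-and-slab fit ->
prioritized sets) on simulated or user-supplied inputs.
``run_benchmark`` drives the simulation comparison of the Bayesian fit
against the joint-OLS baseline (top-k true positives and
cross-validated prediction accuracy, with correlated or uncorrelated
extra gene sets).  Every artifact directory carries the JSON config,
its hash, and a manifest with file checksums, so a run is fully
reproducible from seed + config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import baseline as baseline_mod
from .blr_single import GeneSetDesign, SamplerConfig, fit_single, prioritize
from .evaluate import prediction_accuracy, ranking_auc, topk_true_positives
from .genestats import compute_gene_stats
from .simulate import (
    SimulationScenario,
    build_genes_and_sets,
    build_overlapping_sets,
    compute_gene_ld,
    gwas_scan,
    gwas_z,
    simulate_effects,
    simulate_genotypes,
    simulate_phenotype,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_prioritization", "run_benchmark", "simulate_study"]


@dataclasses.dataclass
class RunConfig:
    """Nested stage parameters for a pipeline run, JSON-serializable."""

    seed: int = 0
    out_dir: str = "gsblr_run"
    scenario: dict = dataclasses.field(
        default_factory=lambda: {
            "h2": 0.3,
            "causal_prop": 0.01,
            "architecture": "GA1",
            "trait_type": "quantitative",
            "prevalence": None,
            "n_ind": 2000,
            "n_snp": 2000,
        }
    )
    genes: dict = dataclasses.field(default_factory=lambda: {"snps_per_gene": 10})
    sets: dict = dataclasses.field(
        default_factory=lambda: {
            "set_sizes": [10, 25, 50],
            "causal_counts": [0, 5, 10],
            "n_replicates": 2,
            "n_control_sets": 0,
        }
    )
    overlap: dict = dataclasses.field(
        default_factory=lambda: {"enabled": False, "n_extra": 191, "mode": "correlated"}
    )
    sampler: dict = dataclasses.field(
        default_factory=lambda: {"n_iter": 3000, "burn_in": 500, "pi_prior": 0.001}
    )
    pip_threshold: float = 0.1
    strict: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict):
                merged = dict(getattr(cfg, key))
                merged.update(value)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        return cfg

    @property
    def config_hash(self) -> str:
        # hash the scientific parameters only; where outputs land is not
        # part of run identity
        data = dataclasses.asdict(self)
        data.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(data, sort_keys=True).encode()
        ).hexdigest()[:12]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out: Path, config: RunConfig) -> None:
    # config.json carries out_dir (run identity lives in config_hash)
    files = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name not in ("manifest.json", "config.json")
    )
    manifest = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def simulate_study(config: RunConfig) -> dict:
    """Run the simulation stages of a config and return in-memory artifacts."""
    sc = config.scenario
    scenario = SimulationScenario(
        h2=sc["h2"],
        causal_prop=sc["causal_prop"],
        architecture=sc["architecture"],
        trait_type=sc["trait_type"],
        prevalence=sc.get("prevalence"),
        n_ind=sc["n_ind"],
        n_snp=sc["n_snp"],
        seed=config.seed,
    )
    t0 = time.perf_counter()
    G, meta = simulate_genotypes(scenario.n_ind, scenario.n_snp, seed=config.seed)
    beta, causal_idx = simulate_effects(
        scenario.n_snp, scenario.causal_prop, scenario.architecture, seed=config.seed + 1
    )
    y, _liab = simulate_phenotype(G, beta, scenario)
    folds = gwas_scan(
        G, y, meta, scenario.trait_type, n_folds=5, seed=config.seed + 2
    )
    genes, gene_snps, collection, truth = build_genes_and_sets(
        meta,
        causal_idx,
        set_sizes=tuple(config.sets["set_sizes"]),
        causal_counts=tuple(config.sets["causal_counts"]),
        n_control_sets=config.sets["n_control_sets"],
        n_replicates=config.sets["n_replicates"],
        seed=config.seed + 3,
        snps_per_gene=config.genes["snps_per_gene"],
    )
    if config.overlap.get("enabled"):
        causal_set = set(causal_idx.tolist())
        causal_genes = {
            g.gene_id for g in genes if causal_set & set(gene_snps[g.gene_id].tolist())
        }
        collection, truth = build_overlapping_sets(
            collection,
            truth,
            causal_genes,
            [g.gene_id for g in genes],
            n_extra=config.overlap["n_extra"],
            overlap_mode=config.overlap["mode"],
            seed=config.seed + 4,
        )
    logger.info(
        "stage=simulate seed=%d wall=%.1fs n_sets=%d",
        config.seed, time.perf_counter() - t0, len(collection),
    )
    return {
        "scenario": scenario,
        "genotypes": G,
        "meta": meta,
        "phenotype": y,
        "folds": folds,
        "genes": genes,
        "gene_snps": gene_snps,
        "collection": collection,
        "truth": truth,
        "causal_idx": causal_idx,
    }


def _fold_gene_stats(study: dict, fold: int, strict: bool = False):
    G = study["genotypes"]
    f = study["folds"][fold]
    ld = compute_gene_ld(G[f["train_idx"]], study["meta"], study["gene_snps"])
    gstats = compute_gene_stats(
        f["variants"], study["genes"], ld, up_bp=0, down_bp=0, strict=strict
    )
    return gstats


def run_prioritization(config: RunConfig) -> Path:
    """Core workflow on a simulated study; writes a reproducible artifact dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    study = simulate_study(config)
    t0 = time.perf_counter()
    gstats = _fold_gene_stats(study, fold=0, strict=config.strict)
    gene_ids = [g.gene_id for g in gstats]
    yz = np.array([g.z for g in gstats])
    header = f"# gsblr config_hash={config.config_hash} seed={config.seed}\n"
    gs_path = out / "genestats.tsv"
    with open(gs_path, "w") as fh:
        fh.write(header)
        pd.DataFrame(
            [(g.gene_id, g.chrom, g.start, g.end, g.n_snps, g.T, g.p, g.z) for g in gstats],
            columns=["gene_id", "chrom", "start", "end", "n_snps", "T", "p", "z"],
        ).to_csv(fh, sep="\t", index=False)
    logger.info("stage=genestats wall=%.1fs n_genes=%d", time.perf_counter() - t0, len(gstats))

    t0 = time.perf_counter()
    design = GeneSetDesign.from_collection(gene_ids, study["collection"])
    cfg = SamplerConfig(seed=config.seed + 5, **config.sampler)
    result = fit_single(yz, design, cfg)
    ranked = prioritize(result, pip_threshold=config.pip_threshold)
    logger.info("stage=fit wall=%.1fs n_associated=%d", time.perf_counter() - t0, len(ranked))

    with open(out / "fit.tsv", "w") as fh:
        fh.write(header)
        fh.write(
            f"# pi_mean={result.pi_mean:.6g} sigma_b2_mean={result.sigma_b2_mean:.6g} "
            f"sigma_e2_mean={result.sigma_e2_mean:.6g}\n"
        )
        pd.DataFrame(
            {
                "set_id": result.set_ids,
                "n_genes": design.X.sum(axis=0).astype(int),
                "pip": result.pip,
                "b_mean": result.b_mean,
                "b_sd": result.b_sd,
            }
        ).to_csv(fh, sep="\t", index=False)
    with open(out / "associated.tsv", "w") as fh:
        fh.write(header)
        pd.DataFrame(ranked, columns=["set_id", "pip", "b_mean"]).to_csv(
            fh, sep="\t", index=False
        )
    truth_df = pd.DataFrame(
        [(t.set_id, t.size, t.n_causal, t.is_causal_set) for t in study["truth"]],
        columns=["set_id", "size", "n_causal", "is_causal_set"],
    )
    truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
    _write_manifest(out, config)
    return out


def run_benchmark(config: RunConfig, n_seeds: int = 3) -> dict:
    """Compare the Bayesian fit against the joint-OLS baseline over seeds.

    For each seed: simulate (with extra overlapping sets when enabled),
    compute gene statistics on fold 0's training split, fit both
    methods, and score top-k true positives plus prediction accuracy
    against fold 0's validation-split gene Z-scores.  Returns summary
    tables (means and SDs across seeds).
    """
    rows = []
    for s in range(n_seeds):
        cfg = dataclasses.replace(config, seed=config.seed + 101 * s)
        study = simulate_study(cfg)
        gstats = _fold_gene_stats(study, fold=0)
        gene_ids = [g.gene_id for g in gstats]
        yz = np.array([g.z for g in gstats])
        design = GeneSetDesign.from_collection(gene_ids, study["collection"])
        truth = study["truth"]

        blr = fit_single(yz, design, SamplerConfig(seed=cfg.seed + 5, **cfg.sampler))
        order = np.argsort(-blr.pip)
        blr_rank = [blr.set_ids[i] for i in order]

        gene_nsnp = np.array([g.n_snps for g in gstats], dtype=float)
        gene_len = np.array([max(g.end - g.start + 1, 1) for g in gstats], dtype=float)
        C, cnames = baseline_mod.default_covariates(design, gene_nsnp, gene_len)
        ols = baseline_mod.fit_joint_linear(yz, design, C, cnames)
        ols_rank = baseline_mod.rank_by_pvalue(ols)

        # validation gene Z-scores: GWAS on the held-out 20%, same LD reference
        f0 = study["folds"][0]
        G = study["genotypes"]
        zv = gwas_z(G[f0["validation_idx"]], study["phenotype"][f0["validation_idx"]],
                    study["scenario"].trait_type)
        val_variants = [
            dataclasses.replace(v, z=float(zv[i]), n=len(f0["validation_idx"]))
            for i, v in enumerate(f0["variants"])
        ]
        ld = compute_gene_ld(G[f0["train_idx"]], study["meta"], study["gene_snps"])
        val_stats = compute_gene_stats(val_variants, study["genes"], ld, up_bp=0, down_bp=0)
        val_map = {g.gene_id: g.z for g in val_stats}
        y_val = _expand(val_map, gene_ids)
        acc_blr = prediction_accuracy(blr.b_mean, design, y_val)
        acc_ols = prediction_accuracy(ols.beta, design, y_val)

        truth_by_id = {t.set_id: t.is_causal_set for t in truth}
        auc = ranking_auc(blr.pip, np.array([truth_by_id[s_] for s_ in blr.set_ids]))
        row = {"seed": cfg.seed, "auc_blr": auc, "acc_blr": acc_blr, "acc_ols": acc_ols}
        for k, v in topk_true_positives(blr_rank, truth).items():
            row[f"blr_top{k}"] = v
        for k, v in topk_true_positives(ols_rank, truth).items():
            row[f"ols_top{k}"] = v
        rows.append(row)

    df = pd.DataFrame(rows)
    summary = {"per_seed": df, "mean": df.mean(numeric_only=True), "sd": df.std(numeric_only=True)}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    df.to_csv(out / "benchmark_per_seed.tsv", sep="\t", index=False)
    summary["mean"].to_frame("mean").join(summary["sd"].to_frame("sd")).to_csv(
        out / "benchmark_summary.tsv", sep="\t"
    )
    _write_manifest(out, config)
    return summary


def _expand(val_map: dict, gene_ids: list[str]) -> np.ndarray:
    return np.array([val_map.get(g, 0.0) for g in gene_ids])
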