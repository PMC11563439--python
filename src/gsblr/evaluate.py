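"""Scoring and benchmarking of gene-set prioritization.

Covers the classification metrics (precision / recall / F1 against
simulation truth), top-k true-positive counts for method comparison,
PIP calibration against truth labels (pooled by PIP rank across
replicates, with binomial intervals), cross-validated prediction
accuracy of the fitted gene-set predictor, and the end-to-end
calibration experiment driver (simulate -> gene statistics -> BLR fit,
repeated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .blr_single import BLRResult, GeneSetDesign, SamplerConfig, fit_single
from .simulate import GeneSetTruth

__all__ = [
    "EvaluationResult",
    "CalibrationTable",
    "classification_scores",
    "topk_true_positives",
    "pip_calibration",
    "prediction_accuracy",
    "ranking_auc",
    "run_calibration_experiment",
]


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion counts with precision, recall and F1.

    Empty denominators follow the zero convention: precision is 0 when
    nothing is predicted positive, recall is 0 when nothing is truly
    positive, and F1 is 0 when precision + recall is 0 — so all three
    are always defined.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


@dataclass
class CalibrationTable:
    """Per-rank (or per-bin) calibration of PIPs against truth.

    ``ci_low``/``ci_high`` bound the causal fraction expected if the
    causal indicator were Bernoulli(mean_pip): the central 95% interval
    of Binomial(n, mean_pip) / n.  Well-calibrated PIPs keep the
    observed causal fraction inside this band.
    """

    mean_pip: np.ndarray
    causal_fraction: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: np.ndarray

    def coverage(self) -> float:
        """Fraction of rows whose causal fraction falls inside the interval."""
        ok = (self.causal_fraction >= self.ci_low) & (self.causal_fraction <= self.ci_high)
        return float(np.mean(ok))


def classification_scores(
    predicted_positive: set[str],
    truth: list[GeneSetTruth],
) -> EvaluationResult:
    """Confusion counts of predicted-associated sets against truth labels."""
    universe = {t.set_id for t in truth}
    unknown = set(predicted_positive) - universe
    if unknown:
        raise ValueError(f"predictions outside truth universe: {sorted(unknown)[:5]}")
    tp = fp = fn = tn = 0
    for t in truth:
        pred = t.set_id in predicted_positive
        if t.is_causal_set and pred:
            tp += 1
        elif t.is_causal_set:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    return EvaluationResult(tp, fp, fn, tn)


def topk_true_positives(
    ranking: list[str],
    truth: list[GeneSetTruth],
    k_list: tuple[int, ...] = (10, 20, 50),
) -> dict[int, int]:
    """Number of causal sets among the top k of a ranked list, per k."""
    causal = {t.set_id for t in truth if t.is_causal_set}
    out: dict[int, int] = {}
    for k in k_list:
        kk = min(k, len(ranking))
        out[k] = sum(1 for sid in ranking[:kk] if sid in causal)
    return out


def ranking_auc(pips: np.ndarray, is_causal: np.ndarray) -> float:
    """Probability a causal set outranks a null set (Mann-Whitney AUC)."""
    pips = np.asarray(pips, dtype=float)
    is_causal = np.asarray(is_causal, dtype=bool)
    pos = pips[is_causal]
    neg = pips[~is_causal]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both causal and null sets for AUC")
    u, _ = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    return float(u / (pos.size * neg.size))


def _binomial_interval(n: np.ndarray, p: np.ndarray, level: float = 0.95):
    """Central interval of Binomial(n, p)/n (exact, via the binomial ppf)."""
    a = (1 - level) / 2
    lo = stats.binom.ppf(a, n, p) / n
    hi = stats.binom.ppf(1 - a, n, p) / n
    return lo, hi


def pip_calibration(
    pips: np.ndarray,
    is_causal: np.ndarray,
    mode: str = "rank",
    n_bins: int = 10,
) -> CalibrationTable:
    """Calibration of PIPs against causal labels.

    Rank mode expects stacked replicates — ``pips`` and ``is_causal``
    of shape (n_replicates, n_sets) — orders each replicate by PIP and
    pools across replicates at each rank.  Bin mode pools flat vectors
    into PIP deciles.
    """
    pips = np.asarray(pips, dtype=float)
    is_causal = np.asarray(is_causal, dtype=bool)
    if mode == "rank":
        if pips.ndim != 2 or pips.shape[0] < 2:
            raise ValueError("rank mode needs >= 2 replicates (2-D input)")
        order = np.argsort(-pips, axis=1)
        sorted_pips = np.take_along_axis(pips, order, axis=1)
        sorted_causal = np.take_along_axis(is_causal, order, axis=1)
        mean_pip = sorted_pips.mean(axis=0)
        frac = sorted_causal.mean(axis=0)
        n = np.full(mean_pip.size, pips.shape[0])
    elif mode == "bin":
        flat_p = pips.ravel()
        flat_c = is_causal.ravel()
        edges = np.quantile(flat_p, np.linspace(0, 1, n_bins + 1))
        edges[0] -= 1e-12
        which = np.clip(np.searchsorted(edges, flat_p, side="right") - 1, 0, n_bins - 1)
        mean_pip, frac, n = [], [], []
        for b in range(n_bins):
            mask = which == b
            if not mask.any():
                continue
            mean_pip.append(flat_p[mask].mean())
            frac.append(flat_c[mask].mean())
            n.append(int(mask.sum()))
        mean_pip, frac, n = map(np.asarray, (mean_pip, frac, n))
    else:
        raise ValueError("mode must be 'rank' or 'bin'")
    lo, hi = _binomial_interval(n, np.clip(mean_pip, 0.0, 1.0))
    return CalibrationTable(mean_pip, frac, lo, hi, n)


def prediction_accuracy(
    b_mean: np.ndarray,
    design: GeneSetDesign,
    y_validation: np.ndarray,
    gene_subset: np.ndarray | None = None,
) -> float:
    """Pearson correlation of the gene-level predictor X b with validation Z-scores.

    ``b_mean`` is the posterior mean (BLR) or OLS coefficient vector
    (baseline); aliased NaN coefficients count as zero.  A
    zero-variance predictor yields accuracy 0 by convention.
    """
    b = np.nan_to_num(np.asarray(b_mean, dtype=float))
    yhat = design.X @ b
    y_val = np.asarray(y_validation, dtype=float)
    if gene_subset is not None:
        yhat = yhat[gene_subset]
        y_val = y_val[gene_subset]
    if np.std(yhat) == 0 or np.std(y_val) == 0:
        return 0.0
    return float(np.corrcoef(yhat, y_val)[0, 1])


def run_calibration_experiment(
    set_sizes: tuple[int, ...] = (20, 50, 100, 150),
    causal_frac_range: tuple[float, float] = (0.05, 0.5),
    n_causal_sets_per_size: int = 1,
    n_control: int = 198,
    n_repeats: int = 50,
    seed: int = 0,
    n_ind: int = 1000,
    n_snp: int = 4000,
    snps_per_gene: int = 5,
    h2: float = 0.3,
    causal_prop: float = 0.01,
    sampler: SamplerConfig | None = None,
) -> tuple[CalibrationTable, np.ndarray, np.ndarray]:
    """Repeated simulate -> gene statistics -> BLR fit, pooled by PIP rank.

    Each repeat simulates a quantitative trait, builds causal gene sets
    of the requested sizes with a causal-gene fraction drawn uniformly
    from ``causal_frac_range`` plus ``n_control`` non-causal sets, fits
    the single-trait model, and records PIPs with truth labels.
    Returns the rank-mode calibration table plus the raw (n_repeats x
    n_sets) PIP and truth matrices.
    """
    from .genestats import compute_gene_stats
    from .simulate import (
        SimulationScenario,
        build_genes_and_sets,
        compute_gene_ld,
        simulate_effects,
        simulate_genotypes,
        simulate_phenotype,
        gwas_scan,
    )

    all_pips, all_truth = [], []
    for rep in range(n_repeats):
        rep_seed = seed + 1000 * rep
        rng = np.random.default_rng(rep_seed)
        scenario = SimulationScenario(
            h2=h2, causal_prop=causal_prop, architecture="GA1",
            trait_type="quantitative", n_ind=n_ind, n_snp=n_snp, seed=rep_seed,
        )
        G, meta = simulate_genotypes(n_ind, n_snp, seed=rep_seed)
        beta, causal_idx = simulate_effects(n_snp, causal_prop, "GA1", seed=rep_seed + 1)
        y_pheno, _ = simulate_phenotype(G, beta, scenario)
        folds = gwas_scan(G, y_pheno, meta, "quantitative", n_folds=5, seed=rep_seed + 2)
        variants = folds[0]["variants"]

        sizes, counts = [], []
        for size in set_sizes:
            for _ in range(n_causal_sets_per_size):
                frac = rng.uniform(*causal_frac_range)
                sizes.append(size)
                counts.append(max(1, int(round(frac * size))))
        genes, gene_snps, collection, truth = _build_explicit_sets(
            meta, causal_idx, list(zip(sizes, counts)), n_control, rep_seed + 3,
            snps_per_gene,
        )
        ld = compute_gene_ld(G[folds[0]["train_idx"]], meta, gene_snps)
        gstats = compute_gene_stats(variants, genes, ld, up_bp=0, down_bp=0)
        gene_ids = [g.gene_id for g in gstats]
        yz = np.array([g.z for g in gstats])
        design = GeneSetDesign.from_collection(gene_ids, collection)
        cfg = sampler if sampler is not None else SamplerConfig(seed=rep_seed + 4)
        import dataclasses

        cfg = dataclasses.replace(cfg, seed=rep_seed + 4)
        res = fit_single(yz, design, cfg)
        truth_by_id = {t.set_id: t.is_causal_set for t in truth}
        all_pips.append(res.pip)
        all_truth.append([truth_by_id[s] for s in res.set_ids])

    pips = np.asarray(all_pips)
    labels = np.asarray(all_truth, dtype=bool)
    table = pip_calibration(pips, labels, mode="rank")
    return table, pips, labels


def _build_explicit_sets(meta, causal_idx, size_count_pairs, n_control, seed, snps_per_gene):
    """Genes plus one set per explicit (size, n_causal) pair plus controls."""
    from .io import GeneSetCollection
    from .simulate import build_gene_map

    genes, gene_snps = build_gene_map(meta, snps_per_gene)
    causal_set = set(causal_idx.tolist())
    causal_genes = [g.gene_id for g in genes if causal_set & set(gene_snps[g.gene_id].tolist())]
    noncausal = [g.gene_id for g in genes if g.gene_id not in set(causal_genes)]
    rng = np.random.default_rng(seed)

    sets, truth = [], []
    for i, (size, n_causal) in enumerate(size_count_pairs):
        n_causal = min(n_causal, len(causal_genes), size)
        chosen = list(rng.choice(causal_genes, n_causal, replace=False)) + list(
            rng.choice(noncausal, size - n_causal, replace=False)
        )
        sets.append((f"causal{i}", f"size={size}", [str(g) for g in chosen]))
        truth.append(GeneSetTruth(f"causal{i}", size, n_causal))
    sizes = [sc[0] for sc in size_count_pairs]
    for i in range(n_control):
        size = int(rng.choice(sizes))
        chosen = rng.choice(noncausal, size, replace=False)
        sets.append((f"control{i}", f"size={size}", [str(g) for g in chosen]))
        truth.append(GeneSetTruth(f"control{i}", size, 0))
    return genes, gene_snps, GeneSetCollection(sets), truth
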