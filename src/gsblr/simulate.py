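"""Synthetic GWAS data generator mirroring the simulation design of the method.

The generator produces everything the rest of the package consumes,
end-to-end and fully seeded:

genotypes -> phenotypes -> single-marker GWAS z-scores -> genes
(aligned to LD blocks) -> gene sets with truth labels -> per-gene LD
matrices.

Genotypes are 0/1/2 dosages obtained by thresholding a latent Gaussian
with AR(1) correlation (``ld_rho``) within blocks of ``ld_block_size``
SNPs at Hardy-Weinberg genotype frequencies; blocks are independent, so
genes tiled along blocks show realistic within-gene LD and no LD
leakage between distant genes.  Phenotypes follow the standard additive
model on column-standardized dosages with residual variance set so the
realized heritability matches the target h^2; binary traits threshold
the liability at the empirical (1 - prevalence) quantile, giving the
exact case fraction.  Two genetic architectures are supported: GA1
(causal effects from a single normal) and GA2 (a three-component
normal scale mixture, i.e. heavy-tailed effects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneRecord, GeneSetCollection, LDMatrix, VariantStat

__all__ = [
    "SimulationScenario",
    "GeneSetTruth",
    "scenario_grid",
    "scenario_by_name",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotype",
    "gwas_scan",
    "build_gene_map",
    "build_genes_and_sets",
    "build_overlapping_sets",
    "compute_gene_ld",
    "MemoryLDSource",
]

GA2_VARIANCES = (1.0, 0.1, 0.01)
GA2_WEIGHTS = (0.1, 0.2, 0.7)


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulated-phenotype design.

    h2 in {0.1, 0.3}, causal proportion pi in {0.01, 0.001},
    architecture GA1/GA2, and for binary traits a prevalence in
    {0.05, 0.15} — the full grid is 8 quantitative and 16 binary
    scenarios (see :func:`scenario_grid`).
    """

    h2: float
    causal_prop: float
    architecture: str  # GA1 | GA2
    trait_type: str  # quantitative | binary
    prevalence: float | None = None
    n_ind: int = 2000
    n_snp: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.h2 < 1):
            raise ValueError("h2 must lie in (0, 1)")
        if not (0 < self.causal_prop < 1):
            raise ValueError("causal_prop must lie in (0, 1)")
        if self.architecture not in ("GA1", "GA2"):
            raise ValueError("architecture must be GA1 or GA2")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError("trait_type must be quantitative or binary")
        if self.trait_type == "binary":
            if self.prevalence is None or not (0 < self.prevalence < 1):
                raise ValueError("binary traits require prevalence in (0, 1)")
        elif self.prevalence is not None:
            raise ValueError("prevalence only applies to binary traits")


@dataclass(frozen=True)
class GeneSetTruth:
    """Truth label for a simulated gene set."""

    set_id: str
    size: int
    n_causal: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_causal <= self.size):
            raise ValueError("need 0 <= n_causal <= size")

    @property
    def is_causal_set(self) -> bool:
        return self.n_causal > 0


def scenario_grid(n_ind: int = 2000, n_snp: int = 2000, seed: int = 0) -> list[SimulationScenario]:
    """The full simulated-phenotype grid: 8 quantitative + 16 binary scenarios."""
    out = []
    for h2 in (0.3, 0.1):
        for pi in (0.001, 0.01):
            for ga in ("GA1", "GA2"):
                out.append(
                    SimulationScenario(h2, pi, ga, "quantitative", None, n_ind, n_snp, seed)
                )
                for prev in (0.05, 0.15):
                    out.append(
                        SimulationScenario(h2, pi, ga, "binary", prev, n_ind, n_snp, seed)
                    )
    return out


def scenario_by_name(
    name: str, n_ind: int = 2000, n_snp: int = 2000, seed: int = 0
) -> SimulationScenario:
    """Look up a named grid cell: Sim1-Sim8 (quantitative), sim1-sim16 (binary)."""
    grid = scenario_grid(n_ind=n_ind, n_snp=n_snp, seed=seed)
    quant = [s for s in grid if s.trait_type == "quantitative"]
    binary = [s for s in grid if s.trait_type == "binary"]
    if name.startswith("Sim"):
        idx = int(name[3:]) - 1
        if not (0 <= idx < len(quant)):
            raise ValueError(f"unknown quantitative scenario {name!r} (Sim1..Sim8)")
        return quant[idx]
    if name.startswith("sim"):
        idx = int(name[3:]) - 1
        if not (0 <= idx < len(binary)):
            raise ValueError(f"unknown binary scenario {name!r} (sim1..sim16)")
        return binary[idx]
    raise ValueError(f"scenario name {name!r} must look like Sim3 or sim11")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_ind: int,
    n_snp: int,
    maf_low: float = 0.01,
    maf_high: float = 0.5,
    ld_block_size: int = 50,
    ld_rho: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Block-AR(1) latent-Gaussian genotypes thresholded at HWE frequencies.

    Returns an (n_ind x n_snp) int8 dosage matrix and a variant
    metadata frame with columns variant_id, chrom, pos, maf, block.
    Positions lie on a synthetic 1-based map (1 kb spacing) so genes
    tiled over blocks align with LD structure.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if ld_block_size < 1 or not (0 <= ld_rho < 1):
        raise ValueError("bad LD block parameters")
    rng = np.random.default_rng(seed)

    maf = rng.uniform(maf_low, maf_high, size=n_snp)
    # HWE genotype frequencies for minor-allele dosage 0/1/2
    p0 = (1 - maf) ** 2
    p2 = maf**2
    # latent u ~ N(0,1); dosage 2 if u > c2, 1 if u > c1
    c2 = stats.norm.isf(p2)
    c1 = stats.norm.isf(p2 + 1 - p0 - p2)  # = isf(1 - p0)

    G = np.empty((n_ind, n_snp), dtype=np.int8)
    sq = np.sqrt(1.0 - ld_rho**2)
    for start in range(0, n_snp, ld_block_size):
        stop = min(start + ld_block_size, n_snp)
        width = stop - start
        U = np.empty((n_ind, width))
        U[:, 0] = rng.standard_normal(n_ind)
        for k in range(1, width):
            U[:, k] = ld_rho * U[:, k - 1] + sq * rng.standard_normal(n_ind)
        block = (U > c1[start:stop]).astype(np.int8) + (U > c2[start:stop]).astype(np.int8)
        G[:, start:stop] = block

    meta = pd.DataFrame(
        {
            "variant_id": [f"snp{i}" for i in range(n_snp)],
            "chrom": "1",
            "pos": 1 + 1000 * np.arange(n_snp),
            "maf": maf,
            "block": np.arange(n_snp) // ld_block_size,
        }
    )
    return G, meta


# ---------------------------------------------------------------------------
# Effects and phenotypes
# ---------------------------------------------------------------------------

def simulate_effects(
    n_snp: int,
    causal_prop: float,
    architecture: str = "GA1",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP effect vector and causal index set.

    Each SNP is causal independently with probability ``causal_prop``.
    GA1 draws effects from N(0, 1); GA2 from a three-component normal
    mixture with variances (1, 0.1, 0.01) and weights (0.1, 0.2, 0.7).
    Effects are on the standardized-genotype scale and are rescaled by
    :func:`simulate_phenotype` to hit the target heritability.
    """
    if architecture not in ("GA1", "GA2"):
        raise ValueError("architecture must be GA1 or GA2")
    rng = np.random.default_rng(seed)
    causal = np.flatnonzero(rng.random(n_snp) < causal_prop)
    if causal.size == 0:
        causal = np.flatnonzero(rng.random(n_snp) < causal_prop)
    if causal.size == 0:
        raise RuntimeError("no causal SNPs sampled after one resample; raise causal_prop")
    beta = np.zeros(n_snp)
    if architecture == "GA1":
        beta[causal] = rng.standard_normal(causal.size)
    else:
        comp = rng.choice(3, size=causal.size, p=GA2_WEIGHTS)
        sd = np.sqrt(np.array(GA2_VARIANCES))[comp]
        beta[causal] = rng.standard_normal(causal.size) * sd
    return beta, causal


def _standardize(G: np.ndarray) -> np.ndarray:
    Gs = G.astype(float)
    Gs -= Gs.mean(axis=0)
    sd = Gs.std(axis=0)
    sd[sd == 0] = 1.0
    return Gs / sd


def simulate_phenotype(
    genotypes: np.ndarray,
    effects: np.ndarray,
    scenario: SimulationScenario,
) -> tuple[np.ndarray, np.ndarray]:
    """Additive phenotype with target heritability; liability threshold for binary.

    Returns (phenotype, liability).  For quantitative traits the two are
    identical.  For binary traits an individual is a case when its
    liability exceeds the empirical (1 - prevalence) quantile, so the
    case fraction equals the prevalence exactly.
    """
    if genotypes.shape[1] != effects.size:
        raise ValueError("genotypes and effects disagree on SNP count")
    g = _standardize(genotypes) @ effects
    var_g = float(np.var(g))
    if var_g == 0:
        raise ValueError("degenerate genetic values (no causal variance)")
    rng = np.random.default_rng(scenario.seed + 7_001)
    e = rng.standard_normal(g.size) * np.sqrt(var_g * (1 - scenario.h2) / scenario.h2)
    liability = g + e
    if scenario.trait_type == "quantitative":
        return liability, liability
    cut = np.quantile(liability, 1 - scenario.prevalence)
    y = (liability > cut).astype(float)
    return y, liability


# ---------------------------------------------------------------------------
# Single-marker GWAS with cross-validation folds
# ---------------------------------------------------------------------------

def _linear_gwas_z(G: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized per-SNP simple-regression z = beta_hat / se."""
    n = y.size
    Gc = G.astype(float) - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    sxy = Gc.T @ yc
    syy = float(yc @ yc)
    mono = sxx == 0
    sxx_safe = np.where(mono, 1.0, sxx)
    r2 = np.clip(sxy**2 / (sxx_safe * syy), 0.0, 1.0 - 1e-12)
    z = np.sign(sxy) * np.sqrt(r2 * (n - 2) / (1.0 - r2))
    z[mono] = 0.0
    return z


def _logistic_gwas_z(G: np.ndarray, y: np.ndarray, max_iter: int = 30) -> np.ndarray:
    """Vectorized per-SNP logistic Wald z via 2-parameter Newton iterations.

    SNPs whose Newton iteration fails to converge (e.g. quasi-complete
    separation) fall back to the score-test z under the intercept-only
    null, which is well defined there.
    """
    n, p = G.shape
    x = G.astype(float)
    ybar = y.mean()
    a = np.full(p, np.log(ybar / (1 - ybar)))
    b = np.zeros(p)
    ok = np.ones(p, dtype=bool)
    for _ in range(max_iter):
        eta = a + x * b
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1 - mu)
        ga = (y[:, None] - mu).sum(axis=0)
        gb = np.einsum("ij,ij->j", x, y[:, None] - mu)
        Haa = w.sum(axis=0)
        Hab = np.einsum("ij,ij->j", x, w)
        Hbb = np.einsum("ij,ij->j", x * x, w)
        det = Haa * Hbb - Hab**2
        bad = det <= 1e-10
        det_safe = np.where(bad, 1.0, det)
        da = (Hbb * ga - Hab * gb) / det_safe
        db = (Haa * gb - Hab * ga) / det_safe
        da[bad] = 0.0
        db[bad] = 0.0
        step = np.maximum(np.abs(da), np.abs(db))
        scale = np.where(step > 5.0, 5.0 / np.maximum(step, 1e-300), 1.0)
        a += da * scale
        b += db * scale
        ok &= ~bad
        if np.all(np.maximum(np.abs(da), np.abs(db)) < 1e-8):
            break
    converged = ok & (np.maximum(np.abs(da), np.abs(db)) < 1e-4) & (np.abs(b) < 30)

    eta = a + x * b
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = mu * (1 - mu)
    Haa = w.sum(axis=0)
    Hab = np.einsum("ij,ij->j", x, w)
    Hbb = np.einsum("ij,ij->j", x * x, w)
    det = Haa * Hbb - Hab**2
    se_b = np.sqrt(np.where(det > 0, Haa / np.where(det > 0, det, 1.0), np.inf))
    z = np.where(converged & np.isfinite(se_b) & (se_b > 0), b / se_b, 0.0)

    # score-test fallback for non-converged SNPs
    fb = ~converged
    if np.any(fb):
        xc = x[:, fb] - x[:, fb].mean(axis=0)
        U = xc.T @ (y - ybar)
        V = ybar * (1 - ybar) * np.einsum("ij,ij->j", xc, xc)
        zf = np.where(V > 0, U / np.sqrt(np.where(V > 0, V, 1.0)), 0.0)
        z[fb] = zf
    mono = x.std(axis=0) == 0
    z[mono] = 0.0
    return z


def gwas_z(genotypes: np.ndarray, phenotype: np.ndarray, trait_type: str) -> np.ndarray:
    """Per-SNP single-marker z-scores on one sample (no CV splitting)."""
    if trait_type == "quantitative":
        return _linear_gwas_z(genotypes, phenotype)
    if trait_type == "binary":
        return _logistic_gwas_z(genotypes, phenotype)
    raise ValueError("trait_type must be quantitative or binary")


def gwas_scan(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    variant_meta: pd.DataFrame,
    trait_type: str = "quantitative",
    cv_split: tuple[float, float] = (0.8, 0.2),
    n_folds: int = 5,
    seed: int = 0,
) -> list[dict]:
    """Per-fold single-marker GWAS on the training 80% of each CV replicate.

    Each of the ``n_folds`` replicates holds out a disjoint 20%
    validation slice (folds partition the individuals).  Returns one
    dict per fold with keys ``variants`` (list of VariantStat computed
    on the training portion), ``train_idx`` and ``validation_idx``.
    """
    if abs(sum(cv_split) - 1.0) > 1e-9:
        raise ValueError("cv_split must sum to 1")
    n = genotypes.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    out = []
    for f in range(n_folds):
        val_idx = np.sort(folds[f])
        train_idx = np.sort(np.concatenate([folds[g] for g in range(n_folds) if g != f]))
        Gt = genotypes[train_idx]
        yt = phenotype[train_idx]
        if trait_type == "quantitative":
            z = _linear_gwas_z(Gt, yt)
        elif trait_type == "binary":
            z = _logistic_gwas_z(Gt, yt)
        else:
            raise ValueError("trait_type must be quantitative or binary")
        variants = [
            VariantStat(
                variant_id=str(row.variant_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                a1="A",
                a2="G",
                z=float(z[i]),
                n=len(train_idx),
            )
            for i, row in enumerate(variant_meta.itertuples(index=False))
        ]
        out.append({"variants": variants, "train_idx": train_idx, "validation_idx": val_idx})
    return out


# ---------------------------------------------------------------------------
# Genes, gene sets, truth labels
# ---------------------------------------------------------------------------

def build_gene_map(
    variant_meta: pd.DataFrame,
    snps_per_gene: int = 10,
) -> tuple[list[GeneRecord], dict[str, np.ndarray]]:
    """Tile the synthetic map into genes of ``snps_per_gene`` consecutive SNPs.

    Genes never straddle LD-block boundaries, so within-gene LD comes
    from a single AR(1) block.  Returns the gene records and the
    gene -> SNP-index mapping.
    """
    genes: list[GeneRecord] = []
    gene_snps: dict[str, np.ndarray] = {}
    gid = 0
    for _block, sub in variant_meta.groupby("block", sort=True):
        idx = sub.index.to_numpy()
        for start in range(0, idx.size, snps_per_gene):
            chunk = idx[start : start + snps_per_gene]
            gene_id = f"gene{gid}"
            gid += 1
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    chrom=str(sub.loc[chunk[0], "chrom"]),
                    start=int(sub.loc[chunk[0], "pos"]),
                    end=int(sub.loc[chunk[-1], "pos"]),
                    strand="+",
                )
            )
            gene_snps[gene_id] = chunk
    return genes, gene_snps


def build_genes_and_sets(
    variant_meta: pd.DataFrame,
    causal_index: np.ndarray,
    set_sizes: tuple[int, ...] = (10, 25, 50, 100, 200),
    causal_counts: tuple[int, ...] = (0, 5, 10, 25, 50, 100, 200),
    n_control_sets: int = 0,
    n_replicates: int = 10,
    seed: int = 0,
    snps_per_gene: int = 10,
) -> tuple[list[GeneRecord], dict[str, np.ndarray], GeneSetCollection, list[GeneSetTruth]]:
    """Build genes, gene sets over them, and truth labels.

    Genes containing at least one causal SNP are causal genes.  For
    every feasible (size, n_causal) configuration with
    0 < n_causal <= size, ``n_replicates`` sets are sampled (genes
    without replacement within a set; overlap across sets is free).
    ``n_control_sets`` additional all-non-causal sets of sizes drawn
    from ``set_sizes`` are appended.
    """
    genes, gene_snps = build_gene_map(variant_meta, snps_per_gene)
    causal_set = set(causal_index.tolist())
    causal_genes = [g.gene_id for g in genes if causal_set & set(gene_snps[g.gene_id].tolist())]
    noncausal_genes = [g.gene_id for g in genes if g.gene_id not in set(causal_genes)]

    rng = np.random.default_rng(seed)
    sets: list[tuple[str, str, list[str]]] = []
    truth: list[GeneSetTruth] = []

    def sample_set(size: int, n_causal: int, set_id: str) -> None:
        if n_causal > len(causal_genes) or size - n_causal > len(noncausal_genes):
            raise ValueError(
                f"infeasible configuration (size={size}, n_causal={n_causal}): "
                f"{len(causal_genes)} causal / {len(noncausal_genes)} non-causal genes available"
            )
        chosen = list(rng.choice(causal_genes, size=n_causal, replace=False)) + list(
            rng.choice(noncausal_genes, size=size - n_causal, replace=False)
        )
        rng.shuffle(chosen)
        sets.append((set_id, f"size={size};n_causal={n_causal}", [str(g) for g in chosen]))
        truth.append(GeneSetTruth(set_id, size, n_causal))

    for size in set_sizes:
        for n_causal in causal_counts:
            if not (0 < n_causal <= size):
                continue
            for rep in range(n_replicates):
                sample_set(size, n_causal, f"set_s{size}_c{n_causal}_r{rep}")
    if 0 in causal_counts:
        for size in set_sizes:
            for rep in range(n_replicates):
                sample_set(size, 0, f"set_s{size}_c0_r{rep}")
    for i in range(n_control_sets):
        size = int(rng.choice(set_sizes))
        sample_set(size, 0, f"control{i}")

    return genes, gene_snps, GeneSetCollection(sets), truth


def build_overlapping_sets(
    base_collection: GeneSetCollection,
    base_truth: list[GeneSetTruth],
    causal_genes: set[str],
    all_genes: list[str],
    n_extra: int = 191,
    overlap_mode: str = "correlated",
    seed: int = 0,
) -> tuple[GeneSetCollection, list[GeneSetTruth]]:
    """Extend a collection with extra sets, correlated or not with the base.

    Correlated mode resamples a base set and swaps a uniform 10-50% of
    its genes for random genes (so each extra set shares >= 50% of its
    genes with its source).  Uncorrelated mode draws extra sets
    entirely from genes outside all base sets.  Truth labels are
    recomputed from causal-gene content.
    """
    if len(base_collection) == 0:
        raise ValueError("base collection is empty")
    if overlap_mode not in ("correlated", "uncorrelated"):
        raise ValueError("overlap_mode must be correlated or uncorrelated")
    rng = np.random.default_rng(seed)
    base_sets = list(base_collection)
    base_genes = base_collection.all_genes()
    outside = sorted(set(all_genes) - base_genes)

    new_sets = list(base_sets)
    new_truth = list(base_truth)
    for i in range(n_extra):
        sid = f"extra_{overlap_mode}_{i}"
        if overlap_mode == "correlated":
            _src_id, _d, src_genes = base_sets[rng.integers(len(base_sets))]
            genes = list(src_genes)
            n_swap = int(round(rng.uniform(0.1, 0.5) * len(genes)))
            pool = sorted(set(all_genes) - set(genes))
            if n_swap > 0 and pool:
                drop = rng.choice(len(genes), size=n_swap, replace=False)
                add = rng.choice(pool, size=min(n_swap, len(pool)), replace=False)
                genes = [g for k, g in enumerate(genes) if k not in set(drop.tolist())]
                genes.extend(str(g) for g in add)
        else:
            size = len(base_sets[rng.integers(len(base_sets))][2])
            if size > len(outside):
                raise ValueError(
                    f"uncorrelated mode infeasible: need {size} outside genes, "
                    f"have {len(outside)}"
                )
            genes = [str(g) for g in rng.choice(outside, size=size, replace=False)]
        n_causal = len(set(genes) & causal_genes)
        new_sets.append((sid, f"extra;{overlap_mode}", genes))
        new_truth.append(GeneSetTruth(sid, len(genes), n_causal))
    return GeneSetCollection(new_sets), new_truth


# ---------------------------------------------------------------------------
# Per-gene LD from simulated genotypes
# ---------------------------------------------------------------------------

class MemoryLDSource:
    """In-memory per-gene LD source with the LDDirectory lookup protocol."""

    def __init__(self, matrices: dict[str, LDMatrix]):
        self.matrices = matrices

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.matrices

    def get(self, gene_id: str, variant_ids) -> LDMatrix:
        ld = self.matrices[gene_id]
        if list(variant_ids) == ld.variant_ids:
            return ld
        return ld.subset(list(variant_ids))


def compute_gene_ld(
    genotypes: np.ndarray,
    variant_meta: pd.DataFrame,
    gene_snps: dict[str, np.ndarray],
) -> MemoryLDSource:
    """Empirical dosage correlation matrices per gene (reference-panel role)."""
    ids = variant_meta["variant_id"].to_numpy()
    matrices: dict[str, LDMatrix] = {}
    for gene_id, idx in gene_snps.items():
        sub = genotypes[:, idx].astype(float)
        sd = sub.std(axis=0)
        keepvar = sd > 0
        K = np.eye(idx.size)
        if keepvar.sum() >= 2:
            C = np.corrcoef(sub[:, keepvar], rowvar=False)
            K[np.ix_(np.flatnonzero(keepvar), np.flatnonzero(keepvar))] = C
        K = np.clip(0.5 * (K + K.T), -1.0, 1.0)
        np.fill_diagonal(K, 1.0)
        matrices[gene_id] = LDMatrix([str(v) for v in ids[idx]], K)
    return MemoryLDSource(matrices)
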