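# gsblr — Bayesian gene-set prioritization from GWAS summary statistics

`gsblr` identifies biological gene sets (pathways) associated with a
complex trait using nothing but GWAS summary statistics, gene
annotations, gene-set definitions and linkage-disequilibrium (LD)
reference matrices.  It is aimed at statistical geneticists who want a
sparse Bayesian alternative to competitive gene-set regression tools,
with posterior inclusion probabilities instead of p-values, and a fully
seeded simulation suite for validating the method without access to
individual-level data.

## The model

**Gene level.**  For each gene *g* with variant z-scores
*z* = (z₁, …, z_p)' and local LD matrix *K*, the gene statistic is the
quadratic form

T_g = Σᵢ zᵢ² = **z**'**z**,  with **z** ~ N(0, K) under the null,

so T_g is distributed as Σᵢ λᵢ χ²₁ with λᵢ the eigenvalues of *K*.  The
survival probability is evaluated exactly (scaled chi-square when the
positive eigenvalues coincide, Imhof numerical inversion in the central
region) with a Kuonen saddlepoint in the far tail, and converted to the
gene Z-score y_g = Φ⁻¹(1 − p_g).  Variants are assigned to genes using
a 35 kb upstream / 10 kb downstream strand-aware window.

**Gene-set level.**  Gene Z-scores are regressed on the binary
n-genes × m-sets membership matrix *X*:

y = Xb + e,  e ~ N(0, σ²ₑI),
b_j = 0 with probability 1 − π,  b_j ~ N(0, σ²_b) with probability π,

the BayesC spike-and-slab prior.  σ²_b and σ²ₑ carry scaled inverse
chi-square priors, π a Beta(1, 1) prior (estimated by default; the
classical fixed value is π = 0.001).  Gibbs sampling (3000 iterations,
500 burn-in by default) yields for each gene set its **posterior
inclusion probability** (PIP) — the prioritization score — and the
posterior mean effect, whose sign separates enrichment for associated
genes (+) from enrichment for non-associated genes (−).  Sets with
PIP ≥ 0.1 and a positive mean effect are reported as associated.

A multi-trait extension fits several traits jointly with
inverse-Wishart priors on the effect and residual covariance matrices,
letting a set influence any combination of traits and borrowing
strength across correlated traits.  A MAGMA-style joint-OLS baseline,
precision/recall/F1 and top-k evaluation utilities, a PIP-calibration
driver, and an exact hypergeometric enrichment test complete the
toolchain.

## Worked example

Everything below is generated on the fly — no downloads.

```python
from gsblr.pipeline import RunConfig, run_prioritization

cfg = RunConfig(
    seed=2, out_dir="demo_run",
    scenario={"h2": 0.3, "causal_prop": 0.01, "architecture": "GA1",
              "trait_type": "quantitative", "prevalence": None,
              "n_ind": 2000, "n_snp": 2000},
    genes={"snps_per_gene": 10},
    sets={"set_sizes": [20], "causal_counts": [0, 10], "n_replicates": 3,
          "n_control_sets": 14},
)
out = run_prioritization(cfg)
print(open(out / "associated.tsv").read())
```

```
# gsblr config_hash=abd0ccacd677 seed=2
set_id	pip	b_mean
set_s20_c10_r0	0.462	0.5196053032554147
set_s20_c10_r2	0.4524	0.5208028263488829
set_s20_c10_r1	0.17	0.16422440075834513
```

The three planted causal sets (each containing 10 causal genes out of
20) are recovered with PIPs 0.46, 0.45 and 0.17 — all above the 0.1
association threshold with positive effects — while the largest PIP
among the 17 non-causal sets is 0.023.  `fit.tsv` holds the
full per-set posterior summary, `genestats.tsv` the per-gene VEGAS
statistics, `truth.tsv` the simulation labels, and `manifest.json`
checksums that make the run reproducible from the config hash + seed.

The same workflow is scriptable from the shell:

```bash
gsblr genestats --gwas gwas.tsv --genes genes.gtf --ld LD_DIR \
      --up 35000 --down 10000 --out genestats.tsv
gsblr fit --genestats genestats.tsv --gmt sets.gmt --seed 1 --out fit.tsv
gsblr baseline --genestats genestats.tsv --gmt sets.gmt --covars auto --out ols.tsv
gsblr enrich --gmt sets.gmt --disease-list disease.tsv \
      --genestats genestats.tsv --out enrich.tsv
```

Coordinates are 1-based inclusive throughout (GTF convention); GWAS
column names are configurable (`--col-z`, `--col-beta`, `--col-se`, …);
LD is supplied as per-gene plain-text correlation matrices
(`<gene_id>.ld`).

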