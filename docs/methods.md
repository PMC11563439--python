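# Methods

This note documents the statistical models implemented in `gsblr`, the
priors and defaults, the synthetic-data generator used to validate
them, and the numerical choices that a maintainer or careful user
should know about.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. Gene-level statistics

For gene *g* the statistic is T_g = Σᵢ zᵢ², the sum of squared
variant-level z-scores mapped to the gene.  Under the null the
variant z-vector is N(0, K) with K the local LD correlation matrix, so

T_g ~ Σᵢ λᵢ χ²₁,   λᵢ = eigenvalues of K.

**Variant-to-gene windows.** A variant belongs to a gene when its
position lies in [start − 35 kb, end + 10 kb] for +/unknown strand and
[start − 10 kb, end + 35 kb] for − strand.  The windows are applied
relative to transcription direction because regulatory flanks are
asymmetric; unknown strand is treated as +.  Both flanks are
parameters (`up_bp`, `down_bp`).

**LD regularization.** Reference-panel correlation matrices are
rank-deficient; eigenvalues below max(λ)·1e-8 are floored at zero
before use.

**Tail evaluation.** Three regimes:

* all positive eigenvalues equal (identity or rank-one LD): the
  distribution is an exact scaled chi-square, evaluated in closed form;
* central region (saddlepoint p ≥ 1e-7): Imhof numerical inversion of
  the characteristic function, evaluated by 12-point Gauss–Legendre
  quadrature on uniform panels whose width bounds the phase change by
  π, truncated where the alternating-tail bound falls below ~1e-9.
  This is effectively exact (validated against large Monte-Carlo to a
  fraction of the MC standard error);
* far tail: Kuonen's (Lugannani–Rice) saddlepoint, whose relative
  accuracy is excellent exactly where the Imhof integral underflows.

The reason the central region does not use the saddlepoint by default:
the first-order (and Daniels second-order) saddlepoint carries an
irreducible relative bias of roughly 0.3–3% for few-eigenvalue
spectra, which is visible at the accuracy our validation demands.  A
pure saddlepoint path (`method="saddlepoint"`) is retained, with a
seeded Monte-Carlo fallback (≥1e6 draws) at its singularity q = E[Q],
where p ≈ 0.5 and accuracy is uncritical.

P-values are floored at 1e-300 and the probit transform
y_g = Φ⁻¹(1 − p_g) is capped (p = 1 maps to ≈ −8.2, the floor maps to
z ≈ +37) so the regression response is always finite.

## 2. Single-trait spike-and-slab regression

y = Xb + e with X the binary gene-set membership matrix.  The response
is centered (the intercept is absorbed); X is left uncentered so b_j
keeps the sign interpretation "enrichment above baseline", which the
negative-effect exclusion rule relies on.

Priors: b_j is zero with probability 1 − π and N(0, σ²_b) otherwise;
σ²_b ~ χ⁻¹(S_b, ν_b), σ²ₑ ~ χ⁻¹(S_e, ν_e) (parameterized so a draw is
νS/χ²_ν); π ~ Beta(1, 1) (the two-component Dirichlet with α = (1,1)),
estimated by default with `--fix-pi` available (fixed default 0.001).

Defaults where a choice was open: ν_b = ν_e = 4; S_b set so the prior
mode of σ²_b is 0.5·var(y)/(m·π₀) and S_e so the prior mode of σ²ₑ is
0.5·var(y) — weakly informative and scale-matched to the response.
Note that with π₀ = 0.001 and small m the slab prior is very wide;
this is deliberate sparsity pressure, and it means weakly separated
designs (small m, diffuse signal) can under-include.  The slab scale
is exposed (`S_b`) for users who want to match it to an expected
inclusion level.

Sampling is single-site Gibbs in fixed column order, 3000 iterations
with 500 burn-in by default, no thinning.  The inclusion indicator d_j
is drawn with b_j marginalized (collapsed within site), which mixes
better than the joint update; given d_j = 1, b_j is drawn from its
normal full conditional.  σ²_b uses only currently included effects;
with none included it is refreshed from the prior.  PIP_j is the
post-burn-in mean of d_j.  Everything is reproducible from the seed.
Convergence is reported, not enforced: effective sample sizes (Geyer
initial-positive-sequence estimator) and split-chain R̂ for the
variance components, plus a multi-chain helper
(`fit_single_chains` / `--chains`) reporting the maximum split-R̂.

**Exactness checks.** On enumerable problems the sampler is validated
against closed forms: exhaustive conjugate model averaging over all
2³ submodels of a 60-gene/3-set toy (PIPs agree within 0.02 at 20k
iterations), and the ridge solution (X'X + I·σ²ₑ/σ²_b)⁻¹X'y in the
π → 1 limit (relative L2 error below 1% on a 200×20 problem).

**A structural caveat on "null calibration".** Under pure-noise y one
might expect the average PIP to equal the posterior mean of π.  The
two quantities differ by construction: π | d ~ Beta(m₁+1, m₀+1) gives
E[π] = (E[m₁]+1)/(m+2), while mean PIP = E[m₁]/m; with an informative
likelihood keeping E[m₁] near zero the Beta pseudo-count leaves a gap
of ≈ 1/m that no amount of sampling removes.  The identity holds only
for an uninformative likelihood.  The test suite states the check
honestly and it fails at ~1/m precision; the two quantities are both
reported by the acceptance script.

## 3. Multi-trait model

Y = XB + E with rows of E ~ N(0, V_E); each set carries an inclusion
vector δ_j ∈ {0,1}^t and, conditional on δ_j, the active effects are
N(0, [V_B]_δ).  V_B and V_E carry inverse-Wishart priors; correlated
effect estimates let the model borrow strength across traits.  The
printed normal equations follow the standard multivariate spike-and-
slab structure: the active sub-vector's full-conditional precision is
X_j'X_j·[V_E⁻¹]_δ + ([V_B]_δ)⁻¹, and δ_j is drawn from its collapsed
conditional with the active effects marginalized
(r_j ~ N(0, X_j'X_j·V_E + (X_j'X_j)²·[V_B]_δ-padded)).

Two inclusion structures: `combination` (default, t ≤ 5) samples δ_j
over all 2^t configurations with a Dirichlet(1) prior on configuration
probabilities — "any combination of traits"; `per-trait` uses
independent Bernoulli indicators with per-trait Beta(1,1) inclusion
probabilities and is the default beyond five traits where the 2^t
mixture is wasteful.  The two-trait combination path is implemented
with closed-form 2×2 algebra (it is the workhorse).

Defaults: ν_B = ν_E = t + 3 with scale matrices making the prior means
0.5·diag(var(y_t))/(m·π₀) and 0.5·diag(var(y_t)).  V_B's full
conditional is taken over sets with at least one active trait, using
the zero-padded effect vectors; with no active set it is refreshed
from the prior.  Gene alignment across traits is complete-case.  A
diagonal-covariance constraint (`diagonal_covariance=True`, scaled
inverse chi-square updates per trait, priors matched to the
single-trait ones) plus per-trait indicators reduces the model to
independent single-trait fits — verified within Monte-Carlo error —
so the joint machinery adds nothing when traits are unrelated.

## 4. Baseline

The comparison method is a transparent MAGMA-style competitive
regression: joint OLS of y on [1 | covariates | X] with one-sided
per-set p-values (H₁: β_j > 0; enrichment is directional, mirroring
the negative-effect exclusion).  Default covariates are log SNP count
and log gene length.  Rank deficiency is detected by pivoted QR and
aliased columns are reported as NaN.  This is not a re-implementation
of MAGMA's gene analysis or permutation machinery.

## 5. Synthetic-data generator

The generator reproduces the statistical structure the method
consumes, end-to-end and fully seeded.

* **Genotypes**: 0/1/2 dosages from a latent Gaussian with AR(1)
  correlation (default ρ = 0.8) inside blocks of 50 SNPs, thresholded
  at Hardy–Weinberg genotype frequencies for per-SNP MAFs drawn
  uniformly from [0.01, 0.5]; blocks are independent.  Positions sit
  on a synthetic 1 kb-spaced map.
* **Effects**: each SNP causal independently with probability π
  (study values 0.01/0.001).  GA1 draws causal effects from one
  normal; GA2 from a three-component normal scale mixture with
  variances (1, 0.1, 0.01) and weights (0.1, 0.2, 0.7) — our choice
  of a heavy-tailed architecture, exposed in config.
* **Phenotypes**: additive on column-standardized dosages with
  residual variance set from the realized genetic variance, so the
  target h² (0.1/0.3) is hit up to sampling error.  Binary traits
  threshold the liability at the empirical (1 − prevalence) quantile
  (prevalence 0.05/0.15 exact by construction — one noise source
  removed at desk scale).  The full grid is 8 quantitative and 16
  binary scenarios.
* **GWAS**: five cross-validation replicates, each 80% training / 20%
  validation; per-SNP simple linear regression z for quantitative
  traits and a vectorized two-parameter Newton logistic Wald z for
  binary traits, with a null score-test fallback under
  (quasi-)separation and z = 0 for monomorphic SNPs.
* **Genes and sets**: genes tile the map in runs of consecutive SNPs
  and never straddle LD blocks, so per-gene LD is a clean AR(1)
  block; per-gene LD matrices are empirical dosage correlations from
  the training split (the reference-panel role).  Sets are sampled by
  (size, number of causal genes) configuration with replication;
  control sets contain no causal genes; "extra" sets are either
  correlated with the base collection (resample a base set, swap a
  uniform 10–50% of genes) or drawn entirely outside it.

**What the generator does not emulate**: real minor-allele-frequency
spectra and long-range LD, ancestry structure and relatedness, gene
length/SNP-density distributions of real annotations, and overlap
patterns of curated pathway databases.  LD "leakage" is, however,
real and present: genes sharing a block with a causal gene carry
partial signal, so "non-causal" genes are not clean nulls — exactly
as in real data.  Passing tests therefore demonstrate statistical
correctness and calibration of the machinery under a realistic LD
model, not performance on any particular real cohort.

## 6. Validation studies and their conditions

The seeded studies in `gsblr.experiments` (run by the test suite and
`scripts/acceptance.py`) use the following fixed conditions, chosen
once:

* **Calibration** (rank-pooled): per repeat, a quantitative trait with
  h² = 0.3 and π = 0.01 over 4000 SNPs / 1000 individuals; causal sets
  of sizes 20 and 50 (two per size) with a causal-gene fraction drawn
  uniformly from [5%, 50%], plus 198 control sets; 5 repeats at
  acceptance scale (50 in the full design).  Sets are ordered by PIP
  within each repeat and pooled by rank; the 95% band is the central
  interval of Binomial(n, mean PIP)/n.  Coverage ≥ 90% of ranks is
  the pass mark.
* **Recovery / baseline comparison**: a 200-set correlated-overlap
  membership matrix over 400 genes (ten size-25 sets with 10 causal
  genes, ten matched controls, 85 random controls, 95 correlated
  extras), response y = Xb + e at the regression level with b = 0.5 on
  the ten causal sets and residual sd 0.5 (per-set signal-to-noise 1);
  five seeds.  Measured: PIP-ranking AUC and top-10 true positives for
  both methods.  The regression-level design isolates the samplers'
  ranking behaviour; defining truth through the full genotype chain
  instead labels heavily diluted overlap sets (one causal gene in 25)
  as causal, which no method separates at this scale.
* **Multi-trait gain**: two traits, ten shared causal sets among 100,
  causal effects of magnitude ~0.35 with correlation 0.9 across traits
  and matched marginal scale, residual sd 0.7, ten seeds; measured as
  mean causal-set PIP of the joint fit minus the per-trait fits.
* **Problem sizes** throughout are chosen as the smallest that leave
  the conclusions clearly resolved above Monte-Carlo noise.

## 7. Numerical and degenerate-input conventions

* p-value floor 1e-300; probit caps as in §1.
* Empty gene sets (all-zero design columns) are rejected at
  construction; all-zero rows (gene in no set) are fine.
* Precision/recall at empty denominators are defined as 0, so F1 is
  always defined.
* Prediction accuracy (cross-validated) is the Pearson correlation
  between the gene-level predictor Xb̂ and validation-split gene
  Z-scores; a zero-variance predictor scores 0 by convention.  This
  definition of "prediction accuracy" is this package's choice of the
  natural gene-level analogue of genomic-prediction accuracy.
* The hypergeometric enrichment p-value is the exact upper tail
  P(X ≥ k), summed in log space; the default universe is the set of
  genes present in the gene-statistics table.
* Ties in ranked outputs break by |effect| descending, then set id.
* All readers validate invariants (symmetry and unit diagonal of LD
  within stated tolerances, unique identifiers, 1-based coordinates)
  and fail with the offending column/line named.

## 8. Known limitations

* Allele harmonization, strand flipping and liftover are out of scope;
  variant and gene identifiers must already be consistent.
* The baseline approximates MAGMA's joint gene-set regression, not its
  gene analysis, permutation null, or raw-genotype mode.
* The multi-trait model assumes no sample overlap between the traits'
  GWAS cohorts and a shared gene universe (complete-case).
* With π estimated and very few sets (m ≲ 30) the default slab scale
  is wide and inclusion is conservative; supply `S_b` when analysing
  tiny collections.
* The combination inclusion model enumerates 2^t configurations per
  set and sweep; beyond five traits the per-trait structure is used.
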