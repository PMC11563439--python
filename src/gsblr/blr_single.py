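"""Single-trait Bayesian linear regression with a BayesC spike-and-slab prior.

The model regresses gene-level Z-scores y (length n genes) on a binary
gene-set membership matrix X (n x m):

    y = X b + e,    e ~ N(0, sigma_e^2 I)

with a two-component mixture prior on each gene-set effect:

    b_j = 0                 with probability 1 - pi
    b_j ~ N(0, sigma_b^2)   with probability pi

sigma_b^2 and sigma_e^2 carry scaled inverse chi-square priors
chi^{-1}(S, nu); the mixture proportion pi carries a Beta(1, 1) prior
(the two-component Dirichlet with alpha = (1, 1)) and is estimated by
default, or can be fixed (the classical BayesC default is pi = 0.001).
Inference is single-site Gibbs sampling: inclusion indicators d_j are
drawn with b_j marginalized out (collapsed within site), which improves
mixing over the joint (d_j, b_j) update.  The posterior inclusion
probability PIP_j is the post-burn-in mean of d_j and is the
prioritization score for gene set j.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetDesign",
    "SamplerConfig",
    "BLRResult",
    "fit_single",
    "prioritize",
    "effective_sample_size",
    "split_rhat",
]


@dataclass
class GeneSetDesign:
    """Binary n-genes x m-sets membership matrix with identifiers.

    Rows may be all-zero (a gene in no set); all-zero columns (empty
    sets) are rejected.
    """

    gene_ids: list[str]
    set_ids: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a matrix")
        n, m = X.shape
        if n != len(self.gene_ids) or m != len(self.set_ids):
            raise ValueError("X shape does not match identifier lists")
        if not np.all(np.isin(X, (0.0, 1.0))):
            raise ValueError("X entries must be 0 or 1")
        if m and np.any(X.sum(axis=0) == 0):
            j = int(np.argmax(X.sum(axis=0) == 0))
            raise ValueError(f"empty gene set (all-zero column): {self.set_ids[j]!r}")
        if len(set(self.set_ids)) != m:
            raise ValueError("duplicate set_ids")
        self.X = X

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_sets(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_collection(cls, gene_ids: Sequence[str], collection) -> "GeneSetDesign":
        """Build the membership matrix for a gene universe from a GeneSetCollection.

        Sets with no gene in the universe are dropped with a warning.
        """
        index = {g: i for i, g in enumerate(gene_ids)}
        cols, kept = [], []
        for set_id, _desc, genes in collection:
            col = np.zeros(len(gene_ids))
            hits = [index[g] for g in genes if g in index]
            if not hits:
                logger.warning("set %s: no genes in universe, dropped", set_id)
                continue
            col[hits] = 1.0
            cols.append(col)
            kept.append(set_id)
        X = np.column_stack(cols) if cols else np.zeros((len(gene_ids), 0))
        return cls(list(gene_ids), kept, X)


@dataclass
class SamplerConfig:
    """MCMC settings and prior hyperparameters for the single-trait model.

    Defaults: 3000 iterations with 500 burn-in; prior inclusion
    probability pi = 0.001 (used as the fixed value when
    ``estimate_pi=False`` and as the initial value otherwise);
    Dirichlet concentration alpha = (1, 1).  If the inverse chi-square
    scale parameters ``S_b`` / ``S_e`` are left as None they are set at
    fit time so the prior modes are 0.5 var(y) / (m pi) and 0.5 var(y)
    respectively (weakly informative, scale-matched to the response).
    """

    n_iter: int = 3000
    burn_in: int = 500
    pi_prior: float = 0.001
    nu_b: float = 4.0
    S_b: float | None = None
    nu_e: float = 4.0
    S_e: float | None = None
    alpha: tuple[float, float] = (1.0, 1.0)
    seed: int = 0
    estimate_pi: bool = True
    fix_sigma_b2: float | None = None  # fix variance components (testing/ridge limit)
    fix_sigma_e2: float | None = None
    keep_samples: bool = False

    def __post_init__(self) -> None:
        if self.n_iter <= 0:
            raise ValueError("n_iter must be positive")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if not (0 < self.pi_prior < 1):
            raise ValueError("pi_prior must lie in (0, 1)")
        if self.nu_b <= 0 or self.nu_e <= 0:
            raise ValueError("prior degrees of freedom must be positive")


@dataclass
class BLRResult:
    """Posterior summaries of a single-trait fit."""

    set_ids: list[str]
    pip: np.ndarray
    b_mean: np.ndarray
    b_sd: np.ndarray
    sigma_b2_mean: float
    sigma_e2_mean: float
    pi_mean: float
    diagnostics: dict = field(default_factory=dict)
    b_samples: np.ndarray | None = None
    d_samples: np.ndarray | None = None


def _scaled_inv_chi2(rng: np.random.Generator, nu: float, S: float) -> float:
    """Draw sigma^2 ~ chi^{-1}(S, nu), i.e. nu * S / chi2(nu)."""
    return nu * S / rng.chisquare(nu)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    # sum pairwise autocorrelations while positive (Geyer initial positive)
    tau = 1.0
    for k in range(1, n - 1, 2):
        pair = acf[k] + acf[k + 1] if k + 1 < n else acf[k]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(n / max(tau, 1.0))


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction over chains (axis 0) x draws."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1] // 2
    if n < 2:
        return float("nan")
    halves = np.vstack([x[:, :n], x[:, n : 2 * n]])
    W = halves.var(axis=1, ddof=1).mean()
    B = n * halves.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + B / (n * W)))


def fit_single(y: np.ndarray, design: GeneSetDesign, config: SamplerConfig) -> BLRResult:
    """Gibbs sampler for the spike-and-slab gene-set regression.

    y is centered internally (intercept absorbed); X columns are used
    raw (0/1) so b_j keeps its enrichment-above-baseline sign
    interpretation.  Per iteration, a fixed-order single-site sweep over
    the m sets updates (d_j, b_j); then sigma_b^2, sigma_e^2 and (if
    estimated) pi are drawn from their full conditionals.  When no
    effect is currently included, sigma_b^2 is refreshed from its prior.
    Fully reproducible given ``config.seed``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if design.n_sets == 0:
        raise ValueError("design has no gene sets")
    if y.size != design.n_genes:
        raise ValueError("length of y does not match design rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")

    X = design.X
    n, m = X.shape
    y = y - y.mean()
    var_y = float(np.var(y)) if np.var(y) > 0 else 1.0

    cfg = config
    S_b = cfg.S_b if cfg.S_b is not None else 0.5 * var_y / (m * cfg.pi_prior) * (cfg.nu_b + 2) / cfg.nu_b
    S_e = cfg.S_e if cfg.S_e is not None else 0.5 * var_y * (cfg.nu_e + 2) / cfg.nu_e

    rng = np.random.default_rng(cfg.seed)
    xtx = np.einsum("ij,ij->j", X, X)

    b = np.zeros(m)
    d = np.zeros(m, dtype=bool)
    sigma_b2 = cfg.fix_sigma_b2 if cfg.fix_sigma_b2 is not None else _scaled_inv_chi2(rng, cfg.nu_b, S_b)
    sigma_e2 = cfg.fix_sigma_e2 if cfg.fix_sigma_e2 is not None else var_y
    pi = cfg.pi_prior
    resid = y.copy()  # y - X b, maintained incrementally

    n_keep = cfg.n_iter - cfg.burn_in
    pip_acc = np.zeros(m)
    b_acc = np.zeros(m)
    b2_acc = np.zeros(m)
    sb2_acc = se2_acc = pi_acc = 0.0
    trace_sb2 = np.empty(n_keep)
    trace_se2 = np.empty(n_keep)
    trace_pi = np.empty(n_keep)
    trace_nincl = np.empty(n_keep)
    b_samples = np.empty((n_keep, m)) if cfg.keep_samples else None
    d_samples = np.empty((n_keep, m), dtype=bool) if cfg.keep_samples else None

    log_pi_ratio = np.log(pi) - np.log1p(-pi)

    for it in range(cfg.n_iter):
        for j in range(m):
            xj = X[:, j]
            rhs = xj @ resid + xtx[j] * b[j]  # X_j' (y - Xb + X_j b_j)
            v0 = xtx[j] * sigma_e2
            v1 = v0 + xtx[j] ** 2 * sigma_b2
            # collapsed Bernoulli: logit P(d_j=1) under marginalized b_j
            log_bf = 0.5 * (np.log(v0 / v1) + rhs**2 * (1.0 / v0 - 1.0 / v1))
            logit = log_bf + log_pi_ratio
            if logit >= 0:
                p_incl = 1.0 / (1.0 + np.exp(-logit))
            else:
                e = np.exp(logit)
                p_incl = e / (1.0 + e)
            new_d = rng.random() < p_incl
            old_b = b[j]
            if new_d:
                prec = xtx[j] + sigma_e2 / sigma_b2
                mean = rhs / prec
                new_b = mean + rng.standard_normal() * np.sqrt(sigma_e2 / prec)
            else:
                new_b = 0.0
            if new_b != old_b:
                resid -= xj * (new_b - old_b)
            b[j] = new_b
            d[j] = new_d

        m1 = int(d.sum())
        if cfg.fix_sigma_b2 is None:
            if m1 > 0:
                ssb = float(np.sum(b[d] ** 2))
                sigma_b2 = (cfg.nu_b * S_b + ssb) / rng.chisquare(cfg.nu_b + m1)
            else:
                sigma_b2 = _scaled_inv_chi2(rng, cfg.nu_b, S_b)
        if cfg.fix_sigma_e2 is None:
            sse = float(resid @ resid)
            sigma_e2 = (cfg.nu_e * S_e + sse) / rng.chisquare(cfg.nu_e + n)
        if cfg.estimate_pi:
            pi = rng.beta(m1 + cfg.alpha[0], m - m1 + cfg.alpha[1])
            pi = min(max(pi, 1e-12), 1 - 1e-12)
            log_pi_ratio = np.log(pi) - np.log1p(-pi)

        if it >= cfg.burn_in:
            k = it - cfg.burn_in
            pip_acc += d
            b_acc += b
            b2_acc += b**2
            sb2_acc += sigma_b2
            se2_acc += sigma_e2
            pi_acc += pi
            trace_sb2[k] = sigma_b2
            trace_se2[k] = sigma_e2
            trace_pi[k] = pi
            trace_nincl[k] = m1
            if cfg.keep_samples:
                b_samples[k] = b
                d_samples[k] = d

    pip = pip_acc / n_keep
    b_mean = b_acc / n_keep
    b_var = np.maximum(b2_acc / n_keep - b_mean**2, 0.0)
    diagnostics = {
        "ess": {
            "sigma_b2": effective_sample_size(trace_sb2),
            "sigma_e2": effective_sample_size(trace_se2),
            "pi": effective_sample_size(trace_pi),
            "n_included": effective_sample_size(trace_nincl),
        },
        "split_rhat": {
            "sigma_b2": split_rhat(trace_sb2),
            "sigma_e2": split_rhat(trace_se2),
            "pi": split_rhat(trace_pi),
            "n_included": split_rhat(trace_nincl),
        },
    }
    return BLRResult(
        set_ids=list(design.set_ids),
        pip=pip,
        b_mean=b_mean,
        b_sd=np.sqrt(b_var),
        sigma_b2_mean=sb2_acc / n_keep,
        sigma_e2_mean=se2_acc / n_keep,
        pi_mean=pi_acc / n_keep,
        diagnostics=diagnostics,
        b_samples=b_samples,
        d_samples=d_samples,
    )


def prioritize(
    result: BLRResult,
    pip_threshold: float = 0.1,
    exclude_negative: bool = True,
) -> list[tuple[str, float, float]]:
    """Rank gene sets considered associated.

    Sets with PIP >= threshold are returned sorted by PIP (descending;
    ties by |posterior mean effect| then set id).  A negative posterior
    mean effect marks a set enriched for non-associated genes and is
    excluded by default.
    """
    if not (0 <= pip_threshold <= 1):
        raise ValueError("pip_threshold must lie in [0, 1]")
    rows = [
        (sid, float(p), float(bm))
        for sid, p, bm in zip(result.set_ids, result.pip, result.b_mean)
        if p >= pip_threshold and not (exclude_negative and bm < 0)
    ]
    rows.sort(key=lambda r: (-r[1], -abs(r[2]), r[0]))
    return rows


def fit_single_chains(
    y: np.ndarray,
    design: GeneSetDesign,
    config: SamplerConfig,
    n_chains: int = 4,
) -> tuple[BLRResult, dict]:
    """Run independent seeded chains; report pooled result and max split-Rhat."""
    import dataclasses

    results = []
    for c in range(n_chains):
        cfg = dataclasses.replace(config, seed=config.seed + 1000 * c, keep_samples=True)
        results.append(fit_single(y, design, cfg))
    pip = np.mean([r.pip for r in results], axis=0)
    b_mean = np.mean([r.b_mean for r in results], axis=0)
    nincl = np.stack([r.d_samples.sum(axis=1).astype(float) for r in results])
    rhat = {
        "n_included": split_rhat(nincl),
        "sigma_e2": max(r.diagnostics["split_rhat"]["sigma_e2"] for r in results),
    }
    pooled = BLRResult(
        set_ids=list(design.set_ids),
        pip=pip,
        b_mean=b_mean,
        b_sd=np.mean([r.b_sd for r in results], axis=0),
        sigma_b2_mean=float(np.mean([r.sigma_b2_mean for r in results])),
        sigma_e2_mean=float(np.mean([r.sigma_e2_mean for r in results])),
        pi_mean=float(np.mean([r.pi_mean for r in results])),
        diagnostics={"max_split_rhat": rhat, "n_chains": n_chains},
    )
    return pooled, rhat
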