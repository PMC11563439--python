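"""Multi-trait spike-and-slab gene-set regression.

Extends the single-trait BayesC model to t traits analysed jointly:

    Y = X B + E,    rows of E ~ N(0, V_E)

where Y (n genes x t traits) holds per-trait gene Z-scores, B (m x t)
the gene-set effects and V_E the t x t residual covariance.  Each set j
carries a per-trait inclusion vector delta_j in {0,1}^t; conditional on
inclusion, the active effects are jointly normal with covariance the
corresponding submatrix of V_B.  Both covariance matrices carry
inverse-Wishart priors, so correlated effects let the model borrow
strength across traits.

Two inclusion structures are available:

* ``combination`` (default for t <= 5): delta_j ranges over all 2^t
  configurations with a Dirichlet(1) prior on configuration
  probabilities — a set may affect any combination of traits.
* ``per-trait``: independent Bernoulli indicators per trait, each with
  its own Beta(1,1)-distributed inclusion probability; used for t > 5
  where the 2^t mixture is wasteful.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .blr_single import GeneSetDesign, SamplerConfig

logger = logging.getLogger(__name__)

__all__ = [
    "MultiTraitResponse",
    "MultiTraitConfig",
    "MultiTraitResult",
    "fit_multi",
    "prioritize_multi",
]


@dataclass
class MultiTraitResponse:
    """Gene Z-scores for several traits aligned on a shared gene list.

    Construction is complete-case: build with :meth:`from_gene_stats`
    to drop genes missing any trait's statistic (count logged).
    """

    trait_ids: list[str]
    gene_ids: list[str]
    Y: np.ndarray

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        if Y.ndim != 2 or Y.shape != (len(self.gene_ids), len(self.trait_ids)):
            raise ValueError("Y shape must be (n_genes, n_traits)")
        if not np.all(np.isfinite(Y)):
            raise ValueError("Y contains non-finite values")
        self.Y = Y

    @classmethod
    def from_gene_stats(cls, trait_ids, per_trait_stats) -> "MultiTraitResponse":
        """Align per-trait {gene_id: z} mappings on their common genes."""
        maps = [dict(s) for s in per_trait_stats]
        common = set(maps[0])
        for mp in maps[1:]:
            common &= set(mp)
        dropped = len(set().union(*maps)) - len(common)
        if dropped:
            logger.info("complete-case alignment dropped %d genes", dropped)
        genes = sorted(common)
        Y = np.array([[mp[g] for mp in maps] for g in genes])
        return cls(list(trait_ids), genes, Y)


@dataclass
class MultiTraitConfig(SamplerConfig):
    """Sampler settings for the multi-trait model.

    ``nu_B`` / ``S_B`` and ``nu_E`` / ``S_E`` parameterize the
    inverse-Wishart priors on the effect and residual covariance
    matrices.  Left as None, they default at fit time to
    nu = t + 3 and scale matrices making the prior means
    0.5 diag(var(y_trait)) / (m pi) and 0.5 diag(var(y_trait)).
    ``diagonal_covariance=True`` constrains both covariance matrices to
    be diagonal (per-trait scaled inverse chi-square updates), which
    together with ``inclusion_model='per-trait'`` reduces the model to
    independent single-trait fits.
    """

    nu_B: float | None = None
    S_B: np.ndarray | None = None
    nu_E: float | None = None
    S_E: np.ndarray | None = None
    inclusion_model: str = "combination"
    diagonal_covariance: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.inclusion_model not in ("combination", "per-trait"):
            raise ValueError("inclusion_model must be 'combination' or 'per-trait'")
        for S, name in ((self.S_B, "S_B"), (self.S_E, "S_E")):
            if S is not None:
                S = np.asarray(S, dtype=float)
                if np.abs(S - S.T).max() > 1e-10 or np.any(np.linalg.eigvalsh(S) <= 0):
                    raise ValueError(f"{name} must be symmetric positive definite")


@dataclass
class MultiTraitResult:
    """Posterior summaries of a multi-trait fit."""

    set_ids: list[str]
    trait_ids: list[str]
    pip: np.ndarray        # m x t per-trait inclusion probabilities
    pip_any: np.ndarray    # P(included for >= 1 trait)
    B_mean: np.ndarray     # m x t posterior mean effects
    V_B_mean: np.ndarray
    V_E_mean: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def _inv_wishart(rng: np.random.Generator, nu: float, S: np.ndarray) -> np.ndarray:
    """Draw from IW(S, nu) via the Wishart of the inverse scale."""
    W = stats.wishart.rvs(df=nu, scale=np.linalg.inv(S), random_state=rng)
    W = np.atleast_2d(W)
    return np.linalg.inv(W)


def _mvn_logpdf_zero_mean(r: np.ndarray, cov: np.ndarray) -> float:
    L = np.linalg.cholesky(cov)
    sol = np.linalg.solve(L, r)
    return float(
        -0.5 * sol @ sol - np.sum(np.log(np.diag(L))) - 0.5 * r.size * np.log(2 * np.pi)
    )


def fit_multi(
    Y: MultiTraitResponse,
    design: GeneSetDesign,
    config: MultiTraitConfig,
) -> MultiTraitResult:
    """Gibbs sampler for the multi-trait spike-and-slab model.

    Per sweep, for each set j: sample the inclusion configuration
    delta_j from its collapsed full conditional (active effects
    marginalized), then the active effect sub-vector from its
    multivariate-normal full conditional with precision
    X_j'X_j [V_E^{-1}]_delta + ([V_B]_delta)^{-1}; finally V_B and V_E
    from their inverse-Wishart full conditionals and the inclusion
    prior from its Dirichlet / Beta full conditional.
    """
    t = len(Y.trait_ids)
    if t < 2:
        raise ValueError("multi-trait model needs >= 2 traits; use fit_single for one")
    if t > 9:
        raise ValueError("at most 9 traits supported")
    inclusion_model = config.inclusion_model
    if inclusion_model == "combination" and t > 5:
        logger.info("combination inclusion restricted to t <= 5; using per-trait")
        inclusion_model = "per-trait"
    if Y.Y.shape[0] != design.n_genes:
        raise ValueError("response rows do not match design rows")

    X = design.X
    n, m = X.shape
    Yc = Y.Y - Y.Y.mean(axis=0, keepdims=True)
    var_y = Yc.var(axis=0)
    var_y[var_y == 0] = 1.0

    cfg = config
    if cfg.diagonal_covariance:
        # diagonal mode mirrors the single-trait scaled-inverse-chi-square
        # priors per trait; S_B/S_E diagonals are the chi^{-1} scale params
        nu_B = cfg.nu_B if cfg.nu_B is not None else 4.0
        nu_E = cfg.nu_E if cfg.nu_E is not None else 4.0
        S_B = (
            np.asarray(cfg.S_B, dtype=float)
            if cfg.S_B is not None
            else np.diag(0.5 * var_y / (m * cfg.pi_prior) * (nu_B + 2) / nu_B)
        )
        S_E = (
            np.asarray(cfg.S_E, dtype=float)
            if cfg.S_E is not None
            else np.diag(0.5 * var_y * (nu_E + 2) / nu_E)
        )
    else:
        nu_B = cfg.nu_B if cfg.nu_B is not None else t + 3.0
        nu_E = cfg.nu_E if cfg.nu_E is not None else t + 3.0
        # prior mean of IW(S, nu) is S / (nu - t - 1)
        S_B = (
            np.asarray(cfg.S_B, dtype=float)
            if cfg.S_B is not None
            else 0.5 * np.diag(var_y) / (m * cfg.pi_prior) * (nu_B - t - 1)
        )
        S_E = (
            np.asarray(cfg.S_E, dtype=float)
            if cfg.S_E is not None
            else 0.5 * np.diag(var_y) * (nu_E - t - 1)
        )

    rng = np.random.default_rng(cfg.seed)
    xtx = np.einsum("ij,ij->j", X, X)

    B = np.zeros((m, t))
    delta = np.zeros((m, t), dtype=bool)
    V_B = S_B / max(nu_B - t - 1, 1.0)
    V_E = np.diag(var_y.copy())
    resid = Yc.copy()  # Y - X B

    if inclusion_model == "combination":
        n_cfg = 2**t
        configs = np.array([[(c >> k) & 1 for k in range(t)] for c in range(n_cfg)], dtype=bool)
        # Dirichlet prior over configurations; start near the BayesC prior
        rho = np.full(n_cfg, (1.0 - cfg.pi_prior) / max(n_cfg - 1, 1))
        rho[-1] = cfg.pi_prior  # all-traits configuration
        rho /= rho.sum()
    else:
        pi_t = np.full(t, cfg.pi_prior)

    n_keep = cfg.n_iter - cfg.burn_in
    pip_acc = np.zeros((m, t))
    any_acc = np.zeros(m)
    B_acc = np.zeros((m, t))
    VB_acc = np.zeros((t, t))
    VE_acc = np.zeros((t, t))
    trace_nincl = np.empty(n_keep)

    row_idx = [np.flatnonzero(X[:, j]) for j in range(m)]
    fast_two_trait = inclusion_model == "combination" and t == 2

    for it in range(cfg.n_iter):
        V_E_inv = np.linalg.inv(V_E)

        if fast_two_trait:
            # scalar hot path: all 2x2 algebra in closed form
            e00, e01, e11 = float(V_E[0, 0]), float(V_E[0, 1]), float(V_E[1, 1])
            i00, i01, i11 = float(V_E_inv[0, 0]), float(V_E_inv[0, 1]), float(V_E_inv[1, 1])
            vb00, vb01, vb11 = float(V_B[0, 0]), float(V_B[0, 1]), float(V_B[1, 1])
            detb = vb00 * vb11 - vb01 * vb01
            ib00, ib01, ib11 = vb11 / detb, -vb01 / detb, vb00 / detb
            lr = [math.log(max(r, 1e-300)) for r in rho]
            res0, res1 = resid[:, 0], resid[:, 1]
            for j in range(m):
                rows = row_idx[j]
                xtxj = float(xtx[j])
                b0, b1 = float(B[j, 0]), float(B[j, 1])
                r1 = float(res0[rows].sum()) + xtxj * b0
                r2 = float(res1[rows].sum()) + xtxj * b1
                x2 = xtxj * xtxj
                base00, base01, base11 = xtxj * e00, xtxj * e01, xtxj * e11
                lp = [0.0, 0.0, 0.0, 0.0]
                for c in range(4):
                    a00 = base00 + (x2 * vb00 if c & 1 else 0.0)
                    a11 = base11 + (x2 * vb11 if c & 2 else 0.0)
                    a01 = base01 + (x2 * vb01 if c == 3 else 0.0)
                    det = a00 * a11 - a01 * a01
                    quad = (a11 * r1 * r1 - 2 * a01 * r1 * r2 + a00 * r2 * r2) / det
                    lp[c] = -0.5 * (quad + math.log(det)) + lr[c]
                mx = max(lp)
                w = [math.exp(v - mx) for v in lp]
                tot = w[0] + w[1] + w[2] + w[3]
                u = rng.random() * tot
                c_new = 0
                acc = w[0]
                while acc < u and c_new < 3:
                    c_new += 1
                    acc += w[c_new]
                nb0 = nb1 = 0.0
                if c_new == 1:
                    prec = xtxj * i00 + 1.0 / vb00
                    mean = (i00 * r1 + i01 * r2) / prec
                    nb0 = mean + rng.standard_normal() / math.sqrt(prec)
                elif c_new == 2:
                    prec = xtxj * i11 + 1.0 / vb11
                    mean = (i01 * r1 + i11 * r2) / prec
                    nb1 = mean + rng.standard_normal() / math.sqrt(prec)
                elif c_new == 3:
                    p00 = xtxj * i00 + ib00
                    p01 = xtxj * i01 + ib01
                    p11 = xtxj * i11 + ib11
                    detp = p00 * p11 - p01 * p01
                    c00, c01, c11 = p11 / detp, -p01 / detp, p00 / detp
                    m1_ = i00 * r1 + i01 * r2
                    m2_ = i01 * r1 + i11 * r2
                    mu0 = c00 * m1_ + c01 * m2_
                    mu1 = c01 * m1_ + c11 * m2_
                    l00 = math.sqrt(c00)
                    l10 = c01 / l00
                    l11 = math.sqrt(max(c11 - l10 * l10, 1e-300))
                    z0, z1 = rng.standard_normal(), rng.standard_normal()
                    nb0 = mu0 + l00 * z0
                    nb1 = mu1 + l10 * z0 + l11 * z1
                if nb0 != b0:
                    res0[rows] -= nb0 - b0
                if nb1 != b1:
                    res1[rows] -= nb1 - b1
                B[j, 0], B[j, 1] = nb0, nb1
                delta[j, 0] = c_new & 1
                delta[j, 1] = c_new >> 1
        else:
            _generic_sweep(
                X, xtx, row_idx, B, delta, resid, V_B, V_E, V_E_inv, rng,
                inclusion_model, configs if inclusion_model == "combination" else None,
                rho if inclusion_model == "combination" else None,
                pi_t if inclusion_model == "per-trait" else None, t,
            )

        included = delta.any(axis=1)
        m1 = int(included.sum())

        if cfg.diagonal_covariance:
            for k in range(t):
                dk = delta[:, k]
                mk = int(dk.sum())
                if mk > 0:
                    ssb = float(np.sum(B[dk, k] ** 2))
                    V_B[k, k] = (nu_B * S_B[k, k] + ssb) / rng.chisquare(nu_B + mk)
                else:
                    V_B[k, k] = nu_B * S_B[k, k] / rng.chisquare(nu_B)
                sse = float(resid[:, k] @ resid[:, k])
                V_E[k, k] = (nu_E * S_E[k, k] + sse) / rng.chisquare(nu_E + n)
            V_B = np.diag(np.diag(V_B))
            V_E = np.diag(np.diag(V_E))
        else:
            if m1 > 0:
                SSB = B[included].T @ B[included]
                V_B = _inv_wishart(rng, nu_B + m1, S_B + SSB)
            else:
                V_B = _inv_wishart(rng, nu_B, S_B)
            SSE = resid.T @ resid
            V_E = _inv_wishart(rng, nu_E + n, S_E + SSE)

        if cfg.estimate_pi:
            if inclusion_model == "combination":
                counts = np.array(
                    [np.sum(np.all(delta == configs[c], axis=1)) for c in range(n_cfg)]
                )
                rho = rng.dirichlet(counts + 1.0)
                rho = np.clip(rho, 1e-12, None)
                rho /= rho.sum()
            else:
                for k in range(t):
                    mk = int(delta[:, k].sum())
                    pi_t[k] = rng.beta(mk + cfg.alpha[0], m - mk + cfg.alpha[1])
                pi_t = np.clip(pi_t, 1e-12, 1 - 1e-12)

        if it >= cfg.burn_in:
            pip_acc += delta
            any_acc += included
            B_acc += B
            VB_acc += V_B
            VE_acc += V_E
            trace_nincl[it - cfg.burn_in] = m1

    return MultiTraitResult(
        set_ids=list(design.set_ids),
        trait_ids=list(Y.trait_ids),
        pip=pip_acc / n_keep,
        pip_any=any_acc / n_keep,
        B_mean=B_acc / n_keep,
        V_B_mean=VB_acc / n_keep,
        V_E_mean=VE_acc / n_keep,
        diagnostics={"n_included_trace_mean": float(trace_nincl.mean())},
    )


def _generic_sweep(X, xtx, row_idx, B, delta, resid, V_B, V_E, V_E_inv, rng,
                   inclusion_model, configs, rho, pi_t, t):
    """Single-site sweep for t != 2 or per-trait inclusion (general algebra)."""
    m = X.shape[1]
    n_cfg = 0 if configs is None else len(configs)
    for j in range(m):
        xj = X[:, j]
        rhs = resid.T @ xj + xtx[j] * B[j]  # t-vector X_j'(Y - XB + X_j b_j)

        if inclusion_model == "combination":
            logp = np.empty(n_cfg)
            base = xtx[j] * V_E
            for c in range(n_cfg):
                a = configs[c]
                cov = base.copy()
                if a.any():
                    idx = np.where(a)[0]
                    cov[np.ix_(idx, idx)] += xtx[j] ** 2 * V_B[np.ix_(idx, idx)]
                logp[c] = _mvn_logpdf_zero_mean(rhs, cov) + np.log(rho[c])
            logp -= logp.max()
            p = np.exp(logp)
            p /= p.sum()
            c_new = int(np.searchsorted(np.cumsum(p), rng.random() * p.sum()))
            c_new = min(c_new, n_cfg - 1)
            a = configs[c_new]
        else:
            # per-trait indicators: single-site conditional updates,
            # collapsed over b_j for the two candidate states of each
            a = delta[j].copy()
            base = xtx[j] * V_E
            for k in range(t):
                logp2 = np.empty(2)
                for state in (0, 1):
                    a[k] = bool(state)
                    cov = base.copy()
                    if a.any():
                        idx = np.where(a)[0]
                        cov[np.ix_(idx, idx)] += xtx[j] ** 2 * V_B[np.ix_(idx, idx)]
                    prior = np.log(pi_t[k]) if state else np.log1p(-pi_t[k])
                    logp2[state] = _mvn_logpdf_zero_mean(rhs, cov) + prior
                logp2 -= logp2.max()
                p2 = np.exp(logp2)
                a[k] = rng.random() < p2[1] / p2.sum()

        old_b = B[j].copy()
        new_b = np.zeros(t)
        if a.any():
            idx = np.where(a)[0]
            if idx.size == 1:
                k = idx[0]
                prec = xtx[j] * V_E_inv[k, k] + 1.0 / V_B[k, k]
                mean = (V_E_inv[k] @ rhs) / prec
                new_b[k] = mean + rng.standard_normal() / np.sqrt(prec)
            else:
                prec = xtx[j] * V_E_inv[np.ix_(idx, idx)] + np.linalg.inv(
                    V_B[np.ix_(idx, idx)]
                )
                cov = np.linalg.inv(prec)
                mean = cov @ (V_E_inv @ rhs)[idx]
                L = np.linalg.cholesky(cov)
                new_b[idx] = mean + L @ rng.standard_normal(idx.size)
        db = new_b - old_b
        if np.any(db != 0):
            resid -= np.outer(xj, db)
        B[j] = new_b
        delta[j] = a


def prioritize_multi(
    result: MultiTraitResult,
    pip_threshold: float = 0.1,
    exclude_negative: bool = True,
) -> tuple[dict[str, list[tuple[str, float, float]]], list[dict]]:
    """Per-trait ranked association lists plus a cross-trait summary table.

    A set is flagged associated overall when its PIP passes the
    threshold for at least one trait; the negative-effect exclusion is
    applied per trait.
    """
    if not (0 <= pip_threshold <= 1):
        raise ValueError("pip_threshold must lie in [0, 1]")
    per_trait: dict[str, list[tuple[str, float, float]]] = {}
    for k, trait in enumerate(result.trait_ids):
        rows = [
            (sid, float(result.pip[j, k]), float(result.B_mean[j, k]))
            for j, sid in enumerate(result.set_ids)
            if result.pip[j, k] >= pip_threshold
            and not (exclude_negative and result.B_mean[j, k] < 0)
        ]
        rows.sort(key=lambda r: (-r[1], -abs(r[2]), r[0]))
        per_trait[trait] = rows

    cross = []
    for j, sid in enumerate(result.set_ids):
        passing = [
            trait
            for k, trait in enumerate(result.trait_ids)
            if result.pip[j, k] >= pip_threshold
            and not (exclude_negative and result.B_mean[j, k] < 0)
        ]
        if passing:
            cross.append(
                {
                    "set_id": sid,
                    "traits": passing,
                    "pip_any": float(result.pip_any[j]),
                    "max_pip": float(result.pip[j].max()),
                }
            )
    cross.sort(key=lambda r: -r["max_pip"])
    return per_trait, cross
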