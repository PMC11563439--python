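"""MAGMA-style joint linear gene-set regression, used as the comparison method.

Gene Z-scores are regressed jointly on all gene-set membership columns
(plus an intercept and optional gene-level covariates such as log gene
length and log SNP count) by ordinary least squares.  Enrichment is
directional, so per-set p-values are one-sided (H1: beta_j > 0).  This
is a transparent competitive gene-set regression in the spirit of
MAGMA's joint model, not a re-implementation of MAGMA's internals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr
import statsmodels.api as sm

from .blr_single import GeneSetDesign

__all__ = ["JointLinearResult", "fit_joint_linear", "rank_by_pvalue", "default_covariates"]


@dataclass
class JointLinearResult:
    """OLS estimates for each gene set; aliased (rank-deficient) columns are NaN."""

    set_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p_one_sided: np.ndarray
    covariate_names: list[str]
    covariate_coef: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.set_ids)
        for arr in (self.beta, self.se, self.t_stat, self.p_one_sided):
            if len(arr) != k:
                raise ValueError("field lengths inconsistent")


def default_covariates(design: GeneSetDesign, n_snps: np.ndarray, gene_length: np.ndarray):
    """log SNP count and log gene length — the confounders MAGMA conditions on."""
    n_snps = np.asarray(n_snps, dtype=float)
    gene_length = np.asarray(gene_length, dtype=float)
    C = np.column_stack([np.log(np.maximum(n_snps, 1)), np.log(np.maximum(gene_length, 1))])
    return C, ["log_n_snps", "log_gene_length"]


def fit_joint_linear(
    y: np.ndarray,
    design: GeneSetDesign,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
) -> JointLinearResult:
    """Joint OLS of gene Z-scores on [1 | covariates | X].

    Rank deficiency is resolved by pivoted QR: aliased columns (e.g. a
    duplicated set) are dropped from the fit and reported as NaN.
    """
    y = np.asarray(y, dtype=float).ravel()
    n, m = design.X.shape
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        c = covariates.shape[1]
    else:
        c = 0
    if n <= m + c + 1:
        raise ValueError(
            f"under-determined: {n} genes for {m} sets + {c} covariates + intercept "
            f"(need at least {m + c + 2} genes)"
        )

    blocks = [np.ones((n, 1))]
    if c:
        blocks.append(covariates)
    blocks.append(design.X)
    D = np.column_stack(blocks)
    p = D.shape[1]

    # detect aliased columns with pivoted QR
    _, R, piv = qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(D.shape) * np.finfo(float).eps if diag[0] > 0 else 0.0
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    aliased = np.setdiff1d(np.arange(p), keep)

    model = sm.OLS(y, D[:, keep]).fit()
    beta_full = np.full(p, np.nan)
    se_full = np.full(p, np.nan)
    t_full = np.full(p, np.nan)
    beta_full[keep] = model.params
    se_full[keep] = model.bse
    t_full[keep] = model.tvalues

    df_resid = model.df_resid
    from scipy import stats as _st

    p_full = np.full(p, np.nan)
    p_full[keep] = _st.t.sf(t_full[keep], df_resid)  # one-sided, H1: beta > 0

    off = 1 + c
    cov_names = ["intercept"] + (covariate_names or [f"cov{i}" for i in range(c)])
    return JointLinearResult(
        set_ids=list(design.set_ids),
        beta=beta_full[off:],
        se=se_full[off:],
        t_stat=t_full[off:],
        p_one_sided=p_full[off:],
        covariate_names=cov_names,
        covariate_coef=beta_full[:off],
    )


def rank_by_pvalue(result: JointLinearResult) -> list[str]:
    """Sets ordered by ascending one-sided p; ties by |t| descending, then id.

    Aliased sets (NaN p) sort last.
    """
    rows = list(zip(result.set_ids, result.p_one_sided, result.t_stat))
    rows.sort(
        key=lambda r: (
            np.isnan(r[1]),
            r[1] if not np.isnan(r[1]) else np.inf,
            -(abs(r[2]) if not np.isnan(r[2]) else 0.0),
            r[0],
        )
    )
    return [r[0] for r in rows]
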