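"""Hypergeometric enrichment of gene sets against an external gene list.

Validates prioritized gene sets against external disease-gene evidence:
given a universe of N genes, a gene set of size K and a disease list of
size M (after intersecting with the universe), the overlap k is tested
with the exact upper-tail hypergeometric probability P(X >= k).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = ["EnrichmentResult", "hypergeom_enrichment", "read_disease_list"]


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    universe_size: int
    set_size: int
    list_size: int
    overlap: int
    p_value: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.list_size):
            raise ValueError("overlap exceeds min(set size, list size)")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")


def _hypergeom_sf_logspace(k: int, N: int, M: int, K: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, M, K), summed in log space."""
    if k <= 0:
        return 1.0
    upper = min(M, K)
    if k > upper:
        return 0.0
    xs = np.arange(k, upper + 1)
    logs = stats.hypergeom.logpmf(xs, N, M, K)
    return float(min(np.exp(logsumexp(logs)), 1.0))


def hypergeom_enrichment(
    set_genes: set[str],
    disease_genes: set[str],
    universe_genes: set[str],
    set_id: str = "",
) -> EnrichmentResult:
    """Exact upper-tail overlap test of one gene set against a disease list.

    The disease list is intersected with the universe first; the set
    must be contained in the universe.
    """
    if not universe_genes:
        raise ValueError("empty universe")
    if not set_genes:
        raise ValueError("empty gene set")
    if not set_genes <= universe_genes:
        missing = sorted(set_genes - universe_genes)[:5]
        raise ValueError(f"set genes outside universe: {missing}")
    disease = disease_genes & universe_genes
    N, K, M = len(universe_genes), len(set_genes), len(disease)
    k = len(set_genes & disease)
    p = _hypergeom_sf_logspace(k, N, M, K)
    return EnrichmentResult(set_id, N, K, M, k, max(p, np.nextafter(0, 1)))


def read_disease_list(
    path: str | Path,
    score_cutoff: float | None = None,
) -> set[str]:
    """Generic two-column disease-gene list (gene_id, score) with optional cutoff.

    Channel files from disease-gene association databases (text mining,
    knowledge, experiments) are instances of this format.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene_id", "score"])
    if score_cutoff is not None:
        df = df[pd.to_numeric(df["score"], errors="coerce") >= score_cutoff]
    return set(df["gene_id"].astype(str))
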