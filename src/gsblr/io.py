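"""Readers and writers for the external formats the tool consumes.

Every reader returns validated, typed in-memory objects so downstream
modules never touch raw files.  Conventions:

* Genomic coordinates are 1-based and inclusive throughout (GTF style).
* GWAS summary files are TSV/CSV with a header; either a ``z`` column or
  ``beta`` + ``se`` columns must be present (z = beta / se is computed at
  read time).  Allele columns are carried through but never used for
  harmonization.
* LD comes as per-gene plain-text square correlation matrices, either one
  file per gene in a directory (``<gene_id>.ld``) or preloaded in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantStat",
    "GeneRecord",
    "GeneSetCollection",
    "LDMatrix",
    "FormatError",
    "ValidationError",
    "read_gwas",
    "write_gwas",
    "read_gmt",
    "write_gmt",
    "read_gtf_genes",
    "write_genes_tsv",
    "read_genes_tsv",
    "read_ld_matrix",
    "write_ld_matrix",
    "LDDirectory",
]


class FormatError(ValueError):
    """A file does not conform to its expected format."""


class ValidationError(ValueError):
    """A file parses but violates a content invariant."""


@dataclass(frozen=True)
class VariantStat:
    """One GWAS variant's summary statistic.

    ``z`` is the marker-level z-statistic; ``n`` the (optional) GWAS
    sample size.  Positions are 1-based.
    """

    variant_id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    z: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant {self.variant_id}: pos must be >= 1")
        if not np.isfinite(self.z):
            raise ValidationError(f"variant {self.variant_id}: z not finite")
        if self.n is not None and self.n <= 0:
            raise ValidationError(f"variant {self.variant_id}: n must be positive")


@dataclass(frozen=True)
class GeneRecord:
    """A gene's genomic interval (1-based, inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"  # one of {+, -, unknown}

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-", "unknown"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT semantics)."""

    sets: list[tuple[str, str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for set_id, _desc, genes in self.sets:
            if set_id in seen:
                raise ValidationError(f"duplicate set_id {set_id!r}")
            seen.add(set_id)
            if not genes:
                raise ValidationError(f"set {set_id!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"set {set_id!r} has duplicate gene ids")

    @property
    def set_ids(self) -> list[str]:
        return [s[0] for s in self.sets]

    def genes_of(self, set_id: str) -> list[str]:
        for sid, _d, genes in self.sets:
            if sid == set_id:
                return genes
        raise KeyError(set_id)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _sid, _d, genes in self.sets:
            out.update(genes)
        return out

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass
class LDMatrix:
    """Pairwise correlation matrix for the variants of one gene."""

    variant_ids: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise FormatError("LD matrix must be square")
        if K.shape[0] != len(self.variant_ids):
            raise FormatError(
                f"LD matrix size {K.shape[0]} != {len(self.variant_ids)} variant ids"
            )
        if not np.all(np.isfinite(K)):
            raise ValidationError("LD matrix has non-finite entries")
        if np.abs(K - K.T).max(initial=0.0) > 1e-8:
            raise ValidationError("LD matrix not symmetric within 1e-8")
        if np.abs(np.diag(K) - 1.0).max(initial=0.0) > 1e-6:
            raise ValidationError("LD matrix diagonal must be 1 within 1e-6")
        if np.abs(K).max(initial=0.0) > 1.0 + 1e-6:
            raise ValidationError("LD matrix entries must lie in [-1, 1]")
        self.K = K

    def subset(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self.variant_ids.index(v) for v in variant_ids]
        return LDMatrix(list(variant_ids), self.K[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

_DEFAULT_COLS = {
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "a1": "a1",
    "a2": "a2",
    "z": "z",
    "beta": "beta",
    "se": "se",
    "n": "n",
}


def read_gwas(path: str | Path, column_map: Mapping[str, str] | None = None) -> list[VariantStat]:
    """Read GWAS summary statistics from a TSV/CSV file.

    ``column_map`` maps canonical field names (``variant_id``, ``chrom``,
    ``pos``, ``a1``, ``a2``, ``z``, ``beta``, ``se``, ``n``) to the
    column names used in the file.  If no z column is present, z is
    computed as beta / se.  Rows with non-finite z are dropped (count
    logged).
    """
    cols = dict(_DEFAULT_COLS)
    if column_map:
        cols.update(column_map)
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")

    for required in ("variant_id", "chrom", "pos", "a1", "a2"):
        if cols[required] not in df.columns:
            raise FormatError(f"missing mandatory column {cols[required]!r}")

    if cols["z"] in df.columns:
        z = pd.to_numeric(df[cols["z"]], errors="coerce")
    elif cols["beta"] in df.columns and cols["se"] in df.columns:
        beta = pd.to_numeric(df[cols["beta"]], errors="coerce")
        se = pd.to_numeric(df[cols["se"]], errors="coerce")
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
    else:
        raise FormatError(
            f"need either column {cols['z']!r} or columns "
            f"{cols['beta']!r} + {cols['se']!r}"
        )

    keep = np.isfinite(z.to_numpy(dtype=float))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_gwas: dropped %d rows with non-finite z", n_dropped)
    df = df.loc[keep]
    z = z[keep]

    ids = df[cols["variant_id"]].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(f"duplicate variant_id {dup!r}")

    has_n = cols["n"] in df.columns
    out = []
    for i, (_, row) in enumerate(df.iterrows()):
        n_val = row[cols["n"]] if has_n else None
        out.append(
            VariantStat(
                variant_id=str(row[cols["variant_id"]]),
                chrom=str(row[cols["chrom"]]),
                pos=int(row[cols["pos"]]),
                a1=str(row[cols["a1"]]),
                a2=str(row[cols["a2"]]),
                z=float(z.iloc[i]),
                n=int(n_val) if n_val is not None and np.isfinite(n_val) else None,
            )
        )
    return out


def write_gwas(variants: Iterable[VariantStat], path: str | Path) -> None:
    rows = [
        (v.variant_id, v.chrom, v.pos, v.a1, v.a2, v.z, v.n if v.n is not None else "")
        for v in variants
    ]
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "a1", "a2", "z", "n"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-delimited GMT file: set_id TAB description TAB gene1 ..."""
    sets: list[tuple[str, str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT line needs >= 3 fields")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: set has no genes")
            sets.append((fields[0], fields[1], genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, desc, genes in collection:
            fh.write("\t".join([set_id, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(attr: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: unparseable GTF attribute {chunk!r}")
        key, value = parts
        out[key] = value.strip().strip('"')
    return out


def read_gtf_genes(path: str | Path) -> list[GeneRecord]:
    """Extract gene features from a GTF file (1-based inclusive coordinates).

    Strand "." is mapped to ``unknown``.  A GTF with no gene feature
    lines yields an empty list with a warning.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}: line {lineno}: GTF line needs 9 fields")
            if fields[2] != "gene":
                continue
            attrs = _parse_gtf_attributes(fields[8], lineno)
            if "gene_id" not in attrs:
                raise FormatError(f"{path}: line {lineno}: gene feature lacks gene_id")
            gene_id = attrs["gene_id"]
            if gene_id in seen:
                raise ValidationError(f"{path}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            strand = fields[6]
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    chrom=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=strand if strand in ("+", "-") else "unknown",
                )
            )
    if not genes:
        logger.warning("read_gtf_genes: no gene features found in %s", path)
    return genes


def write_genes_tsv(genes: Iterable[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_genes_tsv(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        GeneRecord(str(r.gene_id), str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# LD matrices
# ---------------------------------------------------------------------------

def read_ld_matrix(path: str | Path, variant_ids: Sequence[str]) -> LDMatrix:
    """Read a whitespace-delimited square correlation matrix.

    The matrix is symmetrized as (K + K') / 2 before validation, which
    silently absorbs asymmetries below the 1e-8 tolerance.
    """
    K = np.loadtxt(path, ndmin=2)
    if K.shape[0] != K.shape[1]:
        raise FormatError(f"{path}: LD matrix is {K.shape[0]}x{K.shape[1]}, not square")
    if K.shape[0] != len(variant_ids):
        raise FormatError(
            f"{path}: matrix has {K.shape[0]} rows, expected {len(variant_ids)}"
        )
    if np.abs(K).max(initial=0.0) > 1.0 + 1e-6:
        raise ValidationError(f"{path}: correlation entry outside [-1, 1]")
    K = 0.5 * (K + K.T)
    return LDMatrix(list(variant_ids), K)


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    np.savetxt(path, ld.K, fmt="%.12g")


class LDDirectory:
    """Per-gene LD source backed by a directory of ``<gene_id>.ld`` files.

    Acts as a mapping gene_id -> LDMatrix; the variant ids covered by
    each gene must be supplied at lookup time (they come from the
    variant-to-gene mapping).
    """

    def __init__(self, directory: str | Path, suffix: str = ".ld"):
        self.directory = Path(directory)
        self.suffix = suffix

    def __contains__(self, gene_id: str) -> bool:
        return (self.directory / f"{gene_id}{self.suffix}").exists()

    def get(self, gene_id: str, variant_ids: Sequence[str]) -> LDMatrix:
        path = self.directory / f"{gene_id}{self.suffix}"
        if not path.exists():
            raise KeyError(gene_id)
        return read_ld_matrix(path, variant_ids)
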