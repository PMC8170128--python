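"""Similarity matrices for gene co-expression modules.

A module's network structure within one phenotype group is summarised by a
symmetric gene × gene similarity matrix: either the Spearman rank
correlation, or the signed topological overlap measure (TOM) built from the
signed adjacency a_ij = |(1 + corr_ij)/2|**beta.  Every module-level test
statistic downstream consumes the strict lower triangles of the two
group-wise similarity matrices, vectorized in a fixed column-major order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ExpressionMatrix",
    "SimilarityMatrix",
    "PairedLowerTriangle",
    "spearman_correlation",
    "signed_adjacency",
    "signed_tom",
    "vectorize_pair",
    "lower_triangle",
]

#: default exponent for the signed adjacency; kept at 1 so that differences
#: between correlation- and TOM-based tests reflect neighbourhood averaging
#: rather than the soft-thresholding power.
DEFAULT_BETA = 1.0


@dataclass
class ExpressionMatrix:
    """N samples × P genes expression matrix for one phenotype group.

    Values may be counts or continuous intensities; genes are columns.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    group_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} gene columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} sample rows")
        if len(set(self.gene_ids)) != p:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {', '.join(dupes)}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to the given genes, preserving the requested order."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in expression matrix: {', '.join(missing)}")
        cols = [index[g] for g in genes]
        return ExpressionMatrix(
            self.values[:, cols], list(genes), list(self.sample_ids), self.group_label
        )


@dataclass
class SimilarityMatrix:
    """Symmetric P × P gene similarity matrix.

    ``kind`` is one of ``spearman`` (entries in [-1, 1]), ``signed_adjacency``
    or ``signed_tom`` (entries in [0, 1]); the diagonal is 1.
    """

    values: np.ndarray
    kind: str
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("similarity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if not self.gene_ids:
            self.gene_ids = [f"g{i + 1}" for i in range(p)]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass
class PairedLowerTriangle:
    """The two vectorized strict lower triangles compared by every statistic.

    Both vectors share one fixed entry ordering (column-major over the strict
    lower triangle, i.e. (2,1), (3,1), ..., (P,1), (3,2), ...); all statistics
    are permutation-invariant over entries, so only consistency matters.
    """

    v1: np.ndarray
    v2: np.ndarray

    def __post_init__(self) -> None:
        self.v1 = np.asarray(self.v1, dtype=float).ravel()
        self.v2 = np.asarray(self.v2, dtype=float).ravel()
        if self.v1.shape != self.v2.shape:
            raise ValueError("paired triangles must have equal length")

    @property
    def lam(self) -> int:
        """Number of unique off-diagonal entries, P(P-1)/2."""
        return self.v1.size


def lower_triangle(matrix: np.ndarray) -> np.ndarray:
    """Strict lower triangle of a symmetric matrix in column-major order."""
    m = np.asarray(matrix, dtype=float)
    p = m.shape[0]
    # column-major over the lower triangle == row-major over the upper triangle
    iu = np.triu_indices(p, k=1)
    return m.T[iu]


def pack_lower_triangle(v: np.ndarray, p: int) -> np.ndarray:
    """Inverse of :func:`lower_triangle`: rebuild a symmetric unit-diagonal matrix."""
    v = np.asarray(v, dtype=float)
    if v.size != p * (p - 1) // 2:
        raise ValueError("vector length does not match P(P-1)/2")
    m = np.eye(p)
    iu = np.triu_indices(p, k=1)
    m[iu] = v
    m.T[iu] = v
    return m


def rank_columns(values: np.ndarray) -> np.ndarray:
    """Average (mid-) ranks of each column of a samples × genes matrix."""
    return _sps.rankdata(values, axis=0)


def spearman_correlation(expr: ExpressionMatrix) -> SimilarityMatrix:
    """Spearman rank correlation matrix of the module's genes.

    Ties receive average ranks.  A gene with constant expression has no
    defined rank correlation and raises a ``ValueError`` naming the gene.
    """
    x = expr.values
    n, p = x.shape
    if n < 3:
        raise ValueError("at least 3 samples are required for Spearman correlation")
    if p < 2:
        raise ValueError("at least 2 genes are required")
    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        names = [expr.gene_ids[j] for j in np.flatnonzero(constant)]
        raise ValueError(
            f"constant expression makes Spearman correlation undefined for: {', '.join(names)}"
        )
    ranks = rank_columns(x)
    z = ranks - ranks.mean(axis=0)
    norms = np.sqrt((z**2).sum(axis=0))
    corr = (z.T @ z) / np.outer(norms, norms)
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return SimilarityMatrix(corr, "spearman", list(expr.gene_ids))


def signed_adjacency(corr: SimilarityMatrix, beta: float = DEFAULT_BETA) -> SimilarityMatrix:
    """Signed adjacency a_ij = |(1 + corr_ij)/2|**beta with unit diagonal."""
    if corr.kind != "spearman":
        raise ValueError(f"signed adjacency expects a spearman matrix, got {corr.kind!r}")
    if beta <= 0:
        raise ValueError("beta must be positive")
    a = np.abs((1.0 + corr.values) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return SimilarityMatrix(a, "signed_adjacency", list(corr.gene_ids))


def tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Signed TOM from an adjacency matrix with unit diagonal (array form).

    TOM_ij = (a_ij + sum_{u != i,j} a_iu a_uj) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu; the diagonal is set to 1.
    """
    a = np.asarray(a, dtype=float)
    p = a.shape[0]
    if p < 3:
        raise ValueError("TOM requires at least 3 genes (no shared neighbors otherwise)")
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    sq = a @ a
    # remove the u = i and u = j terms, each contributing a_ij (unit diagonal)
    shared = sq - 2.0 * a
    k = a.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    # off-diagonal denominators are >= 1 (k_i >= a_ij); the diagonal may hit
    # 0/0 for an isolated gene and is overwritten below
    with np.errstate(invalid="ignore"):
        tom = (a + shared) / denom
    np.fill_diagonal(tom, 1.0)
    return (tom + tom.T) / 2.0


def signed_tom(adj: SimilarityMatrix) -> SimilarityMatrix:
    """Signed topological overlap matrix; rewards shared neighbourhoods."""
    if adj.kind != "signed_adjacency":
        raise ValueError(f"signed TOM expects a signed_adjacency matrix, got {adj.kind!r}")
    if (adj.values < -1e-12).any() or (adj.values > 1 + 1e-12).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    return SimilarityMatrix(tom_from_adjacency(adj.values), "signed_tom", list(adj.gene_ids))


def similarity_from_expression(expr: ExpressionMatrix, kind: str = "spearman") -> SimilarityMatrix:
    """One-call similarity: ``spearman`` or ``signed_tom`` (beta = 1)."""
    corr = spearman_correlation(expr)
    if kind == "spearman":
        return corr
    if kind in ("signed_tom", "tom"):
        return signed_tom(signed_adjacency(corr))
    raise ValueError(f"unknown similarity kind {kind!r}")


def vectorize_pair(s1: SimilarityMatrix, s2: SimilarityMatrix) -> PairedLowerTriangle:
    """Strict lower triangles of both matrices, identical entry order."""
    if s1.gene_ids != s2.gene_ids:
        raise ValueError("similarity matrices have mismatched gene orderings")
    return PairedLowerTriangle(lower_triangle(s1.values), lower_triangle(s2.values))
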