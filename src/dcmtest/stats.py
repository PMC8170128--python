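"""Module-level two-group test statistics.

All statistics except GSNCA are functions of the paired lower-triangle
vectors V1, V2 of the two group-wise similarity matrices (length
lambda = P(P-1)/2).  Writing d_k = v1_k - v2_k:

* DI        — mean(d^2), the dispersion index (PND with p = 2, squared)
* MAD       — mean(|d|)
* PND(p)    — (mean(|d|^p))^(1/p), the p-norm difference statistic; large p
              concentrates weight on the largest changed edges, which helps
              when only a small fraction of a module's edges change
* pairedT   — mean(d) * sqrt(lambda) / sqrt(mean(d^2)); the denominator is
              the uncentered root-mean-square of the differences
* wilcoxSRT — Wilcoxon signed-rank W+ of the differences (zeros dropped,
              average ranks for ties)
* QAP       — mean(v1 * v2), a similarity score (smaller = more different)
* GCOR      — sum of products of the centered vectors (unnormalized)
* GHD       — mean squared difference of the centered vectors
* GSNCA     — L1 distance between per-group gene weight vectors, where a
              gene's weight is its normalized absolute-similarity row sum

None of these has a tractable null distribution under the dependence
induced by a correlation matrix; all are calibrated by the permutation
engine in :mod:`dcmtest.permutation`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .similarity import PairedLowerTriangle, SimilarityMatrix

__all__ = [
    "StatisticSpec",
    "StatisticValue",
    "stat_di",
    "stat_mad",
    "stat_pnd",
    "stat_paired_t",
    "stat_wilcoxon_sr",
    "stat_qap",
    "stat_gcor",
    "stat_ghd",
    "stat_gsnca",
    "compute_statistic",
    "parse_stat_names",
    "STATISTIC_NAMES",
]

#: exponents offered for the p-norm difference test
DEFAULT_PND_EXPONENTS = (4, 6, 8, 20)

STATISTIC_NAMES = (
    "PND",
    "DI",
    "MAD",
    "pairedT",
    "wilcoxSRT",
    "QAP",
    "GCOR",
    "GHD",
    "GSNCA",
)

_DIRECTIONS = {
    "PND": "larger_is_more_different",
    "DI": "larger_is_more_different",
    "MAD": "larger_is_more_different",
    "GHD": "larger_is_more_different",
    "GSNCA": "larger_is_more_different",
    "pairedT": "signed",
    "wilcoxSRT": "signed",
    "QAP": "similarity",
    "GCOR": "similarity",
}


@dataclass(frozen=True)
class StatisticSpec:
    """A statistic request: name plus, for PND, the exponent."""

    name: str
    p_exponent: float | None = None

    def __post_init__(self) -> None:
        if self.name not in STATISTIC_NAMES:
            raise ValueError(f"unknown statistic {self.name!r}")
        if self.name == "PND":
            if self.p_exponent is None:
                object.__setattr__(self, "p_exponent", 6.0)
            if self.p_exponent < 1:
                raise ValueError("PND exponent must be >= 1")
        elif self.p_exponent is not None:
            raise ValueError(f"p_exponent only applies to PND, not {self.name}")

    @property
    def label(self) -> str:
        if self.name == "PND":
            p = self.p_exponent
            return f"PND{int(p)}" if float(p) == int(p) else f"PND{p}"
        return self.name

    @classmethod
    def from_label(cls, label: str) -> "StatisticSpec":
        label = label.strip()
        if label.upper().startswith("PND") and len(label) > 3:
            return cls("PND", float(label[3:]))
        for name in STATISTIC_NAMES:
            if label.lower() == name.lower():
                return cls(name)
        raise ValueError(f"unknown statistic {label!r}")


@dataclass(frozen=True)
class StatisticValue:
    value: float
    name: str
    direction: str


def _wrap(value: float, name: str) -> StatisticValue:
    return StatisticValue(float(value), name, _DIRECTIONS[name])


def stat_di(pair: PairedLowerTriangle) -> StatisticValue:
    """Dispersion index: mean squared difference of the triangle vectors."""
    d = pair.v1 - pair.v2
    return _wrap(np.mean(d**2), "DI")


def stat_mad(pair: PairedLowerTriangle) -> StatisticValue:
    """Mean absolute difference of the triangle vectors."""
    return _wrap(np.mean(np.abs(pair.v1 - pair.v2)), "MAD")


def stat_pnd(pair: PairedLowerTriangle, p: float) -> StatisticValue:
    """p-norm difference statistic, (mean |v1 - v2|^p)^(1/p)."""
    if p < 1:
        raise ValueError("PND exponent must be >= 1")
    d = np.abs(pair.v1 - pair.v2)
    return _wrap(np.mean(d**p) ** (1.0 / p), "PND")


def stat_paired_t(pair: PairedLowerTriangle) -> StatisticValue:
    """Paired t-type statistic with uncentered RMS denominator.

    All-zero differences yield the statistic's null anchor 0 (so the
    permutation p-value is 1) rather than a 0/0.
    """
    d = pair.v1 - pair.v2
    rms = np.sqrt(np.mean(d**2))
    if rms == 0:
        return _wrap(0.0, "pairedT")
    return _wrap(np.mean(d) * np.sqrt(d.size) / rms, "pairedT")


def stat_wilcoxon_sr(pair: PairedLowerTriangle) -> StatisticValue:
    """Wilcoxon signed-rank W+: sum of ranks of the positive differences.

    Zero differences are dropped and tied absolute differences receive
    average ranks (the base-R wilcox.test convention).  Differences are
    rounded to 10 decimal places first so that exact zeros and exact ties of
    rank-correlation values (which are rationals) survive floating-point
    noise in the similarity computation.
    """
    d = np.round(pair.v1 - pair.v2, 10)
    d = d[d != 0]
    if d.size == 0:
        return _wrap(0.0, "wilcoxSRT")
    ranks = _sps.rankdata(np.abs(d))
    return _wrap(ranks[d > 0].sum(), "wilcoxSRT")


def stat_qap(pair: PairedLowerTriangle) -> StatisticValue:
    """Quadratic assignment cross-product, mean(v1 * v2)."""
    return _wrap(np.mean(pair.v1 * pair.v2), "QAP")


def stat_gcor(pair: PairedLowerTriangle) -> StatisticValue:
    """Unnormalized sum of products of the centered triangle vectors."""
    c1 = pair.v1 - pair.v1.mean()
    c2 = pair.v2 - pair.v2.mean()
    return _wrap(np.sum(c1 * c2), "GCOR")


def stat_ghd(pair: PairedLowerTriangle) -> StatisticValue:
    """Generalized Hamming distance: mean squared difference after centering."""
    c1 = pair.v1 - pair.v1.mean()
    c2 = pair.v2 - pair.v2.mean()
    return _wrap(np.mean((c1 - c2) ** 2), "GHD")


def gsnca_weights(s: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Per-gene weights: normalized absolute-similarity row sums (diag excluded)."""
    m = s.values if isinstance(s, SimilarityMatrix) else np.asarray(s, dtype=float)
    raw = np.abs(m).sum(axis=1) - np.abs(np.diag(m))
    total = raw.sum()
    if total == 0:
        raise ValueError("all off-diagonal similarities are zero; GSNCA weights undefined")
    return raw / total


def stat_gsnca(s1: SimilarityMatrix, s2: SimilarityMatrix) -> StatisticValue:
    """GSNCA-style statistic: L1 distance between the groups' weight vectors.

    Unlike the difference-based statistics this consumes the full similarity
    matrices, since the weights are row sums rather than edge differences.
    """
    if isinstance(s1, SimilarityMatrix) and isinstance(s2, SimilarityMatrix):
        if s1.gene_ids != s2.gene_ids:
            raise ValueError("similarity matrices have mismatched gene orderings")
        if s1.n_genes < 3:
            raise ValueError("GSNCA requires at least 3 genes")
    w1 = gsnca_weights(s1)
    w2 = gsnca_weights(s2)
    return _wrap(np.abs(w1 - w2).sum(), "GSNCA")


def compute_statistic(
    spec: StatisticSpec,
    s1: SimilarityMatrix,
    s2: SimilarityMatrix,
    pair: PairedLowerTriangle | None = None,
) -> StatisticValue:
    """Registry dispatch: evaluate any statistic from the two similarity matrices."""
    if spec.name == "GSNCA":
        return stat_gsnca(s1, s2)
    if pair is None:
        from .similarity import vectorize_pair

        pair = vectorize_pair(s1, s2)
    if spec.name == "PND":
        return stat_pnd(pair, spec.p_exponent)
    fn = {
        "DI": stat_di,
        "MAD": stat_mad,
        "pairedT": stat_paired_t,
        "wilcoxSRT": stat_wilcoxon_sr,
        "QAP": stat_qap,
        "GCOR": stat_gcor,
        "GHD": stat_ghd,
    }[spec.name]
    return fn(pair)


def parse_stat_names(spec_string: str) -> list[StatisticSpec]:
    """Parse a comma list like ``"PND4,PND6,DI,MAD"`` into statistic specs."""
    return [StatisticSpec.from_label(tok) for tok in spec_string.split(",") if tok.strip()]
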