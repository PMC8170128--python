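"""Permutation calibration of module-level statistics.

The elements of a similarity matrix's lower triangle are mutually dependent,
so none of the module statistics has a usable closed-form null distribution.
Calibration is by group-label permutation at the sample level: the two
expression matrices are pooled, labels are reshuffled preserving group
sizes, the similarity matrices are recomputed from scratch for each shuffle,
and the statistic is recomputed.  The p-value is

    p = [ sum_b I(|theta(b)| >= |theta|) + 1 ] / (B + 1)

which is two-sided in |theta| for every statistic and never smaller than
1/(B+1).

The engine below vectorizes the B shuffles in chunks.  Within-group Spearman
ranks are obtained by double argsort, which equals average (mid-) ranking
whenever the pooled expression values are tie-free within every gene; if any
gene column contains ties the engine falls back to true mid-ranks per
shuffle.  Either way each shuffle's similarity is computed from its own
within-group ranks — nothing is cached across groupings except the tie
check, which is a property of the pooled data alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .similarity import ExpressionMatrix, similarity_from_expression, vectorize_pair
from .stats import StatisticSpec, compute_statistic

__all__ = [
    "PermutationConfig",
    "ModuleTestResult",
    "permutation_test",
    "permutation_test_multi",
    "permuted_statistics",
    "fdr_adjust",
    "derive_module_seed",
]


@dataclass
class PermutationConfig:
    """Settings for one permutation run.

    ``n_permutations`` defaults to 3000 (simulation scale); data analyses
    typically use 10000.  ``on_degenerate`` controls what happens when a
    shuffle produces a constant gene within a permuted group (impossible for
    continuous data): ``error`` raises, ``redraw`` replaces the shuffle and
    counts it.
    """

    n_permutations: int = 3000
    seed: int = 0
    similarity_kind: str = "spearman"
    on_degenerate: str = "error"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if self.similarity_kind not in ("spearman", "signed_tom", "tom"):
            raise ValueError(f"unknown similarity kind {self.similarity_kind!r}")
        if self.on_degenerate not in ("error", "redraw"):
            raise ValueError("on_degenerate must be 'error' or 'redraw'")


@dataclass
class ModuleTestResult:
    module_id: str
    statistic_name: str
    observed_value: float
    p_value: float
    fdr: float = float("nan")
    n_genes: int = 0
    n_samples_per_group: tuple[int, int] = (0, 0)
    n_permutations: int = 0
    n_redrawn: int = 0


def derive_module_seed(seed: int, module_id: str) -> np.random.SeedSequence:
    """Deterministic per-module random stream from (master seed, module id).

    Module-level results therefore do not depend on the order modules are
    iterated in.
    """
    tag = zlib.crc32(str(module_id).encode("utf-8")) & 0x7FFFFFFF
    return np.random.SeedSequence([int(seed), tag])


# ---------------------------------------------------------------------------
# vectorized engine internals


def _has_ties(pooled: np.ndarray) -> bool:
    s = np.sort(pooled, axis=0)
    return bool((np.diff(s, axis=0) == 0).any())


def _ordinal_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n along axis 1 of a (B, n, P) array; equals mid-ranks iff tie-free."""
    return np.argsort(np.argsort(x, axis=1), axis=1) + 1.0


def _mid_ranks_loop(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    for b in range(x.shape[0]):
        out[b] = _sps.rankdata(x[b], axis=0)
    return out


def _corr_from_ranks(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation over axis 1 of (B, n, P) rank arrays.

    Returns (correlations of shape (B, P, P), mask of degenerate batch
    members containing a zero-variance column).
    """
    z = r - r.mean(axis=1, keepdims=True)
    norms = np.sqrt((z**2).sum(axis=1))  # (B, P)
    bad = (norms == 0).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = z / norms[:, None, :]
    c = np.matmul(np.ascontiguousarray(z.transpose(0, 2, 1)), z)
    return c, bad


def _tom_batch(corr: np.ndarray) -> np.ndarray:
    """Signed TOM (beta = 1) for a (B, P, P) batch of correlation matrices."""
    a = (1.0 + corr) / 2.0
    np.clip(a, 0.0, 1.0, out=a)
    b_, p, _ = a.shape
    idx = np.arange(p)
    a[:, idx, idx] = 1.0
    sq = np.matmul(a, a)
    shared = sq - 2.0 * a
    k = a.sum(axis=2) - 1.0
    denom = np.minimum(k[:, :, None], k[:, None, :]) + 1.0 - a
    with np.errstate(invalid="ignore"):  # isolated-gene diagonal, overwritten below
        tom = (a + shared) / denom
    tom[:, idx, idx] = 1.0
    return tom


def _avg_ranks_rows(x: np.ndarray) -> np.ndarray:
    """Average ranks along axis 1 of a 2-D array, tie-aware but fast when tie-free."""
    ranks = np.argsort(np.argsort(x, axis=1), axis=1) + 1.0
    s = np.sort(x, axis=1)
    tied = (np.diff(s, axis=1) == 0).any(axis=1)
    if tied.any():
        for i in np.flatnonzero(tied):
            ranks[i] = _sps.rankdata(x[i])
    return ranks


def _batch_statistics(specs: list[StatisticSpec], s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Evaluate every requested statistic on (B, P, P) similarity batches.

    Returns an array of shape (B, len(specs)).  Mirrors the scalar functions
    in :mod:`dcmtest.stats`; agreement is enforced by the test suite.
    """
    p = s1.shape[1]
    iu = np.triu_indices(p, k=1)
    v1 = s1[:, iu[0], iu[1]]
    v2 = s2[:, iu[0], iu[1]]
    d = v1 - v2
    lam = d.shape[1]
    out = np.empty((s1.shape[0], len(specs)))
    for j, spec in enumerate(specs):
        name = spec.name
        if name == "PND":
            out[:, j] = np.mean(np.abs(d) ** spec.p_exponent, axis=1) ** (1.0 / spec.p_exponent)
        elif name == "DI":
            out[:, j] = np.mean(d**2, axis=1)
        elif name == "MAD":
            out[:, j] = np.mean(np.abs(d), axis=1)
        elif name == "pairedT":
            rms = np.sqrt(np.mean(d**2, axis=1))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.mean(d, axis=1) * np.sqrt(lam) / rms
            out[:, j] = np.where(rms == 0, 0.0, t)
        elif name == "wilcoxSRT":
            # same 10-decimal rounding as the scalar statistic (zero/tie robustness)
            dr = np.round(d, 10)
            absd = np.abs(dr)
            zero_rows = (dr == 0).any(axis=1)
            ranks = _avg_ranks_rows(absd)
            w = np.where(dr > 0, ranks, 0.0).sum(axis=1)
            # rows containing exact zero differences need the drop-zeros rule
            for i in np.flatnonzero(zero_rows):
                di = dr[i][dr[i] != 0]
                w[i] = _sps.rankdata(np.abs(di))[di > 0].sum() if di.size else 0.0
            out[:, j] = w
        elif name == "QAP":
            out[:, j] = np.mean(v1 * v2, axis=1)
        elif name == "GCOR":
            c1 = v1 - v1.mean(axis=1, keepdims=True)
            c2 = v2 - v2.mean(axis=1, keepdims=True)
            out[:, j] = np.sum(c1 * c2, axis=1)
        elif name == "GHD":
            c = d - d.mean(axis=1, keepdims=True)
            out[:, j] = np.mean(c**2, axis=1)
        elif name == "GSNCA":
            r1 = np.abs(s1).sum(axis=2) - 1.0
            r2 = np.abs(s2).sum(axis=2) - 1.0
            w1 = r1 / r1.sum(axis=1, keepdims=True)
            w2 = r2 / r2.sum(axis=1, keepdims=True)
            out[:, j] = np.abs(w1 - w2).sum(axis=1)
        else:  # pragma: no cover
            raise ValueError(name)
    return out


def permuted_statistics(
    pooled: np.ndarray,
    n1: int,
    specs: list[StatisticSpec],
    cfg: PermutationConfig,
    rng: np.random.Generator,
    chunk: int = 512,
) -> tuple[np.ndarray, int]:
    """Statistics for B label shuffles of pooled samples × genes data.

    Returns (array of shape (B, len(specs)), number of redrawn shuffles).
    """
    n = pooled.shape[0]
    b_total = cfg.n_permutations
    ties = _has_ties(pooled)
    use_tom = cfg.similarity_kind in ("signed_tom", "tom")
    results = np.empty((b_total, len(specs)))
    n_redrawn = 0
    done = 0
    while done < b_total:
        c = min(chunk, b_total - done)
        idx = np.argsort(rng.random((c, n)), axis=1)
        for _attempt in range(100):
            data = pooled[idx]
            g1, g2 = data[:, :n1], data[:, n1:]
            r1 = _mid_ranks_loop(g1) if ties else _ordinal_ranks(g1)
            r2 = _mid_ranks_loop(g2) if ties else _ordinal_ranks(g2)
            c1, bad1 = _corr_from_ranks(r1)
            c2, bad2 = _corr_from_ranks(r2)
            bad = bad1 | bad2
            if not bad.any():
                break
            if cfg.on_degenerate == "error":
                raise ValueError(
                    "a permuted group contains a constant gene; "
                    "set on_degenerate='redraw' to resample such shuffles"
                )
            n_redrawn += int(bad.sum())
            idx[bad] = np.argsort(rng.random((int(bad.sum()), n)), axis=1)
        else:
            raise RuntimeError("could not draw a non-degenerate shuffle in 100 attempts")
        if use_tom:
            c1, c2 = _tom_batch(c1), _tom_batch(c2)
        results[done : done + c] = _batch_statistics(specs, c1, c2)
        done += c
    return results, n_redrawn


# ---------------------------------------------------------------------------
# public API


def permutation_test_multi(
    x1: ExpressionMatrix,
    x2: ExpressionMatrix,
    specs: list[StatisticSpec],
    cfg: PermutationConfig,
    module_id: str = "module",
) -> list[ModuleTestResult]:
    """Permutation-calibrate several statistics sharing one set of shuffles.

    The observed statistics are computed through the reference scalar path;
    the shuffled ones through the vectorized engine (the suite checks the
    two paths agree).  Sharing shuffles across statistics is both cheaper
    and what a single-pass analysis of one module does naturally.
    """
    if x1.gene_ids != x2.gene_ids:
        raise ValueError("the two groups must share the same genes in the same order")
    if x1.n_samples < 3 or x2.n_samples < 3:
        raise ValueError("each group needs at least 3 samples")
    s1 = similarity_from_expression(x1, cfg.similarity_kind)
    s2 = similarity_from_expression(x2, cfg.similarity_kind)
    pair = vectorize_pair(s1, s2)
    observed = np.array(
        [compute_statistic(spec, s1, s2, pair).value for spec in specs]
    )

    pooled = np.vstack([x1.values, x2.values])
    rng = np.random.Generator(np.random.PCG64(derive_module_seed(cfg.seed, module_id)))
    perm_stats, n_redrawn = permuted_statistics(pooled, x1.n_samples, specs, cfg, rng)

    b = cfg.n_permutations
    exceed = (np.abs(perm_stats) >= np.abs(observed)[None, :]).sum(axis=0)
    pvals = (exceed + 1.0) / (b + 1.0)
    return [
        ModuleTestResult(
            module_id=module_id,
            statistic_name=spec.label,
            observed_value=float(observed[j]),
            p_value=float(pvals[j]),
            n_genes=x1.n_genes,
            n_samples_per_group=(x1.n_samples, x2.n_samples),
            n_permutations=b,
            n_redrawn=n_redrawn,
        )
        for j, spec in enumerate(specs)
    ]


def permutation_test(
    x1: ExpressionMatrix,
    x2: ExpressionMatrix,
    spec: StatisticSpec,
    cfg: PermutationConfig,
    module_id: str = "module",
) -> ModuleTestResult:
    """Permutation test of one statistic for one module (see module docstring)."""
    return permutation_test_multi(x1, x2, [spec], cfg, module_id)[0]


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
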