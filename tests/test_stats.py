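"""Module statistics: worked examples, identities, symmetries, loop oracle."""

import math

import numpy as np
import pytest

from dcmtest import (
    PairedLowerTriangle,
    SimilarityMatrix,
    StatisticSpec,
    compute_statistic,
    parse_stat_names,
    stat_di,
    stat_gcor,
    stat_ghd,
    stat_gsnca,
    stat_mad,
    stat_paired_t,
    stat_pnd,
    stat_qap,
    stat_wilcoxon_sr,
)

V1 = (0.5, 0.5, 0.5)
V2 = (0.1, 0.5, 0.9)


def pair(v1, v2):
    return PairedLowerTriangle(np.asarray(v1, float), np.asarray(v2, float))


# ---------------------------------------------------------------------------
# independent loop-based oracle (naive Python, no numpy vectorization)


def oracle(name, v1, v2, p=None):
    lam = len(v1)
    d = [a - b for a, b in zip(v1, v2)]
    if name == "DI":
        return sum(x * x for x in d) / lam
    if name == "MAD":
        return sum(abs(x) for x in d) / lam
    if name == "PND":
        return (sum(abs(x) ** p for x in d) / lam) ** (1.0 / p)
    if name == "pairedT":
        rms = math.sqrt(sum(x * x for x in d) / lam)
        return 0.0 if rms == 0 else (sum(d) / lam) * math.sqrt(lam) / rms
    if name == "wilcoxSRT":
        nz = [x for x in d if x != 0]
        if not nz:
            return 0.0
        ordered = sorted(abs(x) for x in nz)
        ranks = []
        for x in nz:
            matches = [i + 1 for i, v in enumerate(ordered) if v == abs(x)]
            ranks.append(sum(matches) / len(matches))
        return sum(r for r, x in zip(ranks, nz) if x > 0)
    if name == "QAP":
        return sum(a * b for a, b in zip(v1, v2)) / lam
    if name == "GCOR":
        m1, m2 = sum(v1) / lam, sum(v2) / lam
        return sum((a - m1) * (b - m2) for a, b in zip(v1, v2))
    if name == "GHD":
        m1, m2 = sum(v1) / lam, sum(v2) / lam
        return sum(((a - m1) - (b - m2)) ** 2 for a, b in zip(v1, v2)) / lam
    raise ValueError(name)


class TestWorkedExamples:
    @pytest.mark.parametrize(
        "fn, v1, v2, expected",
        [
            (stat_di, V1, V2, 0.32 / 3),
            (stat_di, (0.4,), (0.0,), 0.16),
            (stat_mad, V1, V2, 0.8 / 3),
            (stat_mad, (0.4,), (0.0,), 0.4),
            (stat_qap, V1, V2, 0.25),
            (stat_qap, (1, 1, 1), (1, 1, 1), 1.0),
            (stat_qap, V1, (0, 0, 0), 0.0),
            (stat_gcor, (0, 1), (0, 1), 0.5),
            (stat_gcor, (0, 1), (1, 0), -0.5),
            (stat_gcor, (0.3, 0.3), (0, 1), 0.0),
            (stat_ghd, V1, V2, 0.32 / 3),
        ],
    )
    def test_closed_form(self, fn, v1, v2, expected):
        assert fn(pair(v1, v2)).value == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_pnd4_worked_example(self):
        got = stat_pnd(pair(V1, V2), 4).value
        assert got == pytest.approx((0.0512 / 3) ** 0.25, rel=1e-10)
        assert got == pytest.approx(0.36144, abs=5e-6)

    def test_zero_for_identical_inputs(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(-1, 1, 10)
        pr = pair(v, v)
        for fn in (stat_di, stat_mad, stat_ghd, stat_paired_t, stat_wilcoxon_sr):
            assert fn(pr).value == 0.0
        assert stat_pnd(pr, 6).value == 0.0

    def test_ghd_ignores_constant_shift(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(-1, 1, 8)
        assert stat_ghd(pair(v, v + 0.37)).value == pytest.approx(0.0, abs=1e-15)

    def test_paired_t_cases(self):
        assert stat_paired_t(pair((0.4, 0.0, -0.4), (0, 0, 0))).value == pytest.approx(0.0)
        # constant differences c: statistic = sign(c) * sqrt(lam)
        lam = 7
        got = stat_paired_t(pair([0.3] * lam, [0.1] * lam)).value
        assert got == pytest.approx(math.sqrt(lam), rel=1e-12)
        got = stat_paired_t(pair([0.1] * lam, [0.3] * lam)).value
        assert got == pytest.approx(-math.sqrt(lam), rel=1e-12)

    def test_wilcoxon_cases(self):
        # zeros dropped, tied |d| share rank 1.5, only the positive one counts
        assert stat_wilcoxon_sr(pair((0.4, 0.0, -0.4), (0, 0, 0))).value == pytest.approx(1.5)
        # all positive, no ties -> m(m+1)/2
        v1 = (0.5, 0.6, 0.7, 0.8)
        assert stat_wilcoxon_sr(pair(v1, (0.1, 0.3, 0.2, 0.4))).value == pytest.approx(10)
        # all negative -> 0
        assert stat_wilcoxon_sr(pair((0.1, 0.2), (0.5, 0.9))).value == 0.0


class TestGsnca:
    def test_worked_example(self):
        s1 = SimilarityMatrix(np.array([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]]),
                              "spearman")
        s2 = SimilarityMatrix(np.array([[1, 0.9, 0.9], [0.9, 1, 0.1], [0.9, 0.1, 1]]),
                              "spearman")
        got = stat_gsnca(s1, s2).value
        expected = abs(1 / 3 - 9 / 19) + 2 * abs(1 / 3 - 5 / 19)  # = 16/57
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.2807, abs=1e-4)

    def test_identical_matrices_zero(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(-1, 1, (5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        s = SimilarityMatrix(a, "spearman")
        assert stat_gsnca(s, s).value == 0.0

    def test_gene_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(-1, 1, (2, 6, 6))
        a, b = (a + a.T) / 2, (b + b.T) / 2
        np.fill_diagonal(a, 1.0)
        np.fill_diagonal(b, 1.0)
        perm = rng.permutation(6)
        base = stat_gsnca(SimilarityMatrix(a, "spearman"), SimilarityMatrix(b, "spearman"))
        ids = [f"g{i}" for i in perm]
        permuted = stat_gsnca(
            SimilarityMatrix(a[np.ix_(perm, perm)], "spearman", ids),
            SimilarityMatrix(b[np.ix_(perm, perm)], "spearman", ids),
        )
        assert permuted.value == pytest.approx(base.value, rel=1e-12)

    def test_all_zero_offdiagonal_raises(self):
        s0 = SimilarityMatrix(np.eye(4), "spearman")
        s1 = SimilarityMatrix(np.eye(4) * 1.0 + 0.2 - 0.2 * np.eye(4), "spearman")
        with pytest.raises(ValueError, match="undefined"):
            stat_gsnca(s0, s1)


class TestIdentitiesAndProperties:
    def test_pnd_reduces_to_mad_and_di(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            v1, v2 = rng.uniform(-1, 1, (2, 12))
            pr = pair(v1, v2)
            assert stat_pnd(pr, 1).value == pytest.approx(stat_mad(pr).value, rel=1e-12)
            assert stat_pnd(pr, 2).value ** 2 == pytest.approx(stat_di(pr).value, rel=1e-12)

    def test_pnd_large_p_approaches_max(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            v1, v2 = rng.uniform(-1, 1, (2, 30))
            mx = np.max(np.abs(v1 - v2))
            got = stat_pnd(pair(v1, v2), 200).value
            assert abs(got - mx) / mx < 0.05

    def test_pnd_rejects_exponent_below_one(self):
        with pytest.raises(ValueError):
            stat_pnd(pair(V1, V2), 0.5)

    def test_group_symmetry(self):
        rng = np.random.default_rng(10)
        v1, v2 = rng.uniform(-1, 1, (2, 15))
        fwd, rev = pair(v1, v2), pair(v2, v1)
        for fn in (stat_di, stat_mad, stat_ghd, stat_qap, stat_gcor):
            assert fn(fwd).value == pytest.approx(fn(rev).value, rel=1e-12)
        assert stat_pnd(fwd, 6).value == pytest.approx(stat_pnd(rev, 6).value, rel=1e-12)
        # anti-symmetric about their null anchors
        assert stat_paired_t(fwd).value == pytest.approx(-stat_paired_t(rev).value, rel=1e-12)
        m = np.count_nonzero(v1 - v2)
        w_fwd = stat_wilcoxon_sr(fwd).value
        w_rev = stat_wilcoxon_sr(rev).value
        assert w_fwd + w_rev == pytest.approx(m * (m + 1) / 2)

    def test_common_entry_permutation_invariance(self):
        rng = np.random.default_rng(12)
        v1, v2 = rng.uniform(-1, 1, (2, 21))
        perm = rng.permutation(21)
        base, shuffled = pair(v1, v2), pair(v1[perm], v2[perm])
        for name in ("DI", "MAD", "pairedT", "wilcoxSRT", "QAP", "GCOR", "GHD"):
            assert oracle(name, *map(list, (v1, v2))) == pytest.approx(
                oracle(name, list(v1[perm]), list(v2[perm])), rel=1e-10
            )
            spec_fn = {"DI": stat_di, "MAD": stat_mad, "pairedT": stat_paired_t,
                       "wilcoxSRT": stat_wilcoxon_sr, "QAP": stat_qap,
                       "GCOR": stat_gcor, "GHD": stat_ghd}[name]
            assert spec_fn(base).value == pytest.approx(spec_fn(shuffled).value, rel=1e-10)

    def test_agreement_with_loop_oracle_on_random_inputs(self):
        rng = np.random.default_rng(13)
        fns = {"DI": stat_di, "MAD": stat_mad, "pairedT": stat_paired_t,
               "wilcoxSRT": stat_wilcoxon_sr, "QAP": stat_qap, "GCOR": stat_gcor,
               "GHD": stat_ghd}
        for _ in range(100):
            lam = int(rng.integers(2, 40))
            v1, v2 = rng.uniform(-1, 1, (2, lam))
            pr = pair(v1, v2)
            for name, fn in fns.items():
                expected = oracle(name, list(v1), list(v2))
                assert fn(pr).value == pytest.approx(expected, rel=1e-10, abs=1e-12)
            for p in (1.5, 4, 6, 20):
                assert stat_pnd(pr, p).value == pytest.approx(
                    oracle("PND", list(v1), list(v2), p), rel=1e-10
                )


class TestSpecRegistry:
    def test_labels_and_parsing(self):
        specs = parse_stat_names("PND4,PND6,DI,mad,GSNCA")
        assert [s.label for s in specs] == ["PND4", "PND6", "DI", "MAD", "GSNCA"]
        assert specs[0].p_exponent == 4.0

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError):
            StatisticSpec("bogus")
        with pytest.raises(ValueError):
            parse_stat_names("PND4,nope")

    def test_exponent_rules(self):
        with pytest.raises(ValueError):
            StatisticSpec("PND", 0.5)
        with pytest.raises(ValueError):
            StatisticSpec("DI", 4)
        assert StatisticSpec("PND").p_exponent == 6.0

    def test_registry_dispatch_matches_direct_calls(self):
        rng = np.random.default_rng(21)
        a, b = rng.uniform(-1, 1, (2, 5, 5))
        a, b = (a + a.T) / 2, (b + b.T) / 2
        np.fill_diagonal(a, 1.0)
        np.fill_diagonal(b, 1.0)
        s1 = SimilarityMatrix(a, "spearman")
        s2 = SimilarityMatrix(b, "spearman")
        from dcmtest import vectorize_pair

        pr = vectorize_pair(s1, s2)
        assert compute_statistic(StatisticSpec("PND", 4), s1, s2).value == pytest.approx(
            stat_pnd(pr, 4).value
        )
        assert compute_statistic(StatisticSpec("GSNCA"), s1, s2).value == pytest.approx(
            stat_gsnca(s1, s2).value
        )
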