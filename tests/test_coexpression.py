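import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from markersurv.coexpression import (
    CorrelationResult,
    aggregate_max_rank,
    bh_fdr,
    marker_correlation_table,
    signed_p_matrix,
    spearman,
    top_partners,
)
from markersurv.io import ExpressionMatrix, GeneSet
from markersurv.synthetic import CohortConfig, generate_cohort


def rank_pearson_oracle(x, y):
    """Average-rank Pearson computed with plain loops."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def bh_oracle(p):
    """Literal step-up procedure."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestSpearman:
    def test_strictly_increasing(self):
        r, _ = spearman(np.arange(12.0), np.arange(12.0) ** 2)
        assert r == pytest.approx(1.0)

    def test_strictly_decreasing(self):
        r, _ = spearman(np.arange(12.0), -np.arange(12.0))
        assert r == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_tied_data_matches_rank_pearson_oracle(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 5, 40).astype(float)  # heavy ties
        y = r.integers(0, 5, 40).astype(float) + 0.3 * x
        rs, _ = spearman(x, y)
        assert rs == pytest.approx(rank_pearson_oracle(x, y), abs=1e-12)

    def test_matches_scipy_large_n(self, rng):
        x = rng.standard_normal(100)
        y = 0.4 * x + rng.standard_normal(100)
        rs, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rs == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_small_n(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        _, p = spearman(x, y)
        # independent enumeration over all 720 permutations
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        null = [
            abs(np.corrcoef(rx, np.array(perm))[0, 1])
            for perm in itertools.permutations(ry)
        ]
        p_oracle = np.mean([v >= obs - 1e-12 for v in null])
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="zero rank variance"):
            spearman(np.ones(10), np.arange(10.0))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [2.0, 1.0])


class TestBhFdr:
    def test_three_value_arithmetic(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=30, deadline=None)
    def test_matches_step_up_oracle(self, seed):
        p = np.random.default_rng(seed).random(25)
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(list(p)), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(p), ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_fdr_control_under_mixed_simulation(self):
        """10% true effects (p ~ Beta(0.1, 1)), 90% uniform nulls; BH at 0.05
        keeps the realized false-discovery fraction near or below nominal."""
        r = np.random.default_rng(99)
        m, n_sim = 1000, 500
        fdp = []
        for _ in range(n_sim):
            truth = r.random(m) < 0.10
            p = np.where(truth, r.beta(0.1, 1.0, m), r.random(m))
            rej = bh_fdr(p) <= 0.05
            if rej.sum():
                fdp.append((rej & ~truth).sum() / rej.sum())
            else:
                fdp.append(0.0)
        assert np.mean(fdp) <= 0.05 + 0.02


class TestSignedPMatrix:
    def test_formula_and_symmetry(self, rng):
        expr = ExpressionMatrix(
            ["a", "b", "c"], [f"s{i}" for i in range(30)],
            rng.standard_normal((3, 30)),
        )
        sp = signed_p_matrix(expr, ["a", "b", "c"])
        for g1, g2 in itertools.combinations(["a", "b", "c"], 2):
            r, p = spearman(expr.row(g1).to_numpy(), expr.row(g2).to_numpy())
            expected = math.copysign(1.0, r) * (1.0 - p)
            assert sp.loc[g1, g2] == pytest.approx(expected, abs=1e-12)
            assert sp.loc[g1, g2] == sp.loc[g2, g1]

    def test_diagonal_is_one(self, rng):
        expr = ExpressionMatrix(
            ["a", "b"], [f"s{i}" for i in range(20)], rng.standard_normal((2, 20))
        )
        sp = signed_p_matrix(expr, ["a", "b"])
        assert sp.loc["a", "a"] == 1.0 and sp.loc["b", "b"] == 1.0

    def test_constant_gene_zero_with_warning(self, rng):
        vals = np.vstack([rng.standard_normal(20), np.full(20, 3.0)])
        expr = ExpressionMatrix(["a", "flat"], [f"s{i}" for i in range(20)], vals)
        with pytest.warns(UserWarning, match="constant"):
            sp = signed_p_matrix(expr, ["a", "flat"])
        assert sp.loc["a", "flat"] == 0.0

    def test_absent_gene_raises(self, rng):
        expr = ExpressionMatrix(["a"], ["s1", "s2", "s3"], rng.standard_normal((1, 3)))
        with pytest.raises(KeyError):
            signed_p_matrix(expr, ["a", "zz"])


def _table(genes, rs):
    return [
        CorrelationResult(gene=g, r_s=r, p_value=0.1, fdr=0.1, n_pairs=50)
        for g, r in zip(genes, rs)
    ]


def max_rank_oracle(tables, k):
    """Exhaustive aggregation written independently of the implementation."""
    common = set(tables[0][0])
    for genes, _ in tables[1:]:
        common &= set(genes)
    max_rank = {}
    for g in common:
        worst = 0
        for genes, rs in tables:
            pairs = sorted(
                ((genes[i], rs[i]) for i in range(len(genes)) if genes[i] in common),
                key=lambda t: (-t[1], t[0]),
            )
            rank = [p[0] for p in pairs].index(g) + 1
            worst = max(worst, rank)
        max_rank[g] = worst
    return sorted(common, key=lambda g: (max_rank[g], g))[:k]


class TestAggregateMaxRank:
    def test_single_cohort_is_top_k(self):
        tab = _table(["a", "b", "c", "d"], [0.9, 0.1, 0.5, 0.7])
        agg = aggregate_max_rank([tab], k=2)
        assert agg.selection == ["a", "d"]
        assert sorted(agg.per_cohort_ranks[g][0] for g in agg.per_cohort_ranks) == [1, 2, 3, 4]

    def test_max_semantics(self):
        # gene "x" ranked 1,1,50 loses to "y" ranked 10 everywhere
        genes = [f"g{i:02d}" for i in range(50)] + ["x", "y"]
        t1 = _table(genes, list(np.linspace(0.4, 0.1, 50)) + [0.99, 0.45])
        t2 = _table(genes, list(np.linspace(0.4, 0.1, 50)) + [0.99, 0.45])
        t3 = _table(genes, list(np.linspace(0.9, 0.5, 50)) + [0.41, 0.85])
        agg = aggregate_max_rank([t1, t2, t3], k=52)
        assert agg.max_rank["x"] > agg.max_rank["y"]
        assert agg.selection.index("y") < agg.selection.index("x")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        tables, raw = [], []
        for _ in range(3):
            rs = r.uniform(-1, 1, 30).round(2)  # rounding creates rank ties
            tables.append(_table(genes, rs))
            raw.append((genes, list(rs)))
        agg = aggregate_max_rank(tables, k=10)
        assert agg.selection == max_rank_oracle(raw, 10)

    def test_cohort_order_invariance(self, rng):
        genes = [f"g{i}" for i in range(20)]
        tables = [_table(genes, rng.uniform(-1, 1, 20)) for _ in range(3)]
        sel = aggregate_max_rank(tables, k=8).selection
        for perm in itertools.permutations(tables):
            assert aggregate_max_rank(list(perm), k=8).selection == sel

    def test_ranks_form_permutation(self, rng):
        genes = [f"g{i}" for i in range(15)]
        tab = _table(genes, np.repeat(0.5, 15))  # full tie -> lexicographic
        agg = aggregate_max_rank([tab], k=15)
        ranks = sorted(agg.per_cohort_ranks[g][0] for g in genes)
        assert ranks == list(range(1, 16))

    def test_empty_intersection(self):
        with pytest.raises(ValueError, match="intersection"):
            aggregate_max_rank([_table(["a"], [0.5]), _table(["b"], [0.5])], k=1)

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="k="):
            aggregate_max_rank([_table(["a", "b"], [0.5, 0.4])], k=3)


class TestTopPartners:
    def test_partner_set_of_size_k(self):
        tab = _table(["a", "b", "c", "d"], [0.9, 0.8, 0.7, 0.6])
        partners = GeneSet(name="p", members=["b", "d"])
        agg = top_partners([tab], partners, k=2)
        assert agg.selection == ["b", "d"]

    def test_disjoint_partner_set(self):
        tab = _table(["a", "b"], [0.9, 0.8])
        partners = GeneSet(name="p", members=["x", "y"])
        with pytest.raises(ValueError):
            top_partners([tab], partners, k=2)

    def test_stemlike_vs_uncorrelated_cohorts(self):
        """Partners correlated with the marker only in 'stem-like' cohorts
        carry higher selection-mean r_s there than in uncorrelated cohorts."""
        stem = generate_cohort(
            CohortConfig(n_samples=200, n_genes=30, module_genes=10,
                         module_rho=0.6, seed=31)
        )
        flat = generate_cohort(
            CohortConfig(n_samples=200, n_genes=30, module_genes=10,
                         module_rho=0.0, seed=32)
        )
        partners = GeneSet(name="p", members=[f"MOD{i + 1:03d}" for i in range(10)])
        tabs = {
            name: marker_correlation_table(c.expression, "MARKER",
                                           genes=partners.members)
            for name, c in (("stem", stem), ("flat", flat))
        }
        agg = top_partners([tabs["stem"]], partners, k=5)
        mean_r = {
            name: np.mean([t.r_s for t in tab if t.gene in agg.selection])
            for name, tab in tabs.items()
        }
        assert mean_r["stem"] > mean_r["flat"] + 0.2


class TestMarkerCorrelationTable:
    def test_fdr_assigned_and_bounded(self, small_cohort):
        table = marker_correlation_table(small_cohort.expression, "MARKER")
        assert all(t.fdr is not None and 0 <= t.fdr <= 1 for t in table)
        assert all(-1 <= t.r_s <= 1 for t in table)
        assert all(t.n_pairs >= 3 for t in table)

    def test_module_rho_scale_recovered(self):
        # generator rho 0.45 at n=557 lands in the observed r_s scale [0.3, 0.6]
        for seed in (1, 2, 3):
            cohort = generate_cohort(
                CohortConfig(n_samples=557, n_genes=20, module_genes=5,
                             module_rho=0.45, seed=seed)
            )
            table = marker_correlation_table(
                cohort.expression, "MARKER",
                genes=[f"MOD{i + 1:03d}" for i in range(5)],
            )
            for t in table:
                assert 0.3 <= t.r_s <= 0.6
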