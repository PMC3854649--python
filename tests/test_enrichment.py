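"""Unit and property tests for the enrichment statistics.

Expected values come from independent oracles: exhaustive enumeration of
draws for the hypergeometric tail, hand-assembled 2x2 tables for the
chi-squared statistic, a plain-python step-up for BH, and the published
14-gene glycosphingolipid worked example for the pathway scores.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import wsea
from wsea.enrichment import _round_half_up


def enum_tail(N, m, n, k):
    """P(X > k) by exhaustive enumeration of all C(N, n) draws."""
    significant = set(range(m))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(significant.intersection(draw)) > k:
            hits += 1
    return hits / total


class TestGeneScore:
    @pytest.mark.parametrize(
        "fc,a,expected",
        [
            (1.0, 1.0, 0.0),
            (1.0, 3.0, 0.0),
            (0.5, 2.0, 1.0),
            (7.793774, 1.0, 2.962327),  # Gla, the largest-|log2 FC| example gene
            (4.0, 1.0, 2.0),
            (4.0, 0.5, np.sqrt(2.0)),
        ],
    )
    def test_examples(self, fc, a, expected):
        assert wsea.gene_score(fc, a) == pytest.approx(expected, abs=1e-4)

    def test_power_zero_is_changed_indicator(self):
        assert wsea.gene_score(1.0, 0.0) == 0.0
        assert wsea.gene_score(2.5, 0.0) == 1.0
        assert wsea.gene_score(0.3, 0.0) == 1.0

    def test_nonpositive_fc_rejected(self):
        with pytest.raises(ValueError):
            wsea.gene_score(0.0, 1.0)
        with pytest.raises(ValueError):
            wsea.gene_score(-2.0, 1.0)
        with pytest.raises(ValueError):
            wsea.gene_score(2.0, -1.0)

    @given(
        st.floats(0.01, 100.0),
        st.floats(0.01, 100.0),
        st.floats(0.1, 4.0),
    )
    def test_monotone_in_log_fc_magnitude(self, fc1, fc2, a):
        if abs(np.log2(fc1)) <= abs(np.log2(fc2)):
            assert wsea.gene_score(fc1, a) <= wsea.gene_score(fc2, a) + 1e-12


class TestScorePathway:
    def test_globo_scores(self, globo):
        stats, gene_set = globo
        sp = wsea.score_pathway(gene_set, stats, a=1.0)
        assert sp.n == 14
        assert sp.k == pytest.approx(22.14654, abs=1e-4)
        assert sp.k_discrete == 22
        assert sp.Q == pytest.approx(abs(np.log2(0.097302)))
        assert sp.Q_discrete == 3

    def test_members_off_array_excluded(self, globo):
        stats, gene_set = globo
        bigger = wsea.GeneSet(
            gene_set.set_id, gene_set.name, gene_set.members | {"not-measured"}
        )
        sp = wsea.score_pathway(bigger, stats, a=1.0)
        assert sp.n == 14
        assert sp.k == pytest.approx(22.14654, abs=1e-4)

    def test_empty_intersection_untestable(self, small_stats):
        gs = wsea.GeneSet("X", "off-array", frozenset({"zz"}))
        sp = wsea.score_pathway(gs, small_stats, a=1.0)
        assert sp.n == 0 and sp.k == 0.0 and sp.Q == 0.0
        assert not sp.testable

    def test_k_bounded_by_n_times_q(self, small_stats):
        gs = wsea.GeneSet("A", "a", frozenset(small_stats.index))
        sp = wsea.score_pathway(gs, small_stats, a=1.5)
        assert 0 <= sp.k <= sp.n * sp.Q + 1e-12
        assert 0 <= sp.k_discrete <= sp.n * sp.Q_discrete


class TestRounding:
    def test_half_rounds_up(self):
        np.testing.assert_array_equal(
            _round_half_up(np.array([0.4, 0.5, 1.5, 2.5, 2.49])),
            [0.0, 1.0, 2.0, 3.0, 2.0],
        )


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "N,m,n,k,expected",
        [
            (10, 5, 4, 2, 55 / 210),
            (4, 2, 2, 0, 5 / 6),
            (10, 5, 4, 4, 0.0),  # k = min(m, n): tail beyond support
            (8, 0, 3, 0, 0.0),  # no significant genes at all
        ],
    )
    def test_hand_enumerated_examples(self, N, m, n, k, expected):
        assert wsea.hypergeom_tail(N, m, n, k) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_all_small_instances(self):
        for N in range(1, 13):
            for m in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(m, n) + 1):
                        assert wsea.hypergeom_tail(N, m, n, k) == pytest.approx(
                            enum_tail(N, m, n, k), abs=1e-10
                        ), (N, m, n, k)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            wsea.hypergeom_tail(10, 11, 4, 2)
        with pytest.raises(ValueError):
            wsea.hypergeom_tail(10, 5, 4, 5)

    def test_large_arguments_stable(self):
        p = wsea.hypergeom_tail(2_000_000, 50_000, 10_000, 400)
        assert 0.0 <= p <= 1.0


CHI2_PANEL = [
    # (n11, n12, n21, n22, expected) — hand-evaluated N(ad-bc)^2/(margins)
    (50, 10, 950, 90, 4.4070512820512825),
    (20, 20, 30, 30, 0.0),  # proportional rows
    (10, 0, 0, 10, 20.0),
    (3, 1, 2, 4, 10 * (12 - 2) ** 2 / (4 * 6 * 5 * 5)),
    (1, 2, 3, 4, 10 * (4 - 6) ** 2 / (3 * 7 * 4 * 6)),
]


class TestChi2Statistic:
    @pytest.mark.parametrize("n11,n12,n21,n22,expected", CHI2_PANEL)
    def test_hand_computed_panel(self, n11, n12, n21, n22, expected):
        t = wsea.ContingencyTable(n11, n12, n21, n22)
        assert wsea.chi2_statistic(t) == pytest.approx(expected, rel=1e-12)

    def test_df_is_one_for_2x2(self):
        assert wsea.ContingencyTable(1, 2, 3, 4).df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            wsea.chi2_statistic(wsea.ContingencyTable(0, 0, 3, 4))

    @given(
        st.integers(1, 50),
        st.integers(1, 50),
        st.integers(1, 50),
        st.integers(1, 50),
    )
    def test_invariant_under_row_and_column_swaps(self, a, b, c, d):
        base = wsea.chi2_statistic(wsea.ContingencyTable(a, b, c, d))
        rows = wsea.chi2_statistic(wsea.ContingencyTable(c, d, a, b))
        cols = wsea.chi2_statistic(wsea.ContingencyTable(b, a, d, c))
        assert rows == pytest.approx(base, rel=1e-9)
        assert cols == pytest.approx(base, rel=1e-9)


class TestBhFdr:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            wsea.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(wsea.bh_fdr([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            wsea.bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_plain_python_step_up(self, ps):
        adj = wsea.bh_fdr(ps)
        M = len(ps)
        order = np.argsort(ps, kind="mergesort")
        expected = np.empty(M)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            j = M - rank_from_end
            running = min(running, ps[idx] * M / j)
            expected[idx] = running
        np.testing.assert_allclose(adj, expected, atol=1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-12)  # FDR >= raw p
        # monotone along the raw-p ordering
        assert np.all(np.diff(expected[order]) >= -1e-12)


def _random_dataset(rng, n_genes=200, n_sets=10, size_range=(5, 40)):
    genes = [f"g{i}" for i in range(n_genes)]
    stats = pd.DataFrame(
        {
            "fold_change": rng.lognormal(0, 1, n_genes),
            "p_value": rng.uniform(0, 1, n_genes),
        },
        index=genes,
    )
    stats["is_significant"] = stats["p_value"] < 0.05
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(*size_range))
        members = rng.choice(genes, size=size, replace=False)
        sets.append(wsea.GeneSet(f"S{i}", f"set {i}", frozenset(members)))
    return stats, wsea.GeneSetCollection(sets)


class TestEnrichHypergeometric:
    def test_no_significant_genes_gives_p0(self, small_stats):
        stats = small_stats.assign(p_value=0.9, is_significant=False)
        coll = wsea.GeneSetCollection(
            [wsea.GeneSet("A", "a", frozenset({"g0", "g1"}))]
        )
        res = wsea.enrich_hypergeometric(coll, stats, alpha=0.01)
        # m = 0 forces X == 0, so P(X > 0) = 0
        assert res["p_value"].iloc[0] == 0.0

    def test_whole_array_pathway_with_k_eq_min(self, small_stats):
        coll = wsea.GeneSetCollection(
            [wsea.GeneSet("ALL", "all", frozenset(small_stats.index))]
        )
        res = wsea.enrich_hypergeometric(coll, small_stats, alpha=0.01)
        assert res["p_value"].iloc[0] == 0.0  # k = m = min(m, n)

    def test_matches_enumeration_oracle(self, rng):
        stats, coll = _random_dataset(rng, n_genes=12, n_sets=6, size_range=(2, 9))
        res = wsea.enrich_hypergeometric(coll, stats, alpha=0.05).set_index("set_id")
        sig = set(stats.index[stats["is_significant"]])
        m = len(sig)
        for s in coll:
            n = len(s.members)
            k = len(s.members & sig)
            # tail depends only on the counts, so the enumerator may place
            # the m significant genes first
            expected = enum_tail(len(stats), m, n, k)
            assert res.loc[s.set_id, "p_value"] == pytest.approx(expected, abs=1e-10)

    def test_off_array_set_flagged_untestable(self, small_stats):
        coll = wsea.GeneSetCollection(
            [wsea.GeneSet("X", "x", frozenset({"absent"}))]
        )
        res = wsea.enrich_hypergeometric(coll, small_stats)
        assert res["flag"].iloc[0] == "untestable"
        assert res["p_value"].iloc[0] == 1.0


class TestEnrichWeightedHypergeometric:
    def test_pseudo_population_enumeration_example(self):
        # rounded scores (2,1,0,1,0); pathway = first two genes
        # pseudo population 5*2=10 copies, 4 significant, 4 drawn, k=3
        stats = pd.DataFrame(
            {
                "fold_change": [4.0, 2.0, 1.0, 2.0, 1.0],
                "p_value": [0.5] * 5,
            },
            index=[f"g{i}" for i in range(5)],
        )
        coll = wsea.GeneSetCollection(
            [wsea.GeneSet("S1", "s", frozenset({"g0", "g1"}))]
        )
        res = wsea.enrich_weighted_hypergeometric(coll, stats, a=1.0)
        # enumeration over the 10-copy pseudo population
        expected = enum_tail(10, 4, 4, 3)
        assert expected == pytest.approx(1 / 210)
        assert res["p_value"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert res["pathway_score"].iloc[0] == 3

    def test_reduces_to_unweighted_with_indicator_scores(self, rng):
        stats, coll = _random_dataset(rng)
        indicator = stats["is_significant"].astype(float)
        weighted = wsea.enrich_weighted_hypergeometric(
            coll, stats, scores=indicator
        ).set_index("set_id")
        unweighted = wsea.enrich_hypergeometric(coll, stats, alpha=0.05).set_index(
            "set_id"
        )
        nondegenerate = weighted["flag"] != "degenerate"
        assert nondegenerate.sum() > 0
        for sid in weighted.index[nondegenerate]:
            assert weighted.loc[sid, "p_value"] == pytest.approx(
                unweighted.loc[sid, "p_value"], abs=1e-12
            )

    def test_all_unit_fold_changes_degenerate(self, rng):
        stats = pd.DataFrame(
            {"fold_change": np.ones(20), "p_value": rng.uniform(0, 1, 20)},
            index=[f"g{i}" for i in range(20)],
        )
        coll = wsea.GeneSetCollection(
            [wsea.GeneSet("A", "a", frozenset({"g0", "g1", "g2"}))]
        )
        res = wsea.enrich_weighted_hypergeometric(coll, stats, a=1.0)
        assert res["flag"].iloc[0] == "degenerate"
        assert res["p_value"].iloc[0] == 1.0

    def test_successes_capped_at_population(self):
        # every gene has a huge score; the pathway holds the modest one so
        # S_discrete exceeds N * Q_discrete and must be capped
        stats = pd.DataFrame(
            {"fold_change": [2.0, 1024.0, 1024.0, 1024.0], "p_value": [0.5] * 4},
            index=["g0", "g1", "g2", "g3"],
        )
        coll = wsea.GeneSetCollection([wsea.GeneSet("A", "a", frozenset({"g0"}))])
        res = wsea.enrich_weighted_hypergeometric(coll, stats, a=1.0)
        assert res["flag"].iloc[0] == "successes_capped"
        assert 0.0 <= res["p_value"].iloc[0] <= 1.0


class TestEnrichChi2:
    def test_matches_explicit_table_construction(self, rng):
        stats, coll = _random_dataset(rng)
        res = wsea.enrich_chi2(coll, stats, alpha=0.05).set_index("set_id")
        sig = set(stats.index[stats["is_significant"]])
        N, m = len(stats), len(sig)
        from scipy.stats import chi2 as chi2_dist

        for s in coll:
            n = len(s.members)
            k = len(s.members & sig)
            table = wsea.ContingencyTable(n, k, N - n, m - k)
            expected = float(chi2_dist.sf(wsea.chi2_statistic(table), 1))
            assert res.loc[s.set_id, "p_value"] == pytest.approx(expected, rel=1e-12)

    def test_zero_margin_flagged(self, small_stats):
        stats = small_stats.assign(p_value=0.9, is_significant=False)  # m = 0
        coll = wsea.GeneSetCollection(
            [wsea.GeneSet("A", "a", frozenset({"g0", "g1"}))]
        )
        res = wsea.enrich_chi2(coll, stats, alpha=0.01)
        assert res["flag"].iloc[0] == "degenerate"
        assert res["p_value"].iloc[0] == 1.0

    def test_independent_membership_gives_large_p(self, rng):
        # balanced null: membership carries no information about significance
        n_genes = 4000
        stats = pd.DataFrame(
            {
                "fold_change": np.ones(n_genes),
                "p_value": np.where(np.arange(n_genes) % 2 == 0, 0.001, 0.9),
            },
            index=[f"g{i}" for i in range(n_genes)],
        )
        members = frozenset(f"g{i}" for i in range(0, n_genes, 4)) | frozenset(
            f"g{i}" for i in range(1, n_genes, 4)
        )  # exactly half significant, like the array
        coll = wsea.GeneSetCollection([wsea.GeneSet("A", "a", members)])
        res = wsea.enrich_chi2(coll, stats, alpha=0.01)
        assert res["p_value"].iloc[0] > 0.9


class TestEnrichWeightedChi2:
    def test_globo_reported_score(self, globo):
        stats, gene_set = globo
        coll = wsea.GeneSetCollection([gene_set])
        res = wsea.enrich_weighted_chi2(coll, stats, a=1.0)
        assert res["pathway_score"].iloc[0] == pytest.approx(22.14654, abs=1e-4)

    def test_uniform_scores_give_zero_statistic(self):
        # every gene the same score s > 0: k proportional to n, rows proportional
        stats = pd.DataFrame(
            {"fold_change": np.full(30, 4.0), "p_value": np.full(30, 0.5)},
            index=[f"g{i}" for i in range(30)],
        )
        coll = wsea.GeneSetCollection(
            [
                wsea.GeneSet("A", "a", frozenset({"g0", "g1", "g2"})),
                wsea.GeneSet("B", "b", frozenset(f"g{i}" for i in range(15))),
            ]
        )
        res = wsea.enrich_weighted_chi2(coll, stats, a=1.0)
        np.testing.assert_allclose(res["p_value"].to_numpy(), 1.0)

    def test_matches_explicit_table_construction(self, rng):
        from scipy.stats import chi2 as chi2_dist

        stats, coll = _random_dataset(rng)
        res = wsea.enrich_weighted_chi2(coll, stats, a=1.0).set_index("set_id")
        scores = pd.Series(
            wsea.gene_score(stats["fold_change"].to_numpy(), 1.0), index=stats.index
        )
        N, S = len(stats), float(scores.sum())
        for s in coll:
            members = sorted(s.members)
            n = len(members)
            k = float(scores.loc[members].sum())
            table = wsea.ContingencyTable(n, k, N - n, S - k)
            expected = float(chi2_dist.sf(wsea.chi2_statistic(table), 1))
            assert res.loc[s.set_id, "p_value"] == pytest.approx(expected, rel=1e-9)
            assert res.loc[s.set_id, "pathway_score"] == pytest.approx(k)

    def test_all_unit_fold_changes_degenerate(self):
        stats = pd.DataFrame(
            {"fold_change": np.ones(10), "p_value": np.full(10, 0.5)},
            index=[f"g{i}" for i in range(10)],
        )
        coll = wsea.GeneSetCollection([wsea.GeneSet("A", "a", frozenset({"g0"}))])
        res = wsea.enrich_weighted_chi2(coll, stats, a=1.0)
        assert res["flag"].iloc[0] == "degenerate"


class TestRankingAndReportInvariants:
    def test_rank_order_and_ties(self):
        df = pd.DataFrame(
            {
                "set_id": ["a", "b", "c", "d"],
                "name": list("abcd"),
                "p_value": [0.2, 0.1, 0.3, 0.1],
                "fdr": [0.3, 0.2, 0.3, 0.2],
                "pathway_score": [1.0, 2.0, 1.0, 5.0],
                "n_genes": [3, 3, 3, 3],
                "rank": [0, 0, 0, 0],
                "flag": [""] * 4,
            }
        )
        ranked = wsea.rank_and_report(df, top_k=10)
        # ties on p broken by larger score, then set_id
        assert ranked["set_id"].tolist() == ["d", "b", "a", "c"]
        assert ranked["rank"].tolist() == [1, 2, 3, 4]

    def test_top_k_and_cutoff(self):
        df = pd.DataFrame(
            {
                "set_id": [f"s{i}" for i in range(5)],
                "name": [f"s{i}" for i in range(5)],
                "p_value": [0.001, 0.02, 0.3, 0.4, 0.5],
                "fdr": [0.005, 0.05, 0.5, 0.5, 0.5],
                "pathway_score": [1.0] * 5,
                "n_genes": [2] * 5,
                "rank": [0] * 5,
                "flag": [""] * 5,
            }
        )
        assert len(wsea.rank_and_report(df, top_k=3)) == 3
        assert len(wsea.rank_and_report(df, top_k=10)) == 5
        assert wsea.rank_and_report(df, top_k=10, p_cutoff=0.01)[
            "set_id"
        ].tolist() == ["s0"]

    def test_result_invariants_all_methods(self, rng):
        stats, coll = _random_dataset(rng)
        for method in wsea.METHODS:
            res = wsea.enrich(coll, stats, method, a=1.0, alpha=0.05)
            assert res["p_value"].between(0, 1).all()
            assert (res["fdr"] >= res["p_value"] - 1e-12).all()
            assert sorted(res["rank"]) == list(range(1, len(coll) + 1))

    def test_unknown_method_rejected(self, small_stats):
        coll = wsea.GeneSetCollection([wsea.GeneSet("A", "a", frozenset({"g0"}))])
        with pytest.raises(ValueError, match="unknown method"):
            wsea.enrich(coll, small_stats, "gsea")
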