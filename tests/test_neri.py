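"""PPI merging, concordance scoring, cuttings, importance and robustness."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from coexprio import neri as nr
from coexprio import simulate as sim


def kendall_w_oracle(values: np.ndarray) -> float:
    """Direct evaluation of tie-corrected Kendall's W from raw ranks."""
    m, n = values.shape
    ranks = np.array([rankdata(row) for row in values])
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie = 0.0
    for row in ranks:
        for _, t in zip(*np.unique(row, return_counts=True)):
            tie += t**3 - t
    denom = m**2 * (n**3 - n) - m * tie
    return 12.0 * s / denom if denom > 0 else 0.0


def expr_frame(rows: dict[str, list[float]]) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return df


class TestMergePpi:
    def test_undirected_dedup_with_source_union(self):
        t1 = pd.DataFrame({"gene_a": ["A"], "gene_b": ["B"], "source": ["db1"]})
        t2 = pd.DataFrame({"gene_a": ["B", "B"], "gene_b": ["A", "C"], "source": ["db2", "db2"]})
        g = nr.merge_ppi([t1, t2])
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        assert g.edges["A", "B"]["sources"] == {"db1", "db2"}

    def test_self_loops_dropped(self):
        t = pd.DataFrame({"gene_a": ["A", "A"], "gene_b": ["A", "B"], "source": ["x", "x"]})
        g = nr.merge_ppi([t])
        assert not any(a == b for a, b in g.edges)
        assert g.number_of_edges() == 1

    def test_counts_match_set_union_oracle(self):
        rng = np.random.default_rng(0)
        symbols = [f"g{i}" for i in range(30)]
        tables = []
        union = set()
        for t in range(3):
            a = rng.choice(symbols, 50)
            b = rng.choice(symbols, 50)
            tables.append(pd.DataFrame({"gene_a": a, "gene_b": b, "source": f"db{t}"}))
            for x, y in zip(a, b):
                if x != y:
                    union.add(frozenset((x.upper(), y.upper())))
        g = nr.merge_ppi(tables)
        assert g.number_of_edges() == len(union)
        assert set(g.nodes) == {s for e in union for s in e}

    def test_empty_union_rejected(self):
        t = pd.DataFrame({"gene_a": ["A"], "gene_b": ["A"], "source": ["x"]})
        with pytest.raises(ValueError):
            nr.merge_ppi([t])


class TestMapSeeds:
    def test_partition(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        ss = nr.map_seeds(g, ["A", "C", "X", "Y", "B"])
        assert set(ss.mapped) == {"A", "B", "C"}
        assert set(ss.unmapped) == {"X", "Y"}

    def test_case_insensitive(self):
        g = nx.Graph([("ABC1", "DEF2")])
        ss = nr.map_seeds(g, ["abc1", "def2"])
        assert set(ss.mapped) == {"ABC1", "DEF2"}
        assert not ss.unmapped

    def test_no_mapped_seed_is_fatal(self):
        g = nx.Graph([("A", "B")])
        with pytest.raises(ValueError):
            nr.map_seeds(g, ["X"])


class TestPathConcordance:
    def test_identical_profiles_fully_concordant(self):
        expr = expr_frame({"A": [1, 2, 3, 4], "B": [10, 20, 30, 40], "C": [0, 1, 2, 3]})
        assert nr.path_concordance(["A", "B", "C"], expr) == pytest.approx(1.0)

    def test_two_reversed_rankings_score_zero(self):
        expr = expr_frame({"A": [1, 2, 3, 4], "B": [4, 3, 2, 1]})
        assert nr.path_concordance(["A", "B"], expr) == pytest.approx(0.0)

    def test_matches_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            m = int(rng.integers(2, 6))
            n = int(rng.integers(3, 9))
            vals = rng.integers(0, 5, size=(m, n)).astype(float)  # ties likely
            expr = pd.DataFrame(vals, index=[f"G{i}" for i in range(m)])
            got = nr.path_concordance(list(expr.index), expr)
            assert got == pytest.approx(kendall_w_oracle(vals), abs=1e-12)

    def test_unmeasured_genes_reduce_judges(self):
        expr = expr_frame({"A": [1, 2, 3], "B": [1, 2, 3]})
        w = nr.path_concordance(["A", "X", "B"], expr)
        assert w == pytest.approx(1.0)

    def test_single_judge_scores_zero_with_warning(self):
        expr = expr_frame({"A": [1, 2, 3]})
        with pytest.warns(UserWarning):
            assert nr.path_concordance(["A", "X"], expr) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(-50, 50), min_size=4, max_size=4),
            min_size=2,
            max_size=4,
        ),
        st.integers(0, 2),
    )
    def test_invariant_under_monotone_transform_and_bounded(self, rows, which):
        # integer-valued expression keeps strictly monotone maps exactly
        # order-preserving in floating point (no tie collapse)
        vals = np.array(rows, dtype=float)
        expr = pd.DataFrame(vals, index=[f"G{i}" for i in range(len(rows))])
        w0 = nr.path_concordance(list(expr.index), expr)
        assert 0.0 <= w0 <= 1.0
        transforms = [np.exp, lambda x: 3 * x + 7, np.cbrt]
        expr2 = expr.copy()
        expr2.iloc[0] = transforms[which](expr2.iloc[0])  # monotone per-gene map
        assert nr.path_concordance(list(expr2.index), expr2) == pytest.approx(w0, abs=1e-9)


class TestBuildCutting:
    def test_unique_path_selected_regardless_of_concordance(self):
        g = nx.Graph([("S1", "X"), ("X", "S2")])
        expr = expr_frame({"S1": [1, 2, 3], "X": [3, 1, 2], "S2": [2, 3, 1]})
        ss = nr.map_seeds(g, ["S1", "S2"])
        cut = nr.build_cutting(g, ss, expr)
        assert ("S1", "X", "S2") in cut.selected_paths

    def test_diamond_prefers_concordant_branch(self):
        g = nx.Graph([("S", "A"), ("A", "T"), ("S", "B"), ("B", "T")])
        expr = expr_frame(
            {
                "S": [1, 2, 3, 4],
                "T": [1.5, 2.5, 3.5, 4.5],
                "A": [1, 2, 3, 4.2],  # concordant with S, T
                "B": [4, 3, 2, 1],  # anti-concordant
            }
        )
        ss = nr.map_seeds(g, ["S", "T"])
        cut = nr.build_cutting(g, ss, expr)
        st_paths = [p for p in cut.selected_paths if set((p[0], p[-1])) == {"S", "T"}]
        assert len(st_paths) == 1 and "A" in st_paths[0]
        # verify against both candidates' W computed independently
        w_a = nr.path_concordance(["S", "A", "T"], expr)
        w_b = nr.path_concordance(["S", "B", "T"], expr)
        assert w_a > w_b

    def test_star_with_seed_hub_returns_star(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        expr = expr_frame({n: np.random.default_rng(1).normal(size=4) for n in g.nodes})
        with pytest.warns(UserWarning):  # single seed: neighbor pairs only
            ss = nr.map_seeds(g, ["N0"])
        cut = nr.build_cutting(g, ss, expr)
        assert set(cut.subnetwork.edges) == set(g.edges)

    def test_selected_paths_are_shortest(self, small_study):
        _, ctl, _, _, graph, seeds, _ = small_study
        ss = nr.map_seeds(graph, seeds)
        cut = nr.build_cutting(graph, ss, ctl)
        for path in cut.selected_paths[::7]:
            assert len(path) - 1 == nx.shortest_path_length(graph, path[0], path[-1])

    def test_tie_broken_lexicographically(self):
        # two equally concordant length-2 branches: smallest node sequence wins
        g = nx.Graph([("S", "A"), ("A", "T"), ("S", "B"), ("B", "T")])
        expr = expr_frame(
            {"S": [1, 2, 3], "T": [1, 2, 3], "A": [1, 2, 3], "B": [1, 2, 3]}
        )
        ss = nr.map_seeds(g, ["S", "T"])
        cut = nr.build_cutting(g, ss, expr)
        st_paths = [p for p in cut.selected_paths if set((p[0], p[-1])) == {"S", "T"}]
        assert st_paths == [("S", "A", "T")]


class TestRelativeImportance:
    @staticmethod
    def _manual_cuttings():
        # hand-built cuttings over 6 nodes with assigned path scores
        paths_c = [("S1", "A", "S2"), ("S1", "B")]
        scores_c = [0.8, 0.5]
        paths_d = [("S1", "C", "S2"), ("S1", "B")]
        scores_d = [0.6, 0.9]
        sub_c = nx.Graph([("S1", "A"), ("A", "S2"), ("S1", "B")])
        sub_d = nx.Graph([("S1", "C"), ("C", "S2"), ("S1", "B")])
        cut_c = nr.Cutting("control", paths_c, scores_c, sub_c)
        cut_d = nr.Cutting("case", paths_d, scores_d, sub_d)
        seed_set = nr.SeedSet(("S1", "S2"), ("S1", "S2"), ())
        return cut_c, cut_d, seed_set

    def test_hand_computed_importances(self):
        cut_c, cut_d, seed_set = self._manual_cuttings()
        table = nr.relative_importance(cut_c, cut_d, seed_set)
        # control: raw = S1: 0.8+0.5=1.3 (prox 1), S2: 0.8, A: 0.8*prox(1/2)=0.4,
        # B: 0.5*1/2=0.25, C: 0 -> normalized by 1.3
        assert table.loc["S1", "importance_control"] == pytest.approx(1.0, abs=1e-12)
        assert table.loc["S2", "importance_control"] == pytest.approx(0.8 / 1.3, abs=1e-12)
        assert table.loc["A", "importance_control"] == pytest.approx(0.4 / 1.3, abs=1e-12)
        assert table.loc["B", "importance_control"] == pytest.approx(0.25 / 1.3, abs=1e-12)
        assert table.loc["C", "importance_control"] == 0.0
        # case: S1: 0.6+0.9=1.5, S2: 0.6, C: 0.6/2=0.3, B: 0.9/2=0.45
        assert table.loc["C", "importance_case"] == pytest.approx(0.3 / 1.5, abs=1e-12)
        assert table.loc["B", "importance_case"] == pytest.approx(0.45 / 1.5, abs=1e-12)

    def test_sigma_dominates_abs_delta(self):
        cut_c, cut_d, seed_set = self._manual_cuttings()
        table = nr.relative_importance(cut_c, cut_d, seed_set)
        assert (table["sigma"] >= table["delta"].abs() - 1e-12).all()

    def test_delta_changes_sign_when_conditions_swap(self):
        cut_c, cut_d, seed_set = self._manual_cuttings()
        fwd = nr.relative_importance(cut_c, cut_d, seed_set)
        rev = nr.relative_importance(cut_d, cut_c, seed_set)
        assert np.allclose(fwd["delta"], -rev["delta"])
        assert np.allclose(fwd["delta_prime"], -rev["delta_prime"])

    def test_shared_path_with_equal_scores_gives_zero_delta(self):
        paths = [("S1", "A", "S2")]
        sub = nx.Graph([("S1", "A"), ("A", "S2")])
        cut_c = nr.Cutting("control", paths, [0.7], sub)
        cut_d = nr.Cutting("case", paths, [0.7], sub.copy())
        seed_set = nr.SeedSet(("S1", "S2"), ("S1", "S2"), ())
        table = nr.relative_importance(cut_c, cut_d, seed_set)
        assert np.allclose(table["delta"], 0.0)

    def test_importances_invariant_to_node_relabeling(self):
        cut_c, cut_d, seed_set = self._manual_cuttings()
        base = nr.relative_importance(cut_c, cut_d, seed_set)
        relabel = {"S1": "Z9", "S2": "Z8", "A": "Z1", "B": "Z2", "C": "Z3"}

        def rl(cut):
            return nr.Cutting(
                cut.condition,
                [tuple(relabel[g] for g in p) for p in cut.selected_paths],
                list(cut.path_scores),
                nx.relabel_nodes(cut.subnetwork, relabel),
            )

        seed2 = nr.SeedSet(("Z9", "Z8"), ("Z9", "Z8"), ())
        out = nr.relative_importance(rl(cut_c), rl(cut_d), seed2)
        for old, new in relabel.items():
            assert out.loc[new, "importance_control"] == pytest.approx(
                base.loc[old, "importance_control"], abs=1e-12
            )


class TestRankGenes:
    @staticmethod
    def _table(n=2000, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"G{i:05d}" for i in range(n)]
        df = pd.DataFrame(
            {
                "sigma": rng.random(n),
                "delta_prime": rng.uniform(-1, 1, n),
                "sigma_prime": rng.uniform(0, 2, n),
            },
            index=idx,
        )
        return df

    def test_top_fraction_length(self):
        assert len(nr.rank_genes(self._table(2000), fraction=0.10)) == 200

    def test_fraction_one_returns_all(self):
        t = self._table(57)
        assert len(nr.rank_genes(t, fraction=1.0)) == 57

    def test_ties_broken_by_sigma_then_symbol(self):
        t = pd.DataFrame(
            {
                "sigma": [0.2, 0.9, 0.9],
                "delta_prime": [0.5, 0.5, 0.5],
                "sigma_prime": [1.0, 1.0, 1.0],
            },
            index=["G3", "G2", "G1"],
        )
        top = nr.rank_genes(t, fraction=1.0)
        # equal delta': sigma 0.9 beats 0.2; equal sigma: symbol ascending
        assert list(top.index) == ["G1", "G2", "G3"]

    def test_magnitude_ranking_surfaces_both_directions(self):
        t = pd.DataFrame(
            {
                "sigma": [1.0, 1.0, 1.0],
                "delta_prime": [-0.9, 0.8, 0.1],
                "sigma_prime": [1.0, 1.0, 1.0],
            },
            index=["down", "up", "flat"],
        )
        top = nr.rank_genes(t, fraction=2 / 3)
        assert set(top.index) == {"down", "up"}
        signed = nr.rank_genes(t, fraction=2 / 3, signed=True)
        assert list(signed.index) == ["up", "flat"]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            nr.rank_genes(self._table(10), fraction=0.0)


class TestSeedRobustness:
    def test_bookkeeping_record_count(self, small_study):
        _, ctl, scz, _, graph, seeds, _ = small_study
        out = nr.seed_robustness(
            graph, seeds, ctl, scz, fractions=(0.1, 0.2), n_sets=2, tops=(25, 50), rng_seed=0
        )
        assert len(out) == 2 * 2 * 2
        assert ((out["overlap_pct"] >= 0) & (out["overlap_pct"] <= 100)).all()

    def test_zero_removal_gives_full_overlap(self, small_study):
        _, ctl, scz, _, graph, seeds, _ = small_study
        out = nr.seed_robustness(
            graph, seeds, ctl, scz, fractions=(0.0,), n_sets=1, tops=(25, 50), rng_seed=0
        )
        assert (out["overlap_pct"] == 100.0).all()

    def test_too_few_seeds_rejected(self, small_study):
        _, ctl, scz, _, graph, seeds, _ = small_study
        with pytest.raises(ValueError):
            nr.seed_robustness(graph, seeds[:3], ctl, scz, fractions=(0.5,), n_sets=1)
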