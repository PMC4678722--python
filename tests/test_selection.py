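import numpy as np
import pandas as pd
import pytest

from ggselect import (
    GraphParams,
    SelectionResult,
    ggs_select,
    ranked_degree_select,
    predictor_sets,
    parameter_sweep,
    pearson_matrix,
)

from reference import naive_ggs, naive_ranked_degree, random_er_adjacency


class TestGgsToyGraphs:
    def test_star_single_hub(self, star_graph):
        res = ggs_select(star_graph, GraphParams(0.6, redundancy=1, dm_size=1))
        assert res.dm_genes == ["A"]
        assert res.predictable_genes == {"B", "C", "D"}

    def test_two_triangles_one_dm_per_clique(self, two_triangles):
        res = ggs_select(two_triangles, GraphParams(0.6, redundancy=1, dm_size=2))
        assert res.dm_genes == ["A", "D"]
        assert res.predictable_genes == {"B", "C", "E", "F"}

    def test_four_cycle_counts_original_adjacency(self, four_cycle):
        """Redundancy 2 on the 4-cycle: B's edge to A is pruned when A is
        selected, yet B still becomes predictable once C enters the DM set —
        predictability counts neighbors in the original adjacency."""
        res = ggs_select(four_cycle, GraphParams(0.6, redundancy=2, dm_size=2))
        assert res.dm_genes == ["A", "C"]
        assert res.predictable_genes == {"B", "D"}

    def test_pruned_variant_differs_on_four_cycle(self, four_cycle):
        """Under the literal edge-removal reading, redundancy 2 is
        unsatisfiable on the 4-cycle."""
        res = ggs_select(
            four_cycle, GraphParams(0.6, redundancy=2, dm_size=2), predictability="pruned"
        )
        assert res.predictable_genes == set()

    def test_early_exhaustion_logged(self, star_graph):
        res = ggs_select(star_graph, GraphParams(0.6, redundancy=1, dm_size=3))
        assert res.dm_genes == ["A"]
        assert res.exhausted
        assert res.iteration_log[-1].gene == "<exhausted>"


class TestRankedDegree:
    def test_star_top_two(self, star_graph):
        res = ranked_degree_select(star_graph, GraphParams(0.6, 1, 2))
        assert res.dm_genes == ["A", "B"]
        assert res.predictable_genes == {"C", "D"}

    def test_triangles_redundant_panel(self, two_triangles):
        """All degrees tie at 2, so ranked-degree takes A and B from one
        triangle and predicts only C — versus four genes for GGS."""
        ranked = ranked_degree_select(two_triangles, GraphParams(0.6, 1, 2))
        assert ranked.dm_genes == ["A", "B"]
        assert ranked.predictable_genes == {"C"}
        greedy = ggs_select(two_triangles, GraphParams(0.6, 1, 2))
        assert len(greedy.predictable_genes) >= 3 * len(ranked.predictable_genes)

    def test_measure_everything_predicts_nothing(self, two_triangles):
        res = ranked_degree_select(two_triangles, GraphParams(0.6, 1, 6))
        assert res.predictable_genes == set()


class TestCandidates:
    def test_seeded_before_greedy(self, two_triangles):
        """Candidates enter the DM set first; greedy picks continue from
        the pruned graph."""
        res = ggs_select(
            two_triangles, GraphParams(0.6, 1, 1), candidates=["B"]
        )
        assert res.dm_genes[0] == "B"
        assert len(res.dm_genes) == 2  # dm_size counts additional greedy picks
        assert {"A", "C"} <= res.predictable_genes

    def test_total_count_semantics(self, two_triangles):
        res = ggs_select(
            two_triangles,
            GraphParams(0.6, 1, 2),
            candidates=["B"],
            count_candidates_toward_size=True,
        )
        assert len(res.dm_genes) == 2

    def test_absent_candidate_warned_and_kept(self, star_graph):
        with pytest.warns(UserWarning, match="NOTAGENE"):
            res = ggs_select(
                star_graph, GraphParams(0.6, 1, 1), candidates=["NOTAGENE"]
            )
        assert res.dm_genes[0] == "NOTAGENE"
        assert res.missing_candidates == ["NOTAGENE"]
        assert "NOTAGENE" not in res.predictable_genes


class TestInvariants:
    def test_determinism(self):
        rng = np.random.default_rng(31)
        adj = random_er_adjacency(rng, 80, 0.08)
        runs = [
            ggs_select(adj, GraphParams(0.6, 2, 20)) for _ in range(2)
        ]
        assert runs[0].dm_genes == runs[1].dm_genes
        assert runs[0].predictable_genes == runs[1].predictable_genes

    def test_dm_prefix_nesting_and_monotone_predictable(self):
        rng = np.random.default_rng(13)
        adj = random_er_adjacency(rng, 100, 0.06)
        sizes = [5, 10, 20, 40]
        results = [ggs_select(adj, GraphParams(0.6, 1, k)) for k in sizes]
        for small, big in zip(results, results[1:]):
            assert big.dm_genes[: len(small.dm_genes)] == small.dm_genes
            assert len(big.predictable_genes) >= len(small.predictable_genes)

    @pytest.mark.parametrize("redundancy", [1, 2, 3])
    def test_redundancy_guarantee(self, redundancy):
        """Every predictable gene has >= redundancy DM neighbors in the
        original adjacency."""
        rng = np.random.default_rng(41 + redundancy)
        adj = random_er_adjacency(rng, 120, 0.05)
        res = ggs_select(adj, GraphParams(0.6, redundancy, 25))
        dm = [g for g in res.dm_genes if g in adj.index]
        for gene in res.predictable_genes:
            assert adj.loc[gene, dm].sum() >= redundancy

    def test_iteration_count_equals_dm_size(self):
        """One greedy iteration per DM gene (minus early exhaustion)."""
        rng = np.random.default_rng(6)
        adj = random_er_adjacency(rng, 200, 0.05)
        res = ggs_select(adj, GraphParams(0.6, 1, 10))
        greedy_steps = [r for r in res.iteration_log if not r.gene.startswith("<")]
        assert not res.exhausted
        assert len(greedy_steps) == len(res.dm_genes) == 10

    def test_oracle_equivalence_small(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            n = int(rng.integers(10, 60))
            adj = random_er_adjacency(rng, n, float(rng.uniform(0.03, 0.2)))
            redundancy = int(rng.integers(1, 4))
            dm_size = int(rng.integers(1, 15))
            res = ggs_select(adj, GraphParams(0.6, redundancy, dm_size))
            dm_ref, pred_ref = naive_ggs(adj, dm_size, redundancy)
            assert res.dm_genes == dm_ref
            assert res.predictable_genes == pred_ref

    def test_ranked_degree_oracle_equivalence(self):
        rng = np.random.default_rng(78)
        for _ in range(10):
            adj = random_er_adjacency(rng, 50, 0.1)
            res = ranked_degree_select(adj, GraphParams(0.6, 2, 10))
            dm_ref, pred_ref = naive_ranked_degree(adj, 10, 2)
            assert res.dm_genes == dm_ref
            assert res.predictable_genes == pred_ref


class TestPredictorSets:
    def test_four_cycle_predictors(self, four_cycle):
        res = ggs_select(four_cycle, GraphParams(0.6, 2, 2))
        preds = predictor_sets(four_cycle, res)
        assert preds == {"B": ["A", "C"], "D": ["A", "C"]}

    def test_star_predictors(self, star_graph):
        res = ggs_select(star_graph, GraphParams(0.6, 1, 1))
        preds = predictor_sets(star_graph, res)
        assert preds == {"B": ["A"], "C": ["A"], "D": ["A"]}

    def test_lists_meet_redundancy(self):
        rng = np.random.default_rng(55)
        adj = random_er_adjacency(rng, 90, 0.07)
        res = ggs_select(adj, GraphParams(0.6, 2, 20))
        universe = adj.loc[res.dm_genes + sorted(res.predictable_genes)]
        for gene, preds in predictor_sets(adj, res).items():
            assert len(preds) >= 2
            assert set(preds) <= set(res.dm_genes)


class TestParameterSweep:
    @pytest.fixture(scope="class")
    def corr(self):
        from ggselect import SyntheticSpec, generate_block_expression, quantile_filter

        expr, _ = generate_block_expression(
            SyntheticSpec(n_blocks=4, block_size=8, n_samples=200, n_background=30, seed=5)
        )
        filtered, _ = quantile_filter(expr)
        return pearson_matrix(filtered)

    def test_grid_shape(self, corr):
        table = parameter_sweep(corr, [0.6, 0.65, 0.7], [1, 2, 3], [2, 4, 8, 12])
        assert len(table) == 3 * 3 * 4

    def test_single_combination_matches_direct_run(self, corr):
        from ggselect import binarize

        table = parameter_sweep(corr, [0.65], [2], [6])
        direct = ggs_select(binarize(corr, 0.65), GraphParams(0.65, 2, 6))
        row = table.iloc[0]
        assert row["n_predictable"] == len(direct.predictable_genes)
        assert row["n_eligible"] == direct.n_eligible
        assert row["n_missed"] == (
            direct.n_eligible - len(direct.dm_genes) - len(direct.predictable_genes)
        )

    def test_prefix_reconstruction_matches_direct_runs(self, corr):
        from ggselect import binarize

        table = parameter_sweep(corr, [0.6], [1], [2, 5, 9])
        adj = binarize(corr, 0.6)
        for _, row in table.iterrows():
            direct = ggs_select(adj, GraphParams(0.6, 1, int(row["dm_size"])))
            assert row["n_predictable"] == len(direct.predictable_genes)

    def test_missed_plus_covered_equals_eligible(self, corr):
        table = parameter_sweep(corr, [0.6, 0.7], [1, 3], [3, 6])
        covered = table["n_dm"].clip(upper=table["n_eligible"]) + table["n_predictable"]
        assert (table["n_missed"] == table["n_eligible"] - covered).all()


class TestSerialization:
    def test_selection_json_roundtrip(self, two_triangles, tmp_path):
        res = ggs_select(two_triangles, GraphParams(0.6, 1, 2))
        path = tmp_path / "sel.json"
        res.to_json(path)
        back = SelectionResult.from_json(path)
        assert back.dm_genes == res.dm_genes
        assert back.predictable_genes == res.predictable_genes
        assert back.params == res.params
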