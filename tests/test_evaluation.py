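"""Enrichment statistics, coherency/depth, homogeneity/connectivity,
consensus, conservation and module overlap."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import build_ontology
from oracles import hypergeom_tail_oracle, wang_term_sim_oracle
from semmod.clustering import ModuleAssignment
from semmod.evaluation import (
    coherence_depth,
    consensus_assignment,
    consensus_matrix,
    conservation_matrix,
    enrichment_summary,
    f_measure,
    fisher_enrichment,
    homogeneity_and_connectivity,
    module_overlap,
    nestedness_fraction,
    summary_grid,
)
from semmod.ontology import build_annotation_table
from semmod.similarity import ExpressionMatrix, InteractionNetwork


def _assignment(labels: dict[str, int]) -> ModuleAssignment:
    genes = sorted(labels)
    exemplars = {}
    for g in genes:
        exemplars.setdefault(labels[g], g)
    return ModuleAssignment(
        genes=genes, labels=dict(labels), exemplars=exemplars,
        n_modules=len(exemplars), converged=True, net_similarity=0.0,
    )


@pytest.fixture(scope="module")
def toy_enrichment(five_term_ontology):
    """10-gene universe, 2 modules of 5; term C annotates exactly module 0."""
    labels = {f"g{i}": (0 if i < 5 else 1) for i in range(10)}
    direct = {f"g{i}": {"C"} for i in range(5)}
    direct.update({f"g{i}": {"D"} for i in range(5, 10)})
    ann = build_annotation_table(direct, five_term_ontology, universe=sorted(labels))
    return _assignment(labels), ann


class TestFisherEnrichment:
    def test_perfect_module_term_match(self, toy_enrichment):
        asg, ann = toy_enrichment
        table = fisher_enrichment(asg, ann)
        row = table[(table["module"] == 0) & (table["term"] == "C")].iloc[0]
        # universe 10, module 5, term 5, overlap 5 -> 1/C(10,5)
        assert row["p_value"] == pytest.approx(1 / 252, abs=1e-15)
        assert row["overlap"] == 5

    def test_saturated_term_has_p_one(self, toy_enrichment):
        asg, ann = toy_enrichment
        table = fisher_enrichment(asg, ann)
        for _, row in table[table["term"] == "R"].iterrows():
            assert row["p_value"] == pytest.approx(1.0)

    def test_matches_pmf_summation_oracle(self, toy_enrichment):
        asg, ann = toy_enrichment
        table = fisher_enrichment(asg, ann)
        for _, row in table.iterrows():
            expected = hypergeom_tail_oracle(
                int(row["overlap"]), int(row["universe_size"]),
                int(row["term_size"]), int(row["module_size"]),
            )
            assert row["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_relabeling(self, toy_enrichment):
        asg, ann = toy_enrichment
        flipped = _assignment({g: 1 - m for g, m in asg.labels.items()})
        a = fisher_enrichment(asg, ann).sort_values(["term", "overlap"])
        b = fisher_enrichment(flipped, ann).sort_values(["term", "overlap"])
        assert np.allclose(a["p_value"].to_numpy(), b["p_value"].to_numpy())


class TestEnrichmentSummary:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["module", "term", "overlap", "module_size",
                           "term_size", "universe_size", "p_value"]
        )

    def test_hand_counts(self):
        table = self._table([
            (0, "t1", 3, 5, 5, 10, 1e-6),
            (0, "t2", 3, 5, 5, 10, 1e-3),
            (1, "t1", 1, 5, 5, 10, 0.9),
        ])
        s = enrichment_summary(table, 1e-4, n_modules=2, n_terms_in_universe=4)
        assert s.n_enriched_terms == 1 and s.n_enriched_modules == 1
        assert s.sensitivity == pytest.approx(1 / 4)
        assert s.specificity == pytest.approx(1 / 2)

    def test_f_measure_formula(self):
        assert f_measure(0.5, 0.5) == pytest.approx(0.5)
        assert f_measure(1.0, 0.0) == 0.0
        assert f_measure(1.0, 0.5) == pytest.approx(2 / 3)

    def test_monotone_in_threshold(self, toy_enrichment):
        asg, ann = toy_enrichment
        table = fisher_enrichment(asg, ann)
        grid = summary_grid(table, asg.n_modules, 5, exponents=range(1, 8))
        assert (grid["sensitivity"].diff().dropna() <= 1e-12).all()
        assert (grid["specificity"].diff().dropna() <= 1e-12).all()

    def test_zero_sizes_rejected(self):
        with pytest.raises(ValueError):
            enrichment_summary(self._table([]), 1e-4, 0, 5)


class TestCoherenceDepth:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["module", "term", "overlap", "module_size",
                           "term_size", "universe_size", "p_value"]
        )

    def test_duplicate_profile_terms_cohere_perfectly(self):
        # two sibling terms sharing an identical single parent chain profile
        onto = build_ontology([("A", "R", "is_a"), ("A2", "R", "is_a")], root="R")
        # identical profiles => pairwise Wang similarity of A with itself is 1;
        # a module enriched for the same term twice degenerates to one term,
        # so use A and A2 whose similarity is strictly < 1, then the true
        # duplicate case: enriched terms {A, A} collapses to m=1
        table = self._table([(0, "A", 2, 3, 3, 9, 1e-9), (0, "A", 2, 3, 3, 9, 1e-9)])
        coh = coherence_depth(table, onto, threshold=1e-5)
        assert coh.per_module.iloc[0]["n_terms"] == 1
        assert np.isnan(coh.per_module.iloc[0]["coherency"])

    def test_root_only_module_has_depth_zero(self, five_term_ontology):
        table = self._table([(0, "R", 5, 5, 10, 10, 1e-9)])
        coh = coherence_depth(table, five_term_ontology, threshold=1e-5)
        assert coh.per_module.iloc[0]["depth"] == 0.0

    def test_three_term_module_mean_of_pairwise(
        self, five_term_ontology, five_term_edges
    ):
        terms = ["A", "B", "C"]
        table = self._table(
            [(0, t, 3, 5, 5, 10, 1e-9) for t in terms]
        )
        coh = coherence_depth(table, five_term_ontology, threshold=1e-5)
        w = {"is_a": 0.8, "part_of": 0.6}
        expected = np.mean(
            [wang_term_sim_oracle(five_term_edges, a, b, w)
             for a, b in itertools.combinations(terms, 2)]
        )
        assert coh.per_module.iloc[0]["coherency"] == pytest.approx(expected, abs=1e-12)
        expected_depth = np.mean([1, 1, 2])
        assert coh.per_module.iloc[0]["depth"] == pytest.approx(expected_depth)


class TestHomogeneityConnectivity:
    def _expr(self, profiles):
        df = pd.DataFrame.from_dict(profiles, orient="index")
        df.columns = [f"c{i}" for i in range(df.shape[1])]
        return ExpressionMatrix(data=df)

    def test_identical_profiles_homogeneity_one(self):
        asg = _assignment({"a": 0, "b": 0, "c": 0})
        expr = self._expr({g: [1, 2, 3, 4] for g in "abc"})
        net = InteractionNetwork(graph=nx.Graph())
        df = homogeneity_and_connectivity(asg, expr, net)
        assert df[df["module"] == 0]["homogeneity"].iloc[0] == pytest.approx(1.0)

    def test_triangle_connectivity_one_path_zero(self):
        asg = _assignment({"a": 0, "b": 0, "c": 0, "x": 1, "y": 1, "z": 1})
        expr = self._expr({g: [1, 2, 3] for g in "abcxyz"})
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z")])
        df = homogeneity_and_connectivity(asg, expr, InteractionNetwork(graph=g))
        assert df[df["module"] == 0]["connectivity"].iloc[0] == pytest.approx(1.0)
        assert df[df["module"] == 1]["connectivity"].iloc[0] == pytest.approx(0.0)

    def test_singleton_excluded_from_overall_homogeneity(self):
        asg = _assignment({"a": 0, "b": 0, "s": 1})
        expr = self._expr({"a": [1, 2, 3], "b": [1, 2, 3], "s": [9, 1, 5]})
        df = homogeneity_and_connectivity(
            asg, expr, InteractionNetwork(graph=nx.Graph())
        )
        overall = df[df["module"] == "overall"].iloc[0]
        assert overall["homogeneity"] == pytest.approx(1.0)


class TestConsensus:
    def test_identical_runs_recover_common_partition(self):
        asg = _assignment({"a": 0, "b": 0, "c": 1, "d": 1})
        out = consensus_assignment([asg, asg, asg], k=2)
        la, lo = asg.label_array(), out.label_array()
        same_a = la[:, None] == la[None, :]
        same_o = lo[:, None] == lo[None, :]
        assert (same_a == same_o).all()

    def test_two_run_counts(self):
        a = _assignment({"a": 0, "b": 0, "c": 1})
        b = _assignment({"a": 0, "b": 1, "c": 1})
        C = consensus_matrix([a, b])
        genes = sorted(a.labels)
        i, j, k = (genes.index(x) for x in ("a", "b", "c"))
        assert C[i, j] == 0.5 and C[i, k] == 0.0 and C[j, k] == 0.5
        assert np.all(np.diag(C) == 1.0)

    def test_noisy_runs_still_recover_planted(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        planted = {g: i // 10 for i, g in enumerate(genes)}
        runs = []
        for _ in range(10):
            labels = dict(planted)
            for g in rng.choice(genes, size=3, replace=False):
                labels[g] = int(rng.integers(3))
            runs.append(_assignment(labels))
        out = consensus_assignment(runs, k=3)
        from sklearn.metrics import adjusted_rand_score

        planted_arr = np.array([planted[g] for g in out.genes])
        assert adjusted_rand_score(planted_arr, out.label_array()) >= 0.9


class TestConservation:
    def test_identical_partitions_count_all_sets(self):
        asg = _assignment({"a": 0, "b": 0, "c": 1})
        M = conservation_matrix([asg, asg, asg])
        genes = sorted(asg.labels)
        i, j = genes.index("a"), genes.index("b")
        assert M[i, j] == 3
        assert np.all(np.diag(M) == 3)

    def test_never_coclustered_pair_is_zero(self):
        a = _assignment({"a": 0, "b": 1})
        M = conservation_matrix([a, a])
        assert M[0, 1] == 0

    def test_nested_partitions_order_entries(self):
        coarse = _assignment({"a": 0, "b": 0, "c": 0, "d": 1})
        fine = _assignment({"a": 0, "b": 0, "c": 1, "d": 2})
        M = conservation_matrix([coarse, fine])
        genes = sorted(coarse.labels)
        ab = M[genes.index("a"), genes.index("b")]
        ac = M[genes.index("a"), genes.index("c")]
        assert ab == 2 and ac == 1
        assert nestedness_fraction(fine, coarse) == 1.0
        assert M.max() <= 2 and M.min() >= 0
        assert np.allclose(M, M.T)


class TestModuleOverlap:
    def test_identical_assignments_have_unit_diagonal(self):
        asg = _assignment({"a": 0, "b": 0, "c": 1})
        tab = module_overlap(asg, asg)
        diag = tab[tab["module_a"] == tab["module_b"]]
        assert (diag["fraction_of_a"] == 1.0).all()

    def test_relabeling_permutes_rows(self):
        a = _assignment({"a": 0, "b": 0, "c": 1})
        b = _assignment({"a": 1, "b": 1, "c": 0})
        tab = module_overlap(a, b)
        hit = tab[(tab["module_a"] == 0) & (tab["module_b"] == 1)].iloc[0]
        assert hit["shared"] == 2 and hit["fraction_of_a"] == 1.0

    def test_fraction_convention(self):
        # 21-gene module with 16 genes in the reference group -> 76%
        labels_a = {f"g{i}": 0 for i in range(21)}
        labels_b = {f"g{i}": (0 if i < 16 else 1) for i in range(21)}
        tab = module_overlap(_assignment(labels_a), _assignment(labels_b))
        hit = tab[(tab["module_a"] == 0) & (tab["module_b"] == 0)].iloc[0]
        assert hit["shared"] == 16
        assert hit["fraction_of_a"] == pytest.approx(16 / 21)
        assert round(100 * hit["fraction_of_a"]) == 76
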