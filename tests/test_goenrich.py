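"""The parent–child-union hypergeometric test, enrichment tables, the
replicated/pruned display tree and paths-to-root."""

import itertools
import math

import numpy as np
import pytest

from isc.entsets import EntityRef, EntitySet, Level
from isc.goenrich import (
    count_copies,
    display_tree,
    enrich,
    entities_for_term,
    paths_to_root,
    pcu_parameters,
    pcu_pvalue,
)
from isc.refdata import AnnotationTable, propagate_annotations

from conftest import make_dag, random_dag


def enumeration_pvalue(universe, members, study, k):
    """Exhaustive oracle: fraction of all draws of size |study ∩ universe|
    from `universe` containing >= k members; independent of any
    distribution function."""
    n = len(study & universe)
    total = 0
    hit = 0
    for draw in itertools.combinations(sorted(universe), n):
        total += 1
        if len(set(draw) & members) >= k:
            hit += 1
    return hit / total


class TestPcuPvalue:
    def test_zero_hits_gives_one(self, diamond):
        dag, table = diamond
        assert pcu_pvalue("C", {"u1", "u2"}, table, dag) == 1.0

    def test_worked_diamond_case(self, diamond):
        """N=9, m=3, n=4, k=3 -> p = C(3,3)*C(6,1)/C(9,4) = 6/126."""
        dag, table = diamond
        study = {"u1", "u4", "u5", "u6", "u10"}
        n_pop, m, n, k = pcu_parameters("C", study, table, dag)
        assert (n_pop, m, n, k) == (9, 3, 4, 3)
        p = pcu_pvalue("C", study, table, dag)
        assert p == pytest.approx(6 / 126, abs=1e-12)

    def test_single_parent_population_is_that_parent(self, diamond):
        dag, table = diamond
        study = {"u1", "u2", "u4"}
        n_pop, m, n, k = pcu_parameters("A", study, table, dag)
        # A's only parent is the root R: population is propagated(R)
        assert n_pop == len(table.propagated["R"])
        assert m == len(table.propagated["A"])

    def test_root_population_is_all_annotated(self, diamond):
        dag, table = diamond
        n_pop, _, _, _ = pcu_parameters("R", {"u1"}, table, dag)
        assert n_pop == 9

    def test_unknown_term_is_an_error(self, diamond):
        dag, table = diamond
        with pytest.raises(KeyError):
            pcu_pvalue("NOPE", {"u1"}, table, dag)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        """Exhaustive enumeration over all draws on random small DAGs."""
        rng = np.random.default_rng(seed)
        dag = random_dag(rng, n_terms=6, max_parents=2)
        terms = sorted(dag.terms)
        units = [f"u{i}" for i in range(int(rng.integers(6, 11)))]
        direct = {}
        for u in units:
            k = int(rng.integers(1, 3))
            direct[u] = {terms[int(j)] for j in rng.choice(len(terms), k, replace=False)}
        table = propagate_annotations(dag, AnnotationTable(direct=direct))
        study = {u for u in units if rng.random() < 0.5}
        for term in terms:
            n_pop, m, n, k = pcu_parameters(term, study, table, dag)
            if n_pop == 0 or n_pop > 12:
                continue
            universe = set()
            parents = dag.parent_ids(term)
            if parents:
                for p in parents:
                    universe |= table.propagated[p]
            else:
                universe = set().union(*table.propagated.values())
            expect = enumeration_pvalue(universe, table.propagated[term], study, k)
            assert pcu_pvalue(term, study, table, dag) == pytest.approx(expect, abs=1e-12)


class TestEnrich:
    def study_set(self, bundle, proteins):
        return EntitySet("spA").add(
            [EntityRef("spA", Level.PROTEIN, p) for p in proteins],
            bundle.genome("spA"),
        )

    def test_empty_snapshot_yields_empty_result(self, bundle42):
        assert enrich(EntitySet("spA"), bundle42) == []

    def test_whole_annotated_genome_is_never_enriched(self, bundle42):
        table = bundle42.annotation_table("spA")
        snapshot = self.study_set(bundle42, sorted(table.universe))
        results = enrich(snapshot, bundle42)
        assert results, "the full universe still produces rows"
        for r in results:
            assert r.p_value == pytest.approx(1.0, abs=1e-12)
            assert r.draws == r.population
            assert r.hits == r.term_total

    def test_self_enrichment_ranks_chosen_term_first(self, bundle42):
        from isc.goenrich import level_annotations

        annotations = level_annotations(bundle42, "spA", Level.PROTEIN)
        # a mid-sized term: neither a leaf singleton nor the root
        term = min(
            (t for t, u in annotations.propagated.items() if 5 <= len(u) <= 20),
            key=lambda t: t,
        )
        snapshot = self.study_set(bundle42, sorted(annotations.propagated[term]))
        results = enrich(snapshot, bundle42)
        best_p = results[0].p_value
        top_terms = {r.term for r in results if r.p_value == pytest.approx(best_p)}
        assert term in top_terms

    def test_sorted_by_pvalue_then_term(self, bundle42):
        table = bundle42.annotation_table("spA")
        snapshot = self.study_set(bundle42, sorted(table.universe)[:12])
        results = enrich(snapshot, bundle42)
        keys = [(r.p_value, r.term) for r in results]
        assert keys == sorted(keys)

    def test_count_invariants(self, bundle42):
        table = bundle42.annotation_table("spA")
        snapshot = self.study_set(bundle42, sorted(table.universe)[:15])
        by_term = {}
        for r in enrich(snapshot, bundle42):
            assert 0 <= r.direct_in_set <= r.subtree_in_set <= r.set_total
            assert r.direct_in_set <= r.direct_in_genome
            assert 0 < r.p_value <= 1
            assert r.hits <= min(r.term_total, r.draws)
            by_term[r.term] = r
        dag = bundle42.require_go()
        for term, r in by_term.items():
            for parent in dag.parent_ids(term):
                if parent in by_term:
                    assert by_term[parent].subtree_in_set >= r.subtree_in_set

    def test_unannotated_members_count_in_set_total(self, bundle42):
        table = bundle42.annotation_table("spA")
        annotated = sorted(table.universe)[:5]
        unannotated = sorted(set(bundle42.genome("spA").proteins) - table.universe)[:3]
        assert unannotated, "generated bundle should leave some proteins unannotated"
        snapshot = self.study_set(bundle42, annotated + unannotated)
        results = enrich(snapshot, bundle42)
        assert results[0].set_total == len(annotated) + len(unannotated)

    def test_deterministic_output(self, bundle42):
        table = bundle42.annotation_table("spA")
        snapshot = self.study_set(bundle42, sorted(table.universe)[:10])
        assert enrich(snapshot, bundle42) == enrich(snapshot, bundle42)

    def test_gene_level_uses_gene_units(self, bundle42):
        genome = bundle42.genome("spA")
        genes = sorted(genome.genes)[:10]
        snapshot = EntitySet("spA").add(
            [EntityRef("spA", Level.GENE, g) for g in genes], genome
        )
        results = enrich(snapshot, bundle42, level=Level.GENE)
        assert results
        assert all(r.set_total == len(genes) for r in results)

    def test_missing_ontology_is_an_error(self, figure1):
        snapshot = EntitySet("spA")
        with pytest.raises(Exception, match="no ontology"):
            enrich(snapshot, figure1)

    def test_bh_values_are_monotone_and_bounded(self, bundle42):
        table = bundle42.annotation_table("spA")
        snapshot = self.study_set(bundle42, sorted(table.universe)[:12])
        results = enrich(snapshot, bundle42, bh=True)
        vals = [r.bh_value for r in results]
        assert all(0 <= v <= 1 for v in vals)
        assert vals == sorted(vals)
        assert all(r.bh_value >= r.p_value - 1e-12 for r in results)


class TestDisplayTree:
    def make_results(self, dag, table, study):
        class FakeBundle:
            pass

        # go through enrich-independent path: build NodeStats via pcu on the fly
        from isc.goenrich import NodeStats

        results = []
        for term in sorted(dag.terms):
            subtree = len(study & table.propagated[term])
            if subtree == 0:
                continue
            results.append(
                NodeStats(
                    term=term, name=term, namespace="", direct_in_set=0,
                    direct_in_genome=0, subtree_in_set=subtree, set_total=len(study),
                    p_value=1.0, population=0, term_total=0, draws=0, hits=0,
                )
            )
        return results

    def test_multi_parent_term_is_replicated(self, diamond):
        dag, table = diamond
        study = {"u4"}  # matches C, hence A, B, R
        trees = display_tree(self.make_results(dag, table, study), dag)
        copies = count_copies(trees)
        assert copies["C"] == 2  # once under A, once under B
        assert copies["A"] == copies["B"] == copies["R"] == 1

    def test_no_matches_gives_empty_forest(self, diamond):
        dag, table = diamond
        assert display_tree([], dag) == []

    def test_match_free_subtrees_are_pruned(self, diamond):
        dag, table = diamond
        study = {"u1"}  # matches A and R only
        trees = display_tree(self.make_results(dag, table, study), dag)
        copies = count_copies(trees)
        assert set(copies) == {"R", "A"}

    @pytest.mark.parametrize("seed", range(5))
    def test_copy_count_equals_path_count_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        dag = random_dag(rng, n_terms=15)
        units = [f"u{i}" for i in range(10)]
        terms = sorted(dag.terms)
        direct = {
            u: {terms[int(j)] for j in rng.choice(len(terms), 2, replace=False)}
            for u in units
        }
        table = propagate_annotations(dag, AnnotationTable(direct=direct))
        study = set(units[:4])
        results = self.make_results(dag, table, study)
        retained = {r.term for r in results}
        trees = display_tree(results, dag)
        copies = count_copies(trees)

        memo: dict[str, int] = {}

        def path_count(term):
            # DFS oracle: number of root-to-term chains through retained terms
            if term in memo:
                return memo[term]
            parents = [p for p in dag.parent_ids(term) if p in retained]
            out = 1 if not parents else sum(path_count(p) for p in parents)
            memo[term] = out
            return out

        for term in retained:
            assert copies[term] == path_count(term)
        assert set(copies) == retained


class TestPaths:
    def test_diamond_paths(self, diamond):
        dag, _ = diamond
        assert paths_to_root("C", dag) == [["C", "A", "R"], ["C", "B", "R"]]

    def test_root_path_is_itself(self, diamond):
        dag, _ = diamond
        assert paths_to_root("R", dag) == [["R"]]

    @pytest.mark.parametrize("seed", range(5))
    def test_path_count_matches_dfs_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        dag = random_dag(rng, n_terms=12)

        def enumerate_paths(term):
            parents = sorted(dag.parent_ids(term))
            if not parents:
                return [[term]]
            return [[term] + rest for p in parents for rest in enumerate_paths(p)]

        for term in sorted(dag.terms):
            expect = sorted(enumerate_paths(term))
            assert paths_to_root(term, dag) == expect


class TestEntitiesForTerm:
    def test_subtree_mode_returns_propagated_set(self, bundle42):
        from isc.goenrich import level_annotations

        annotations = level_annotations(bundle42, "spA", Level.PROTEIN)
        term = max(annotations.propagated, key=lambda t: len(annotations.propagated[t]))
        out = entities_for_term(term, bundle42, "spA", mode="subtree")
        assert out == annotations.propagated[term]

    def test_node_mode_on_unannotated_term_is_empty(self, diamond):
        dag, table = diamond
        # R carries no direct annotation in the diamond fixture
        assert not table.direct_by_term().get("R", set())

    def test_scope_intersection(self, bundle42):
        genome = bundle42.genome("spA")
        table = bundle42.annotation_table("spA")
        prots = sorted(table.universe)[:3]
        scope = EntitySet("spA").add(
            [EntityRef("spA", Level.PROTEIN, p) for p in prots], genome
        )
        term = next(iter(table.direct[prots[0]]))
        out = entities_for_term(term, bundle42, "spA", mode="subtree", scope=scope)
        assert out <= set(prots)

    def test_results_feed_back_into_sets(self, bundle42):
        genome = bundle42.genome("spA")
        table = bundle42.annotation_table("spA")
        term = next(iter(table.direct[sorted(table.universe)[0]]))
        proteins = entities_for_term(term, bundle42, "spA", mode="subtree")
        snap = EntitySet("spA").add(
            [EntityRef("spA", Level.PROTEIN, p) for p in sorted(proteins)], genome
        )
        snap.check_consistent(genome)
        assert snap.protein_ids == proteins
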