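"""Shared fixtures: the fixed worked-example bundle, a seeded random
bundle, and the small diamond-ontology annotation scenario used to pin
the parent–child-union test."""

from __future__ import annotations

import numpy as np
import pytest

from isc.entsets import EntityRef, EntitySet, Level
from isc.refdata import AnnotationTable, GoDag, load_bundle, propagate_annotations
from isc.synthgen import BundleSpec, figure1_bundle, generate_bundle


@pytest.fixture(scope="session")
def figure1_dir(tmp_path_factory):
    return figure1_bundle(tmp_path_factory.mktemp("figure1"))


@pytest.fixture(scope="session")
def figure1(figure1_dir):
    return load_bundle(figure1_dir)


@pytest.fixture(scope="session")
def genome_a(figure1):
    return figure1.genome("spA")


@pytest.fixture(scope="session")
def bundle42_dir(tmp_path_factory):
    return generate_bundle(BundleSpec(seed=42), tmp_path_factory.mktemp("bundle42"))


@pytest.fixture(scope="session")
def bundle42(bundle42_dir):
    return load_bundle(bundle42_dir)


def make_dag(edges: dict[str, list[str]], terms: list[str] | None = None) -> GoDag:
    """Build a GoDag from child -> [parents] is_a edges."""
    dag = GoDag()
    all_terms = set(edges)
    for parents in edges.values():
        all_terms.update(parents)
    if terms:
        all_terms.update(terms)
    for t in sorted(all_terms):
        dag.terms[t] = {"name": t, "namespace": "biological_process"}
        dag.parents[t] = set()
    for child, parents in edges.items():
        for p in parents:
            dag.parents[child].add((p, "is_a"))
    return dag


def random_dag(rng: np.random.Generator, n_terms: int, max_parents: int = 3) -> GoDag:
    """A random acyclic term graph: parents drawn from earlier terms only."""
    names = [f"T{i:03d}" for i in range(n_terms)]
    edges: dict[str, list[str]] = {}
    for i in range(1, n_terms):
        k = int(rng.integers(1, max_parents + 1))
        k = min(k, i)
        parents = rng.choice(i, size=k, replace=False)
        edges[names[i]] = [names[int(p)] for p in parents]
    return make_dag(edges, terms=names)


@pytest.fixture
def diamond():
    """R <- A, R <- B, A <- C, B <- C with propagated sets
    A={u1..u6}, B={u4..u9}, C={u4,u5,u6}."""
    dag = make_dag({"A": ["R"], "B": ["R"], "C": ["A", "B"]})
    table = AnnotationTable(
        direct={
            "u1": {"A"}, "u2": {"A"}, "u3": {"A"},
            "u4": {"C"}, "u5": {"C"}, "u6": {"C"},
            "u7": {"B"}, "u8": {"B"}, "u9": {"B"},
        }
    )
    return dag, propagate_annotations(dag, table)


def entity_set(genome, genes=(), transcripts=(), proteins=()) -> EntitySet:
    """Build a consistent set through the add path (closure applies)."""
    refs = (
        [EntityRef(genome.species, Level.GENE, g) for g in genes]
        + [EntityRef(genome.species, Level.TRANSCRIPT, t) for t in transcripts]
        + [EntityRef(genome.species, Level.PROTEIN, p) for p in proteins]
    )
    return EntitySet(genome.species).add(refs, genome)
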