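"""GO term statistics for snapshots: per-node counts, the
parent–child-union hypergeometric p-value, the replicated/pruned display
tree and paths-to-root.

The parent–child-union test scores a term t against the union of its
parents' propagated annotation sets rather than the whole genome: with
U_t that union, N_t = |U_t|, m_t = |propagated(t)|, n_t = |study ∩ U_t|
and k_t = |study ∩ propagated(t)|, the p-value is the upper tail
P(X >= k_t) of a hypergeometric with population N_t, m_t successes and
n_t draws.  Conditioning on the parents makes the test ask "is this
term enriched beyond what its parents already explain?", which damps
the cascade of trivially significant ancestors that the classic
term-for-term test produces.  For a root term the union is empty and
the population falls back to all annotated units (the term-for-term
case).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from scipy.stats import hypergeom

from isc.entsets import EntitySet, Level
from isc.refdata import (
    AnnotationTable,
    GoDag,
    ReferenceBundle,
    propagate_annotations,
)


@dataclass(frozen=True)
class NodeStats:
    """The per-term display record.

    ``direct_in_set`` / ``direct_in_genome`` count units annotated to
    the node itself; ``subtree_in_set`` counts units annotated anywhere
    in the subtree rooted at the node (true-path closed);
    ``set_total`` is the study-set size at the analysis level.  The
    hypergeometric internals (population, term_total, draws, hits) are
    kept for auditability.
    """

    term: str
    name: str
    namespace: str
    direct_in_set: int
    direct_in_genome: int
    subtree_in_set: int
    set_total: int
    p_value: float
    population: int
    term_total: int
    draws: int
    hits: int
    bh_value: float | None = None


@dataclass
class TreeNode:
    term: str
    stats: NodeStats | None
    children: list["TreeNode"] = field(default_factory=list)


# ---------------------------------------------------------------------------
# the test itself


def pcu_parameters(
    term: str, study: frozenset[str] | set[str], annotations: AnnotationTable, dag: GoDag
) -> tuple[int, int, int, int]:
    """(N_t, m_t, n_t, k_t) for the parent–child-union test of ``term``."""
    if term not in dag.terms:
        raise KeyError(f"unknown term {term!r}")
    if annotations.propagated is None:
        raise ValueError("annotations are not propagated; call propagate_annotations first")
    prop = annotations.propagated
    parents = dag.parent_ids(term)
    if parents:
        universe: set[str] = set()
        for p in parents:
            universe |= prop.get(p, frozenset())
    else:
        universe = set().union(*prop.values()) if prop else set()
    members = prop.get(term, frozenset())
    study = set(study)
    return (
        len(universe),
        len(members),
        len(study & universe),
        len(study & members),
    )


def pcu_pvalue(
    term: str, study: frozenset[str] | set[str], annotations: AnnotationTable, dag: GoDag
) -> float:
    """Upper-tail parent–child-union hypergeometric p-value, in (0, 1].

    An empty parent population (N_t = 0) is defined as p = 1.
    """
    n_pop, m, n, k = pcu_parameters(term, study, annotations, dag)
    if n_pop == 0:
        return 1.0
    # P(X >= k) with X ~ Hypergeom(N, m, n)
    return float(hypergeom.sf(k - 1, n_pop, m, n))


# ---------------------------------------------------------------------------
# level-aware annotation views


def level_annotations(bundle: ReferenceBundle, species: str, level: Level) -> AnnotationTable:
    """Direct annotations re-keyed to the requested level.

    Proteins are the native annotation unit; a transcript inherits its
    protein's terms and a gene the union of its proteins' terms.
    Returns a propagated table (cached on the bundle).
    """
    cache = getattr(bundle, "_annot_cache", None)
    if cache is None:
        cache = {}
        bundle._annot_cache = cache
    key = (species, level)
    if key in cache:
        return cache[key]
    dag = bundle.require_go()
    base = bundle.annotation_table(species)
    if level is Level.PROTEIN:
        table = base
    else:
        genome = bundle.genome(species)
        direct: dict[str, set[str]] = {}
        for protein, terms in base.direct.items():
            transcript = genome.proteins[protein]
            unit = genome.transcripts[transcript] if level is Level.GENE else transcript
            direct.setdefault(unit, set()).update(terms)
        table = AnnotationTable(direct=direct)
    table = propagate_annotations(dag, table)
    cache[key] = table
    return table


# ---------------------------------------------------------------------------
# enrichment


def enrich(
    entity_set: EntitySet,
    bundle: ReferenceBundle,
    level: Level = Level.PROTEIN,
    namespace: str | None = None,
    bh: bool = False,
) -> list[NodeStats]:
    """Score every term with at least one study hit in its subtree.

    Unannotated study members still count toward ``set_total`` but can
    never contribute hits — the universe is never silently shrunk.
    Results are sorted ascending by p-value, ties by term id.  With
    ``bh`` a Benjamini–Hochberg adjusted value is attached (the raw
    p-value stays the primary statistic).
    """
    dag = bundle.require_go()
    species = entity_set.species
    annotations = level_annotations(bundle, species, level)
    study = set(entity_set.project(level))
    set_total = len(study)
    if not study:
        return []
    direct_by_term = annotations.direct_by_term()

    hit_terms: set[str] = set()
    for unit in study:
        for t in annotations.direct.get(unit, ()):
            if t in dag.terms:
                hit_terms.add(t)
                hit_terms |= dag.ancestors(t)

    results: list[NodeStats] = []
    for term in sorted(hit_terms):
        meta = dag.terms[term]
        if namespace is not None and meta.get("namespace") != namespace:
            continue
        n_pop, m, n, k = pcu_parameters(term, study, annotations, dag)
        subtree_in_set = len(study & annotations.propagated[term])
        if subtree_in_set == 0:
            continue
        p = 1.0 if n_pop == 0 else float(hypergeom.sf(k - 1, n_pop, m, n))
        results.append(
            NodeStats(
                term=term,
                name=meta["name"],
                namespace=meta.get("namespace", ""),
                direct_in_set=len(study & direct_by_term.get(term, set())),
                direct_in_genome=len(direct_by_term.get(term, set())),
                subtree_in_set=subtree_in_set,
                set_total=set_total,
                p_value=p,
                population=n_pop,
                term_total=m,
                draws=n,
                hits=k,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    if bh and results:
        n_tests = len(results)
        adjusted = [r.p_value * n_tests / (i + 1) for i, r in enumerate(results)]
        # enforce monotonicity from the largest p down
        for i in range(n_tests - 2, -1, -1):
            adjusted[i] = min(adjusted[i], adjusted[i + 1])
        results = [
            NodeStats(**{**r.__dict__, "bh_value": min(1.0, a)})
            for r, a in zip(results, adjusted)
        ]
    return results


# ---------------------------------------------------------------------------
# display tree and paths


def display_tree(results: Iterable[NodeStats], dag: GoDag) -> list[TreeNode]:
    """The tree rendering of the DAG restricted to scored terms.

    A term with several retained parents appears once under each
    (replication); subtrees without any match are pruned entirely
    because unscored terms are absent from ``results``.  Returns one
    tree per retained ontology root, roots sorted by term id.
    """
    stats = {r.term: r for r in results}

    def build(term: str) -> TreeNode:
        node = TreeNode(term, stats[term])
        for child in sorted(dag.children_of(term)):
            if child in stats:
                node.children.append(build(child))
        return node

    return [build(r) for r in sorted(dag.roots) if r in stats]


def count_copies(trees: Iterable[TreeNode]) -> dict[str, int]:
    """How many times each term appears across the display trees."""
    counts: dict[str, int] = {}

    def walk(node: TreeNode) -> None:
        counts[node.term] = counts.get(node.term, 0) + 1
        for c in node.children:
            walk(c)

    for t in trees:
        walk(t)
    return counts


def paths_to_root(term: str, dag: GoDag) -> list[list[str]]:
    """All distinct parent chains from ``term`` up to a root, sorted
    lexicographically by the term-id sequence."""
    if term not in dag.terms:
        raise KeyError(f"unknown term {term!r}")
    paths: list[list[str]] = []

    def walk(current: str, acc: list[str]) -> None:
        parents = sorted(dag.parent_ids(current))
        if not parents:
            paths.append(acc)
            return
        for p in parents:
            walk(p, acc + [p])

    walk(term, [term])
    paths.sort()
    return paths


def entities_for_term(
    term: str,
    bundle: ReferenceBundle,
    species: str,
    mode: str = "subtree",
    level: Level = Level.PROTEIN,
    scope: EntitySet | None = None,
) -> frozenset[str]:
    """Units annotated to a node (``mode='node'``) or its subtree
    (``mode='subtree'``), optionally intersected with a snapshot scope."""
    dag = bundle.require_go()
    if term not in dag.terms:
        raise KeyError(f"unknown term {term!r}")
    if mode not in ("node", "subtree"):
        raise ValueError(f"mode must be 'node' or 'subtree', got {mode!r}")
    annotations = level_annotations(bundle, species, level)
    if mode == "node":
        units = frozenset(annotations.direct_by_term().get(term, set()))
    else:
        units = annotations.propagated[term]
    if scope is not None:
        units &= scope.project(level)
    return units
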