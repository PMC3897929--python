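"""Interaction-network expansion of snapshots and pathway/EC
classification.

Networks are built on proteins.  When the resulting nodes are added
back to a snapshot, the transitive rule pulls in the coding transcripts
and genes automatically, so the gene-level bookkeeping of interaction
sources is honored without the network code knowing about it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from isc.entsets import EntitySet
from isc.refdata import InteractionGraph, ReferenceBundle


@dataclass
class NetworkResult:
    """An expanded neighborhood: protein nodes tagged seed/added with
    hop distance, plus the induced edge list."""

    nodes: dict[str, tuple[str, int]] = field(default_factory=dict)  # id -> (tag, hops)
    edges: list[tuple[str, str, float | None]] = field(default_factory=list)


class ECStatus(enum.Enum):
    IN_SET = "in_set"
    IN_GENOME_ONLY = "in_genome_only"
    ABSENT = "absent"


@dataclass
class PathwayHighlight:
    pathway_id: str
    name: str
    status: dict[str, ECStatus]  # EC number -> status


def interaction_network(
    entity_set: EntitySet,
    graph: InteractionGraph,
    hops: int = 1,
    mode: str = "any",
    min_score: float | None = None,
) -> NetworkResult:
    """Expand a snapshot's proteins through the interaction graph.

    mode='any' (default): every protein reachable within ``hops`` edges
    of some seed is added; seed proteins without any edge are left out
    of the display (they stay members of the snapshot itself).
    mode='all': only proteins adjacent to *every* seed are added;
    a common-neighbor query only meaningful at hops=1.
    """
    if entity_set.species != graph.species:
        raise ValueError(
            f"snapshot species {entity_set.species!r} does not match "
            f"interaction graph species {graph.species!r}"
        )
    if hops < 1:
        raise ValueError(f"hops must be >= 1, got {hops}")
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    if mode == "all" and hops > 1:
        raise ValueError("mode='all' is a direct-neighbor query; hops must be 1")

    graph = graph.subgraph_above(min_score)
    seeds = set(entity_set.protein_ids)
    seeds_with_edges = {p for p in seeds if graph.neighbors(p)}

    result = NetworkResult()
    if mode == "any":
        # multi-source BFS out to `hops`
        distance = {p: 0 for p in seeds}
        frontier = set(seeds)
        for d in range(1, hops + 1):
            nxt: set[str] = set()
            for p in frontier:
                for q in graph.neighbors(p):
                    if q not in distance:
                        distance[q] = d
                        nxt.add(q)
            frontier = nxt
        kept = seeds_with_edges | {p for p in distance if p not in seeds}
        for p in sorted(kept):
            tag = "seed" if p in seeds else "added"
            result.nodes[p] = (tag, distance[p])
    else:
        common: set[str] | None = None
        for p in seeds:
            neigh = graph.neighbors(p)
            common = neigh if common is None else common & neigh
        common = (common or set()) - seeds
        for p in sorted(seeds_with_edges):
            result.nodes[p] = ("seed", 0)
        for p in sorted(common):
            result.nodes[p] = ("added", 1)

    node_set = set(result.nodes)
    for a, b, data in graph.graph.edges(data=True):
        if a in node_set and b in node_set:
            x, y = sorted((a, b))
            result.edges.append((x, y, data.get("score")))
    result.edges.sort(key=lambda e: (e[0], e[1]))
    return result


def classify_pathway(
    pathway_id: str, entity_set: EntitySet, bundle: ReferenceBundle
) -> PathwayHighlight:
    """Per-EC status of a pathway against a snapshot: IN_SET if a
    snapshot protein carries the EC, IN_GENOME_ONLY if only some other
    protein of the species does, ABSENT otherwise.  '-' components in a
    pathway EC act as wildcards."""
    if bundle.pathways is None or pathway_id not in bundle.pathways.pathways:
        raise KeyError(f"unknown pathway {pathway_id!r}")
    name, ecs = bundle.pathways.pathways[pathway_id]
    species = entity_set.species
    in_set = set(entity_set.protein_ids)
    status: dict[str, ECStatus] = {}
    for ec in sorted(ecs):
        carriers = bundle.pathways.proteins_with_ec(species, ec)
        if carriers & in_set:
            status[ec] = ECStatus.IN_SET
        elif carriers:
            status[ec] = ECStatus.IN_GENOME_ONLY
        else:
            status[ec] = ECStatus.ABSENT
    return PathwayHighlight(pathway_id, name, status)


def entities_for_pathway(
    key: str, bundle: ReferenceBundle, species: str
) -> frozenset[str]:
    """Genes whose proteins carry the EC number ``key``, or any EC of
    the pathway ``key``; suitable for adding to a snapshot."""
    if bundle.pathways is None:
        raise KeyError(f"unknown pathway or EC {key!r} (no pathway data loaded)")
    genome = bundle.genome(species)
    if key in bundle.pathways.pathways:
        ecs = bundle.pathways.pathways[key][1]
    elif any(key in table for table in bundle.pathways.ec_to_proteins.values()) or "-" in key:
        ecs = frozenset({key})
    else:
        raise KeyError(f"unknown pathway or EC {key!r}")
    genes: set[str] = set()
    for ec in ecs:
        for protein in bundle.pathways.proteins_with_ec(species, ec):
            genes.add(genome.gene_of_protein(protein))
    return frozenset(genes)
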