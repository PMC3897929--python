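"""Orthology-based set translation and the miRNA/disease/drug
association lookups.

Translation works purely on the gene projection: every ortholog of
every source gene lands in the target set (many-to-many relations
expand), transcripts and proteins are never carried across, and genes
without any ortholog are dropped from the result but listed in the
report — a translation is lossy, never an error.
"""

from __future__ import annotations

from dataclasses import dataclass

from isc.entsets import EntitySet
from isc.refdata import AssociationTable, GenomeModel, OrthologyMap


@dataclass
class TranslationReport:
    source_species: str
    target_species: str
    mapped: dict[str, frozenset[str]]  # source gene -> target genes
    unmapped: frozenset[str]
    result: EntitySet  # target species, genes only


def translate(
    entity_set: EntitySet,
    target_species: str,
    orthology: OrthologyMap,
    target_genome: GenomeModel,
) -> TranslationReport:
    """Translate a set to ``target_species`` through the orthology map.

    The source set is never mutated; the result is a fresh gene-only
    set for the target species.
    """
    if target_genome.species != target_species:
        raise ValueError(
            f"target genome is for {target_genome.species!r}, not {target_species!r}"
        )
    source_species = entity_set.species
    mapped: dict[str, frozenset[str]] = {}
    unmapped: set[str] = set()
    target_genes: set[str] = set()
    for gene in entity_set.gene_ids:
        orthologs = orthology.orthologs(source_species, gene, target_species)
        if orthologs:
            mapped[gene] = orthologs
            target_genes |= orthologs
        else:
            unmapped.add(gene)
    for g in target_genes:
        if g not in target_genome.genes:
            raise KeyError(f"ortholog {g!r} missing from {target_species!r} genome model")
    return TranslationReport(
        source_species=source_species,
        target_species=target_species,
        mapped=mapped,
        unmapped=frozenset(unmapped),
        result=EntitySet(target_species, gene_ids=frozenset(target_genes)),
    )


def associations_for_set(
    entity_set: EntitySet, table: AssociationTable
) -> list[tuple[str, str, frozenset[str]]]:
    """Every association key whose gene set intersects the snapshot's
    gene projection, with the hit genes; sorted by hit count descending,
    then key id."""
    if table.species != entity_set.species:
        raise ValueError(
            f"association table is for species {table.species!r}, "
            f"snapshot is {entity_set.species!r}"
        )
    genes = entity_set.gene_ids
    hits = []
    for key, (name, key_genes) in table.entries.items():
        overlap = key_genes & genes
        if overlap:
            hits.append((key, name, overlap))
    hits.sort(key=lambda h: (-len(h[2]), h[0]))
    return hits


def entities_for_association(key_id: str, table: AssociationTable) -> frozenset[str]:
    """The full gene set of one association key, ready for set addition."""
    return table.genes_for(key_id)
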