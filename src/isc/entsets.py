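"""Species-bound entity sets over the gene/transcript/protein hierarchy.

The central invariant is transitive consistency: a member protein forces
its coding transcript into the set, and a member transcript forces its
gene in.  The reverse is never implied — a gene may sit in a set without
any of its transcripts, which is what lets a set carry "this gene, but
only this one isoform" semantics.

Sets are immutable; every operation returns a new :class:`EntitySet`.
Operations that need the parent maps (``add``, ``extend``, ``minus``)
take the species' :class:`~isc.refdata.GenomeModel`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover
    from isc.refdata import GenomeModel


class SpeciesMismatchError(ValueError):
    """Raised when an operation mixes sets or entities of different species."""


class UnknownEntityError(KeyError):
    """Raised when an identifier is absent from the species' genome model."""


class Level(enum.Enum):
    """The stratum at which comparisons and set-minus operate.

    Ordered GENE > TRANSCRIPT > PROTEIN: closure propagates upward,
    removal cascades downward.
    """

    GENE = "gene"
    TRANSCRIPT = "transcript"
    PROTEIN = "protein"

    @property
    def rank(self) -> int:
        return {Level.GENE: 2, Level.TRANSCRIPT: 1, Level.PROTEIN: 0}[self]


@dataclass(frozen=True)
class EntityRef:
    """A single identifier qualified by species and level."""

    species: str
    level: Level
    id: str


@dataclass(frozen=True)
class Comparison:
    equal: bool
    subset: bool
    proper_subset: bool


@dataclass(frozen=True)
class EntitySet:
    """A transitively consistent set of genes, transcripts and proteins.

    All members belong to ``species``.  Construct empty sets directly;
    build populated ones through :meth:`add` so the upward closure and
    membership validation apply.
    """

    species: str
    gene_ids: frozenset[str] = field(default_factory=frozenset)
    transcript_ids: frozenset[str] = field(default_factory=frozenset)
    protein_ids: frozenset[str] = field(default_factory=frozenset)

    # -- basic views ---------------------------------------------------

    def project(self, level: Level) -> frozenset[str]:
        """The member identifiers at one level; no closure, no side effects."""
        if level is Level.GENE:
            return self.gene_ids
        if level is Level.TRANSCRIPT:
            return self.transcript_ids
        return self.protein_ids

    def is_empty(self) -> bool:
        return not (self.gene_ids or self.transcript_ids or self.protein_ids)

    def counts(self) -> dict[str, int]:
        return {
            "gene": len(self.gene_ids),
            "transcript": len(self.transcript_ids),
            "protein": len(self.protein_ids),
        }

    # -- mutation (returns new sets) -----------------------------------

    def add(self, entities: Iterable[EntityRef], genome: "GenomeModel") -> "EntitySet":
        """Insert entities together with their upward closure.

        A protein drags in its transcript and gene; a transcript its
        gene; a gene drags in nothing below it.
        """
        genes = set(self.gene_ids)
        transcripts = set(self.transcript_ids)
        proteins = set(self.protein_ids)
        for ref in entities:
            if ref.species != self.species:
                raise SpeciesMismatchError(
                    f"cannot add {ref.species!r} entity {ref.id!r} to a "
                    f"{self.species!r} set; translate it first"
                )
            if ref.level is Level.PROTEIN:
                if ref.id not in genome.proteins:
                    raise UnknownEntityError(f"unknown protein {ref.id!r} in {self.species!r}")
                proteins.add(ref.id)
                t = genome.proteins[ref.id]
                transcripts.add(t)
                genes.add(genome.transcripts[t])
            elif ref.level is Level.TRANSCRIPT:
                if ref.id not in genome.transcripts:
                    raise UnknownEntityError(f"unknown transcript {ref.id!r} in {self.species!r}")
                transcripts.add(ref.id)
                genes.add(genome.transcripts[ref.id])
            else:
                if ref.id not in genome.genes:
                    raise UnknownEntityError(f"unknown gene {ref.id!r} in {self.species!r}")
                genes.add(ref.id)
        return EntitySet(self.species, frozenset(genes), frozenset(transcripts), frozenset(proteins))

    def extend(self, genome: "GenomeModel") -> "EntitySet":
        """Downward closure of the gene projection: for every member gene,
        add all its transcripts and all their proteins."""
        transcripts = set(self.transcript_ids)
        proteins = set(self.protein_ids)
        for g in self.gene_ids:
            for t in genome.transcripts_of_gene(g):
                transcripts.add(t)
                p = genome.protein_of_transcript(t)
                if p is not None:
                    proteins.add(p)
        return EntitySet(self.species, self.gene_ids, frozenset(transcripts), frozenset(proteins))

    def union(self, other: "EntitySet") -> "EntitySet":
        self._check_species(other)
        return EntitySet(
            self.species,
            self.gene_ids | other.gene_ids,
            self.transcript_ids | other.transcript_ids,
            self.protein_ids | other.protein_ids,
        )

    def intersection(self, other: "EntitySet") -> "EntitySet":
        self._check_species(other)
        return EntitySet(
            self.species,
            self.gene_ids & other.gene_ids,
            self.transcript_ids & other.transcript_ids,
            self.protein_ids & other.protein_ids,
        )

    def minus(self, other: "EntitySet", level: Level, genome: "GenomeModel") -> "EntitySet":
        """Remove ``other``'s projection at ``level``, cascading downward.

        Removing a gene removes its member transcripts and their member
        proteins; removing a transcript removes its member proteins;
        removing a protein removes only itself.  Levels above ``level``
        are never touched.
        """
        self._check_species(other)
        remove = other.project(level)
        genes = set(self.gene_ids)
        transcripts = set(self.transcript_ids)
        proteins = set(self.protein_ids)
        if level is Level.GENE:
            genes -= remove
            transcripts = {t for t in transcripts if genome.transcripts[t] in genes}
            proteins = {p for p in proteins if genome.proteins[p] in transcripts}
        elif level is Level.TRANSCRIPT:
            transcripts -= remove
            proteins = {p for p in proteins if genome.proteins[p] in transcripts}
        else:
            proteins -= remove
        return EntitySet(self.species, frozenset(genes), frozenset(transcripts), frozenset(proteins))

    # -- comparison ----------------------------------------------------

    def compare(self, other: "EntitySet", level: Level) -> Comparison:
        """Equality / subset / proper-subset on the two projections at ``level``."""
        self._check_species(other)
        a, b = self.project(level), other.project(level)
        return Comparison(equal=(a == b), subset=a <= b, proper_subset=a < b)

    # -- validation ----------------------------------------------------

    def check_consistent(self, genome: "GenomeModel") -> None:
        """Raise if the transitivity invariant or membership is violated."""
        for p in self.protein_ids:
            if p not in genome.proteins:
                raise UnknownEntityError(f"protein {p!r} not in genome model")
            if genome.proteins[p] not in self.transcript_ids:
                raise ValueError(f"protein {p!r} present without its transcript")
        for t in self.transcript_ids:
            if t not in genome.transcripts:
                raise UnknownEntityError(f"transcript {t!r} not in genome model")
            if genome.transcripts[t] not in self.gene_ids:
                raise ValueError(f"transcript {t!r} present without its gene")
        for g in self.gene_ids:
            if g not in genome.genes:
                raise UnknownEntityError(f"gene {g!r} not in genome model")

    def _check_species(self, other: "EntitySet") -> None:
        if other.species != self.species:
            raise SpeciesMismatchError(
                f"operation mixes species {self.species!r} and {other.species!r}; "
                "use orthology translation to move a set across species"
            )
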