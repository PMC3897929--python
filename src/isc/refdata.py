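"""Reference-data loading: genome models, GO DAG + annotations,
interactions, orthology, associations and pathways.

A *reference bundle* is a directory of plain-text files:

==================  =====================================================
genome.tsv          species, gene_id, gene_name, chromosome, start, end,
                    strand, transcript_id, protein_id (one row per
                    gene–transcript pair; transcript/protein may be empty)
go.obo              OBO 1.2 ontology
annotations.gaf     GAF 2.x annotations (DB-object-ID read as protein id)
interactions.tsv    protein_a, protein_b, score
orthology.tsv       species_a, gene_a, species_b, gene_b
mirna.tsv etc.      key_id, key_name, gene_id  (also disease.tsv, drug.tsv)
ec.tsv              protein_id, ec_number
pathways.tsv        pathway_id, pathway_name, ec_number
==================  =====================================================

Only genome.tsv is required; modules needing an absent file raise when
first used.  All TSVs are tab-separated UTF-8 with one header row;
lines starting with ``#`` are ignored.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import obonet
from intervaltree import IntervalTree

from isc.entsets import Level

log = logging.getLogger(__name__)

GO_RELATIONS = frozenset({"is_a", "part_of"})
ASSOCIATION_KINDS = ("mirna", "disease", "drug")

_EC_RE = re.compile(r"^(\d+|-)\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


class BundleError(ValueError):
    """A reference file violates the documented format or cross-references."""

    def __init__(self, message: str, file: str | None = None, line: int | None = None):
        loc = ""
        if file is not None:
            loc = f"{file}:{line}: " if line is not None else f"{file}: "
        super().__init__(loc + message)
        self.file = file
        self.line = line


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneRecord:
    name: str
    chromosome: str
    start: int
    end: int
    strand: int


@dataclass
class GenomeModel:
    """The gene/transcript/protein hierarchy of one species.

    ``transcripts`` maps transcript id to its gene; ``proteins`` maps
    protein id to its transcript.  Each transcript codes for at most one
    protein, so both maps are functional and the upward closure of any
    entity is unique.
    """

    species: str
    genes: dict[str, GeneRecord] = field(default_factory=dict)
    transcripts: dict[str, str] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)
    _children: dict[str, list[str]] | None = field(default=None, repr=False)
    _t2p: dict[str, str] | None = field(default=None, repr=False)
    _trees: dict[str, IntervalTree] | None = field(default=None, repr=False)

    def transcripts_of_gene(self, gene_id: str) -> list[str]:
        if self._children is None:
            children: dict[str, list[str]] = {}
            for t, g in self.transcripts.items():
                children.setdefault(g, []).append(t)
            self._children = {g: sorted(ts) for g, ts in children.items()}
        return self._children.get(gene_id, [])

    def protein_of_transcript(self, transcript_id: str) -> str | None:
        if self._t2p is None:
            self._t2p = {t: p for p, t in self.proteins.items()}
        return self._t2p.get(transcript_id)

    def gene_of_protein(self, protein_id: str) -> str:
        return self.transcripts[self.proteins[protein_id]]

    def proteins_of_gene(self, gene_id: str) -> list[str]:
        out = []
        for t in self.transcripts_of_gene(gene_id):
            p = self.protein_of_transcript(t)
            if p is not None:
                out.append(p)
        return out

    def level_of(self, entity_id: str) -> Level | None:
        if entity_id in self.genes:
            return Level.GENE
        if entity_id in self.transcripts:
            return Level.TRANSCRIPT
        if entity_id in self.proteins:
            return Level.PROTEIN
        return None


@dataclass
class GoDag:
    """The GO graph restricted to is_a / part_of, child -> parent."""

    terms: dict[str, dict] = field(default_factory=dict)  # id -> {name, namespace}
    parents: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    _children: dict[str, set[str]] | None = field(default=None, repr=False)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.terms if not self.parents.get(t)}

    def parent_ids(self, term: str, relations: frozenset[str] = GO_RELATIONS) -> set[str]:
        return {p for p, rel in self.parents.get(term, set()) if rel in relations}

    def children_of(self, term: str) -> set[str]:
        if self._children is None:
            ch: dict[str, set[str]] = {t: set() for t in self.terms}
            for c, ps in self.parents.items():
                for p, _rel in ps:
                    ch[p].add(c)
            self._children = ch
        return self._children.get(term, set())

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward from ``term``, excluding itself."""
        seen: set[str] = set()
        stack = list(self.parent_ids(term))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parent_ids(t))
        return seen

    def topological_order(self) -> list[str]:
        """Terms ordered children before parents."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for c, ps in self.parents.items():
            for p, _rel in ps:
                g.add_edge(c, p)
        return list(nx.topological_sort(g))


@dataclass
class AnnotationTable:
    """Direct GO annotations plus the true-path-closed view.

    ``direct`` maps an annotated unit (protein by default) to its
    directly assigned terms; ``propagated`` maps a term to every unit
    annotated to it or to any descendant, filled by
    :func:`propagate_annotations`.
    """

    direct: dict[str, set[str]] = field(default_factory=dict)
    propagated: dict[str, frozenset[str]] | None = None

    def direct_by_term(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for unit, terms in self.direct.items():
            for t in terms:
                out.setdefault(t, set()).add(unit)
        return out

    @property
    def universe(self) -> frozenset[str]:
        """Every annotated unit."""
        return frozenset(self.direct)


@dataclass
class InteractionGraph:
    """Undirected protein interaction graph with optional scores in [0, 1000]."""

    species: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def neighbors(self, protein_id: str) -> set[str]:
        if protein_id not in self.graph:
            return set()
        return set(self.graph.neighbors(protein_id))

    def subgraph_above(self, min_score: float | None) -> "InteractionGraph":
        if min_score is None:
            return self
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        for a, b, d in self.graph.edges(data=True):
            s = d.get("score")
            if s is not None and s >= min_score:
                g.add_edge(a, b, **d)
        return InteractionGraph(self.species, g)


@dataclass
class OrthologyMap:
    """Cross-species gene pairs, indexed in both directions."""

    pairs: set[tuple[str, str, str, str]] = field(default_factory=set)
    _index: dict[tuple[str, str, str], set[str]] = field(default_factory=dict, repr=False)

    def add_pair(self, species_a: str, gene_a: str, species_b: str, gene_b: str) -> None:
        self.pairs.add((species_a, gene_a, species_b, gene_b))
        self._index.setdefault((species_a, gene_a, species_b), set()).add(gene_b)
        self._index.setdefault((species_b, gene_b, species_a), set()).add(gene_a)

    def orthologs(self, species: str, gene: str, target_species: str) -> frozenset[str]:
        return frozenset(self._index.get((species, gene, target_species), set()))

    def has_species_pair(self, a: str, b: str) -> bool:
        return any(
            (sa == a and sb == b) or (sa == b and sb == a) for sa, _, sb, _ in self.pairs
        )


@dataclass
class AssociationTable:
    """miRNA-target / disease-gene / drug-target entries for one species."""

    kind: str
    species: str
    entries: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def genes_for(self, key_id: str) -> frozenset[str]:
        if key_id not in self.entries:
            near = [
                k for k, (name, _g) in self.entries.items()
                if key_id.lower() in k.lower() or key_id.lower() in name.lower()
            ]
            hint = f"; near matches: {sorted(near)}" if near else ""
            raise KeyError(f"unknown {self.kind} key {key_id!r}{hint}")
        return self.entries[key_id][1]


@dataclass
class PathwayMap:
    """Pathways as EC-number sets, plus the per-species EC -> protein index."""

    pathways: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    ec_to_proteins: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    def proteins_with_ec(self, species: str, ec_pattern: str) -> frozenset[str]:
        """Proteins of ``species`` whose EC matches ``ec_pattern``;
        '-' components in the pattern match anything."""
        table = self.ec_to_proteins.get(species, {})
        if "-" not in ec_pattern:
            return table.get(ec_pattern, frozenset())
        want = ec_pattern.split(".")
        hits: set[str] = set()
        for ec, prots in table.items():
            have = ec.split(".")
            if all(w in ("-", h) for w, h in zip(want, have)):
                hits |= prots
        return frozenset(hits)


@dataclass
class ReferenceBundle:
    """Everything loaded from one bundle directory."""

    path: Path
    species: dict[str, GenomeModel] = field(default_factory=dict)
    go: GoDag | None = None
    annotations: dict[str, AnnotationTable] = field(default_factory=dict)
    interactions: dict[str, InteractionGraph] = field(default_factory=dict)
    orthology: OrthologyMap = field(default_factory=OrthologyMap)
    associations: dict[tuple[str, str], AssociationTable] = field(default_factory=dict)
    pathways: PathwayMap | None = None

    def genome(self, species: str) -> GenomeModel:
        if species not in self.species:
            raise KeyError(
                f"unknown species {species!r}; bundle has {sorted(self.species)}"
            )
        return self.species[species]

    def require_go(self) -> GoDag:
        if self.go is None or not self.go.terms:
            raise BundleError("no ontology loaded (go.obo missing or empty)")
        return self.go

    def annotation_table(self, species: str) -> AnnotationTable:
        self.genome(species)
        table = self.annotations.get(species)
        if table is None or not table.direct:
            raise BundleError(
                f"no annotations loaded for species {species!r} "
                "(annotations.gaf missing or empty)"
            )
        return table

    def association_table(self, species: str, kind: str) -> AssociationTable:
        if kind not in ASSOCIATION_KINDS:
            raise ValueError(f"unknown association kind {kind!r}")
        table = self.associations.get((species, kind))
        if table is None:
            raise BundleError(f"no {kind} associations loaded for species {species!r}")
        return table

    def interaction_graph(self, species: str) -> InteractionGraph:
        graph = self.interactions.get(species)
        if graph is None:
            raise BundleError(f"no interactions loaded for species {species!r}")
        return graph

    def species_of_entity(self, entity_id: str) -> tuple[str, Level] | None:
        for sp, genome in self.species.items():
            lvl = genome.level_of(entity_id)
            if lvl is not None:
                return sp, lvl
        return None


# ---------------------------------------------------------------------------
# TSV plumbing


def _read_tsv(path: Path, required: list[str]) -> Iterator[tuple[int, dict[str, str]]]:
    """Yield (line number, row dict) from a headered TSV, skipping '#' lines."""
    with open(path, encoding="utf-8", newline="") as fh:
        header: list[str] | None = None
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            if header is None:
                header = [c.strip() for c in row]
                missing = [c for c in required if c not in header]
                if missing:
                    raise BundleError(
                        f"missing required column(s) {missing}", file=path.name, line=lineno
                    )
                continue
            yield lineno, dict(zip(header, (c.strip() for c in row)))


# ---------------------------------------------------------------------------
# loaders


def load_genomes(path: Path) -> dict[str, GenomeModel]:
    genomes: dict[str, GenomeModel] = {}
    owner: dict[str, tuple[str, str]] = {}  # any id -> (species, kind), for uniqueness

    def claim(entity_id: str, species: str, kind: str, lineno: int) -> None:
        prev = owner.get(entity_id)
        if prev is not None and prev != (species, kind):
            raise BundleError(
                f"duplicate identifier {entity_id!r} (already a {prev[1]} of {prev[0]!r})",
                file=path.name,
                line=lineno,
            )
        owner[entity_id] = (species, kind)

    for lineno, row in _read_tsv(
        path, ["species", "gene_id", "chromosome", "start", "end", "strand"]
    ):
        sp = row["species"]
        genome = genomes.setdefault(sp, GenomeModel(species=sp))
        gid = row["gene_id"]
        if not gid:
            raise BundleError("empty gene_id", file=path.name, line=lineno)
        try:
            start, end = int(row["start"]), int(row["end"])
            strand = int(row["strand"])
        except ValueError as exc:
            raise BundleError(f"bad coordinate field: {exc}", file=path.name, line=lineno)
        if start > end:
            raise BundleError(
                f"gene {gid!r} has start > end ({start} > {end})", file=path.name, line=lineno
            )
        if strand not in (1, -1):
            raise BundleError(
                f"gene {gid!r} strand must be 1 or -1, got {row['strand']!r}",
                file=path.name,
                line=lineno,
            )
        record = GeneRecord(row.get("gene_name", ""), row["chromosome"], start, end, strand)
        if gid in genome.genes:
            if genome.genes[gid] != record:
                raise BundleError(
                    f"gene {gid!r} redefined with different coordinates",
                    file=path.name,
                    line=lineno,
                )
        else:
            claim(gid, sp, "gene", lineno)
            genome.genes[gid] = record
        tid = row.get("transcript_id", "")
        pid = row.get("protein_id", "")
        if tid:
            if tid in genome.transcripts and genome.transcripts[tid] != gid:
                raise BundleError(
                    f"transcript {tid!r} assigned to two genes", file=path.name, line=lineno
                )
            claim(tid, sp, "transcript", lineno)
            genome.transcripts[tid] = gid
        if pid:
            if not tid:
                raise BundleError(
                    f"protein {pid!r} given without a transcript", file=path.name, line=lineno
                )
            if pid in genome.proteins and genome.proteins[pid] != tid:
                raise BundleError(
                    f"protein {pid!r} assigned to two transcripts", file=path.name, line=lineno
                )
            existing = {p for p, t in genome.proteins.items() if t == tid}
            if existing - {pid}:
                raise BundleError(
                    f"transcript {tid!r} has more than one protein", file=path.name, line=lineno
                )
            claim(pid, sp, "protein", lineno)
            genome.proteins[pid] = tid
    return genomes


def load_obo(path: Path) -> GoDag:
    graph = obonet.read_obo(path, ignore_obsolete=True)
    dag = GoDag()
    dropped: set[str] = set()
    for term, data in graph.nodes(data=True):
        dag.terms[term] = {
            "name": data.get("name", term),
            "namespace": data.get("namespace", ""),
        }
        dag.parents.setdefault(term, set())
    for child, parent, rel in graph.edges(keys=True):
        if rel not in GO_RELATIONS:
            dropped.add(rel)
            continue
        if parent not in dag.terms:
            raise BundleError(
                f"term {child} references unknown parent {parent}", file=path.name
            )
        dag.parents[child].add((parent, rel))
    if dropped:
        log.warning("ignored OBO relationship types: %s", sorted(dropped))
    _check_acyclic(dag, source=path.name)
    return dag


def _check_acyclic(dag: GoDag, source: str = "ontology") -> None:
    g = nx.DiGraph()
    g.add_nodes_from(dag.terms)
    for c, ps in dag.parents.items():
        for p, _rel in ps:
            g.add_edge(c, p)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise BundleError(f"ontology contains a cycle: {cycle}", file=source)


def load_gaf(path: Path, genomes: dict[str, GenomeModel]) -> dict[str, AnnotationTable]:
    """Read a GAF 2.x file into per-species direct annotation tables.

    Only the DB-object-ID (column 2, read as protein id), qualifier
    (column 4) and GO-ID (column 5) are used; rows whose qualifier
    contains NOT are skipped.
    """
    tables: dict[str, AnnotationTable] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                raise BundleError("GAF row has fewer than 5 columns", file=path.name, line=lineno)
            protein, qualifier, term = cols[1], cols[3], cols[4]
            if "NOT" in qualifier.split("|"):
                continue
            species = None
            for sp, genome in genomes.items():
                if protein in genome.proteins:
                    species = sp
                    break
            if species is None:
                raise BundleError(
                    f"annotation references unknown protein {protein!r}",
                    file=path.name,
                    line=lineno,
                )
            tables.setdefault(species, AnnotationTable()).direct.setdefault(protein, set()).add(term)
    return tables


def load_interactions(
    path: Path, genomes: dict[str, GenomeModel], min_score: float | None = None
) -> dict[str, InteractionGraph]:
    graphs: dict[str, InteractionGraph] = {}
    for lineno, row in _read_tsv(path, ["protein_a", "protein_b"]):
        a, b = row["protein_a"], row["protein_b"]
        if a == b:
            raise BundleError(f"self-interaction on {a!r}", file=path.name, line=lineno)
        sp = None
        for s, genome in genomes.items():
            if a in genome.proteins:
                sp = s
                break
        if sp is None or b not in genomes[sp].proteins:
            bad = a if sp is None else b
            raise BundleError(
                f"interaction references unknown protein {bad!r}", file=path.name, line=lineno
            )
        raw = row.get("score", "")
        score: float | None = None
        if raw:
            score = float(raw)
            if not 0 <= score <= 1000:
                raise BundleError(
                    f"score {score} outside [0, 1000]", file=path.name, line=lineno
                )
            if min_score is not None and score < min_score:
                continue
        elif min_score is not None:
            continue
        graphs.setdefault(sp, InteractionGraph(sp)).graph.add_edge(a, b, score=score)
    return graphs


def load_orthology(path: Path, genomes: dict[str, GenomeModel]) -> OrthologyMap:
    omap = OrthologyMap()
    for lineno, row in _read_tsv(path, ["species_a", "gene_a", "species_b", "gene_b"]):
        sa, ga, sb, gb = row["species_a"], row["gene_a"], row["species_b"], row["gene_b"]
        for sp, g in ((sa, ga), (sb, gb)):
            if sp not in genomes or g not in genomes[sp].genes:
                raise BundleError(
                    f"orthology references unknown gene {g!r} of species {sp!r}",
                    file=path.name,
                    line=lineno,
                )
        omap.add_pair(sa, ga, sb, gb)
    return omap


def load_associations(
    path: Path, kind: str, genomes: dict[str, GenomeModel]
) -> dict[tuple[str, str], AssociationTable]:
    acc: dict[tuple[str, str], dict[str, tuple[str, set[str]]]] = {}
    for lineno, row in _read_tsv(path, ["key_id", "key_name", "gene_id"]):
        key, name, gene = row["key_id"], row["key_name"], row["gene_id"]
        sp = None
        for s, genome in genomes.items():
            if gene in genome.genes:
                sp = s
                break
        if sp is None:
            raise BundleError(
                f"{kind} entry references unknown gene {gene!r}", file=path.name, line=lineno
            )
        entries = acc.setdefault((sp, kind), {})
        if key in entries and entries[key][0] != name:
            raise BundleError(
                f"key {key!r} given two names ({entries[key][0]!r}, {name!r})",
                file=path.name,
                line=lineno,
            )
        entries.setdefault(key, (name, set()))[1].add(gene)
    return {
        (sp, kind): AssociationTable(
            kind, sp, {k: (n, frozenset(g)) for k, (n, g) in entries.items()}
        )
        for (sp, kind), entries in acc.items()
    }


def _validate_ec(ec: str, file: str, line: int) -> str:
    if not _EC_RE.match(ec):
        raise BundleError(f"malformed EC number {ec!r}", file=file, line=line)
    return ec


def load_pathways(
    pathways_path: Path | None, ec_path: Path | None, genomes: dict[str, GenomeModel]
) -> PathwayMap:
    pmap = PathwayMap()
    if ec_path is not None and ec_path.exists():
        for lineno, row in _read_tsv(ec_path, ["protein_id", "ec_number"]):
            pid = row["protein_id"]
            ec = _validate_ec(row["ec_number"], ec_path.name, lineno)
            sp = None
            for s, genome in genomes.items():
                if pid in genome.proteins:
                    sp = s
                    break
            if sp is None:
                raise BundleError(
                    f"EC entry references unknown protein {pid!r}",
                    file=ec_path.name,
                    line=lineno,
                )
            table = pmap.ec_to_proteins.setdefault(sp, {})
            table[ec] = table.get(ec, frozenset()) | {pid}
    if pathways_path is not None and pathways_path.exists():
        acc: dict[str, tuple[str, set[str]]] = {}
        for lineno, row in _read_tsv(pathways_path, ["pathway_id", "pathway_name", "ec_number"]):
            ec = _validate_ec(row["ec_number"], pathways_path.name, lineno)
            acc.setdefault(row["pathway_id"], (row["pathway_name"], set()))[1].add(ec)
        pmap.pathways = {p: (n, frozenset(ecs)) for p, (n, ecs) in acc.items()}
    return pmap


def load_bundle(directory: str | Path, min_interaction_score: float | None = None) -> ReferenceBundle:
    """Load and validate a reference bundle directory.

    Loading is idempotent: the same directory always yields a structurally
    identical bundle.  ``min_interaction_score`` optionally drops
    interaction edges below a score at load time (off by default).
    """
    directory = Path(directory)
    genome_path = directory / "genome.tsv"
    if not genome_path.exists():
        raise BundleError("bundle directory has no genome.tsv", file=str(directory))
    genomes = load_genomes(genome_path)
    bundle = ReferenceBundle(path=directory, species=genomes)

    obo = directory / "go.obo"
    if obo.exists() and obo.stat().st_size > 0:
        bundle.go = load_obo(obo)
    gaf = directory / "annotations.gaf"
    if gaf.exists():
        bundle.annotations = load_gaf(gaf, genomes)
        if bundle.go is not None:
            for table in bundle.annotations.values():
                for unit, terms in table.direct.items():
                    for t in terms:
                        if t not in bundle.go.terms:
                            raise BundleError(
                                f"annotation of {unit!r} references unknown term {t!r}",
                                file=gaf.name,
                            )
    inter = directory / "interactions.tsv"
    if inter.exists():
        bundle.interactions = load_interactions(inter, genomes, min_interaction_score)
    orth = directory / "orthology.tsv"
    if orth.exists():
        bundle.orthology = load_orthology(orth, genomes)
    for kind in ASSOCIATION_KINDS:
        p = directory / f"{kind}.tsv"
        if p.exists():
            bundle.associations.update(load_associations(p, kind, genomes))
    ec_path = directory / "ec.tsv"
    pw_path = directory / "pathways.tsv"
    if ec_path.exists() or pw_path.exists():
        bundle.pathways = load_pathways(pw_path, ec_path, genomes)
    return bundle


# ---------------------------------------------------------------------------
# operations


def propagate_annotations(
    dag: GoDag, table: AnnotationTable, relations: frozenset[str] = GO_RELATIONS
) -> AnnotationTable:
    """Fill the true-path-closed view: propagated(t) is the union of the
    direct annotations of t and the propagated sets of all its children.

    Returns a new table sharing ``direct``; traverses is_a and part_of
    by default.
    """
    by_term = table.direct_by_term()
    propagated: dict[str, set[str]] = {}
    for term in dag.topological_order():  # children before parents
        units = set(by_term.get(term, set()))
        for child in dag.children_of(term):
            rels = {rel for p, rel in dag.parents.get(child, set()) if p == term}
            if rels & relations:
                units |= propagated.get(child, set())
        propagated[term] = units
    return AnnotationTable(
        direct=table.direct, propagated={t: frozenset(u) for t, u in propagated.items()}
    )


def genes_in_region(genome: GenomeModel, chromosome: str, start: int, end: int) -> set[str]:
    """Genes whose 1-based closed interval overlaps [start, end] by >= 1 bp.

    Unknown chromosomes yield an empty set so bundles without coordinate
    data still support every non-genomic module.
    """
    if start > end:
        raise ValueError(f"region start {start} > end {end}")
    if genome._trees is None:
        trees: dict[str, IntervalTree] = {}
        for gid, rec in genome.genes.items():
            # IntervalTree is half-open; +1 makes the stored interval cover
            # the closed [start, end] gene span.
            trees.setdefault(rec.chromosome, IntervalTree()).addi(rec.start, rec.end + 1, gid)
        genome._trees = trees
    tree = genome._trees.get(chromosome)
    if tree is None:
        return set()
    return {iv.data for iv in tree.overlap(start, end + 1)}
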