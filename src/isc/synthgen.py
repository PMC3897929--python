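"""Deterministic synthetic reference bundles.

Two generators live here: :func:`generate_bundle`, which writes a random
but fully valid bundle from a :class:`BundleSpec`, and
:func:`figure1_bundle`, which writes the fixed two-species worked
example used throughout the documentation and tests, together with a
replay script exercising the whole set/container workflow on it.

Only relational structure matters for the downstream modules, so the
generated coordinates and names are minimal.  Each file type draws from
its own seeded random stream, so adding a file type to a spec never
perturbs the files already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# fixed stream indices per file type; appending new types keeps old files stable
_STREAMS = {
    "genome": 1,
    "go": 2,
    "gaf": 3,
    "interactions": 4,
    "orthology": 5,
    "mirna": 6,
    "disease": 7,
    "drug": 8,
    "ec": 9,
    "pathways": 10,
}


@dataclass
class BundleSpec:
    """Parameters of a random reference bundle.

    Defaults describe a small two-species bundle: ~50 genes per species
    with a geometric number of transcripts per gene (mean ~1.5), most
    transcripts coding, a 40-term ontology with up to 3 parents per
    term, and sparse interactions/associations — enough structure for
    every module without being large.
    """

    seed: int = 0
    species_count: int = 2
    genes_per_species: int = 50
    transcripts_per_gene_mean: float = 1.5  # geometric, support >= 1
    protein_probability: float = 0.9
    go_terms: int = 40
    go_roots: int = 1
    max_parents: int = 3
    annotation_density: float = 2.0  # Poisson mean of direct terms per protein
    interaction_edge_prob: float = 0.05
    ortholog_fraction: float = 0.5
    ortholog_fanout_mean: float = 1.2  # geometric, support >= 1
    associations_per_kind: int = 5
    genes_per_association_mean: float = 3.0
    pathway_count: int = 3
    ecs_per_pathway: int = 2
    ec_protein_prob: float = 0.15

    def validate(self) -> None:
        for name in (
            "protein_probability",
            "annotation_density",
            "interaction_edge_prob",
            "ortholog_fraction",
            "ec_protein_prob",
        ):
            v = getattr(self, name)
            if name in ("annotation_density",):
                if v < 0:
                    raise ValueError(f"{name} must be >= 0, got {v}")
            elif not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.go_roots > self.go_terms:
            raise ValueError(
                f"more ontology roots ({self.go_roots}) than terms ({self.go_terms})"
            )
        if self.transcripts_per_gene_mean < 1:
            raise ValueError("transcripts_per_gene_mean must be >= 1")
        if self.species_count < 1 or self.genes_per_species < 1:
            raise ValueError("need at least one species with at least one gene")


def _rng(spec_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([spec_seed, _STREAMS[stream]])


def _species_names(n: int) -> list[str]:
    return [f"sp{chr(ord('A') + i)}" for i in range(n)]


@dataclass
class _Hierarchy:
    genes: list[str] = field(default_factory=list)
    transcripts: dict[str, str] = field(default_factory=dict)  # t -> g
    proteins: dict[str, str] = field(default_factory=dict)  # p -> t


def generate_bundle(spec: BundleSpec, out_dir: str | Path) -> Path:
    """Write a complete random bundle into ``out_dir`` and return the path.

    The same (spec, seed) always produces byte-identical files.
    """
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    species = _species_names(spec.species_count)

    hierarchies = _write_genome(spec, out, species)
    terms = _write_go(spec, out)
    _write_gaf(spec, out, hierarchies, terms)
    _write_interactions(spec, out, hierarchies)
    _write_orthology(spec, out, species, hierarchies)
    for kind in ("mirna", "disease", "drug"):
        _write_association(spec, out, kind, species, hierarchies)
    _write_ec_and_pathways(spec, out, hierarchies)
    return out


def _write_genome(spec: BundleSpec, out: Path, species: list[str]) -> dict[str, _Hierarchy]:
    rng = _rng(spec.seed, "genome")
    hierarchies: dict[str, _Hierarchy] = {}
    rows = ["species\tgene_id\tgene_name\tchromosome\tstart\tend\tstrand\ttranscript_id\tprotein_id"]
    p_geom = 1.0 / spec.transcripts_per_gene_mean
    for sp in species:
        h = _Hierarchy()
        hierarchies[sp] = h
        cursor = {f"chr{i + 1}": 1 for i in range(3)}
        for gi in range(1, spec.genes_per_species + 1):
            gid = f"{sp}_g{gi}"
            h.genes.append(gid)
            chrom = f"chr{int(rng.integers(1, 4))}"
            length = int(rng.integers(500, 5000))
            start = cursor[chrom] + int(rng.integers(0, 2000))
            end = start + length
            cursor[chrom] = end + 1
            strand = 1 if rng.random() < 0.5 else -1
            n_tr = int(rng.geometric(p_geom))
            for ti in range(1, n_tr + 1):
                tid = f"{sp}_g{gi}_t{ti}"
                h.transcripts[tid] = gid
                pid = ""
                if rng.random() < spec.protein_probability:
                    pid = f"{sp}_g{gi}_p{ti}"
                    h.proteins[pid] = tid
                rows.append(
                    f"{sp}\t{gid}\t{gid}_name\t{chrom}\t{start}\t{end}\t{strand}\t{tid}\t{pid}"
                )
    (out / "genome.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    return hierarchies


def _write_go(spec: BundleSpec, out: Path) -> list[str]:
    rng = _rng(spec.seed, "go")
    terms = [f"GO:{i + 1:07d}" for i in range(spec.go_terms)]
    namespaces = ["biological_process", "molecular_function", "cellular_component"]
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    ns_of: dict[str, str] = {}
    for i, term in enumerate(terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: synthetic term {i + 1}")
        if i < spec.go_roots:
            ns = namespaces[i % len(namespaces)]
        else:
            n_par = int(rng.integers(1, spec.max_parents + 1))
            n_par = min(n_par, i)
            parents = rng.choice(i, size=n_par, replace=False)  # earlier terms only: acyclic
            ns = ns_of[terms[int(parents[0])]]
            for j, pidx in enumerate(sorted(int(x) for x in parents)):
                parent = terms[pidx]
                if j == 0 or rng.random() < 0.8:
                    lines.append(f"is_a: {parent} ! synthetic term {pidx + 1}")
                else:
                    lines.append(f"relationship: part_of {parent} ! synthetic term {pidx + 1}")
        ns_of[term] = ns
        lines.append(f"namespace: {ns}")
        lines.append("")
    (out / "go.obo").write_text("\n".join(lines), encoding="utf-8")
    return terms


def _write_gaf(
    spec: BundleSpec, out: Path, hierarchies: dict[str, _Hierarchy], terms: list[str]
) -> None:
    rng = _rng(spec.seed, "gaf")
    lines = ["!gaf-version: 2.1"]
    for sp in sorted(hierarchies):
        for pid in sorted(hierarchies[sp].proteins):
            k = int(rng.poisson(spec.annotation_density))
            if k == 0:
                continue
            k = min(k, len(terms))
            chosen = sorted(int(x) for x in rng.choice(len(terms), size=k, replace=False))
            for idx in chosen:
                lines.append(
                    "\t".join(
                        [
                            "SYN",
                            pid,
                            pid,
                            "",
                            terms[idx],
                            "SYN:0001",
                            "IEA",
                            "",
                            "P",
                            "",
                            "",
                            "protein",
                            "taxon:1",
                            "20130101",
                            "SYN",
                            "",
                            "",
                        ]
                    )
                )
    (out / "annotations.gaf").write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_interactions(spec: BundleSpec, out: Path, hierarchies: dict[str, _Hierarchy]) -> None:
    rng = _rng(spec.seed, "interactions")
    rows = ["protein_a\tprotein_b\tscore"]
    for sp in sorted(hierarchies):
        prots = sorted(hierarchies[sp].proteins)
        for i in range(len(prots)):
            for j in range(i + 1, len(prots)):
                if rng.random() < spec.interaction_edge_prob:
                    score = int(rng.integers(150, 1000))
                    rows.append(f"{prots[i]}\t{prots[j]}\t{score}")
    (out / "interactions.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")


def _write_orthology(
    spec: BundleSpec, out: Path, species: list[str], hierarchies: dict[str, _Hierarchy]
) -> None:
    rng = _rng(spec.seed, "orthology")
    rows = ["species_a\tgene_a\tspecies_b\tgene_b"]
    p_geom = 1.0 / spec.ortholog_fanout_mean
    for a, b in zip(species, species[1:]):
        targets = hierarchies[b].genes
        for gene in hierarchies[a].genes:
            if rng.random() >= spec.ortholog_fraction:
                continue
            fanout = min(int(rng.geometric(p_geom)), len(targets))
            chosen = rng.choice(len(targets), size=fanout, replace=False)
            for idx in sorted(int(x) for x in chosen):
                rows.append(f"{a}\t{gene}\t{b}\t{targets[idx]}")
    (out / "orthology.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")


def _write_association(
    spec: BundleSpec, out: Path, kind: str, species: list[str], hierarchies: dict[str, _Hierarchy]
) -> None:
    rng = _rng(spec.seed, kind)
    prefix = {"mirna": "miR", "disease": "DIS", "drug": "DRG"}[kind]
    rows = ["key_id\tkey_name\tgene_id"]
    for sp in species:
        genes = hierarchies[sp].genes
        for i in range(1, spec.associations_per_kind + 1):
            key = f"{prefix}-{sp}-{i}"
            name = f"{kind} {sp} {i}"
            k = min(1 + int(rng.poisson(spec.genes_per_association_mean)), len(genes))
            chosen = rng.choice(len(genes), size=k, replace=False)
            for idx in sorted(int(x) for x in chosen):
                rows.append(f"{key}\t{name}\t{genes[idx]}")
    (out / f"{kind}.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")


def _write_ec_and_pathways(spec: BundleSpec, out: Path, hierarchies: dict[str, _Hierarchy]) -> None:
    rng = _rng(spec.seed, "ec")
    n_ec = max(spec.pathway_count * spec.ecs_per_pathway, 1)
    ecs = [
        f"{int(rng.integers(1, 7))}.{int(rng.integers(1, 20))}."
        f"{int(rng.integers(1, 20))}.{i + 1}"
        for i in range(n_ec)
    ]
    rows = ["protein_id\tec_number"]
    for sp in sorted(hierarchies):
        for pid in sorted(hierarchies[sp].proteins):
            if rng.random() < spec.ec_protein_prob:
                rows.append(f"{pid}\t{ecs[int(rng.integers(0, n_ec))]}")
    (out / "ec.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")

    prng = _rng(spec.seed, "pathways")
    rows = ["pathway_id\tpathway_name\tec_number"]
    for i in range(1, spec.pathway_count + 1):
        chosen = prng.choice(n_ec, size=min(spec.ecs_per_pathway, n_ec), replace=False)
        for idx in sorted(int(x) for x in chosen):
            rows.append(f"pw{i}\tpathway {i}\t{ecs[idx]}")
    (out / "pathways.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# the fixed worked example
#
# Species A carries five genes; t{a}_{b} is transcript b of gene a and
# p{a}_{b} its protein.  Species B carries four single-transcript genes.
# Only g1 and g2 have orthologs (g6, g7): the scripted workflow needs
# g8 and g9 to be genuinely new in species B, and the reverse
# translation to map a single gene back.  p2_1 exists but has no
# interaction edge, so it drops out of the network view while staying a
# set member.

FIGURE1_SPECIES_A = "spA"
FIGURE1_SPECIES_B = "spB"

FIGURE1_HIERARCHY_A: dict[str, list[tuple[str, str]]] = {
    "g1": [("t1_1", "p1_1"), ("t1_2", "p1_2")],
    "g2": [("t2_1", "p2_1")],
    "g3": [("t3_1", "p3_1")],
    "g4": [("t4_1", "p4_1")],
    "g5": [("t5_1", "p5_1"), ("t5_2", "p5_2")],
}
FIGURE1_HIERARCHY_B: dict[str, list[tuple[str, str]]] = {
    "g6": [("t6_1", "p6_1")],
    "g7": [("t7_1", "p7_1")],
    "g8": [("t8_1", "p8_1")],
    "g9": [("t9_1", "p9_1")],
}
FIGURE1_INTERACTIONS = [("p1_1", "p4_1"), ("p1_2", "p5_1"), ("p3_1", "p5_2")]
FIGURE1_ORTHOLOGY = [("g1", "g6"), ("g2", "g7")]

FIGURE1_REPLAY = """\
# Worked two-species scenario: containers, branching snapshots, the
# transitive rule, extension, network expansion and orthology translation.
container I spA
snapshot a I
add a gene:g1 gene:g2 gene:g3
branch b a
add b protein:p1_1 protein:p4_1
add b transcript:t1_2 transcript:t2_1
remove b gene g3
branch c a
extend c
branch d c
network-add d c
container II spB
snapshot e II
translate-add e d
branch f e
add f gene:g8 gene:g9
remove f gene g7
snapshot g I
translate-add g f
"""


def figure1_bundle(out_dir: str | Path) -> Path:
    """Write the constant worked-example bundle plus ``figure1.replay``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["species\tgene_id\tgene_name\tchromosome\tstart\tend\tstrand\ttranscript_id\tprotein_id"]
    pos = 1000
    for sp, hierarchy in (
        (FIGURE1_SPECIES_A, FIGURE1_HIERARCHY_A),
        (FIGURE1_SPECIES_B, FIGURE1_HIERARCHY_B),
    ):
        for gid in sorted(hierarchy):
            start, end = pos, pos + 999
            pos += 2000
            for tid, pid in hierarchy[gid]:
                rows.append(f"{sp}\t{gid}\t{gid}_name\tchr1\t{start}\t{end}\t1\t{tid}\t{pid}")
    (out / "genome.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")

    rows = ["protein_a\tprotein_b\tscore"]
    for a, b in FIGURE1_INTERACTIONS:
        rows.append(f"{a}\t{b}\t900")
    (out / "interactions.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")

    rows = ["species_a\tgene_a\tspecies_b\tgene_b"]
    for ga, gb in FIGURE1_ORTHOLOGY:
        rows.append(f"{FIGURE1_SPECIES_A}\t{ga}\t{FIGURE1_SPECIES_B}\t{gb}")
    (out / "orthology.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")

    (out / "figure1.replay").write_text(FIGURE1_REPLAY, encoding="utf-8")
    return out
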