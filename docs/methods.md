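# Methods

## The data model

`isc` manages *entity sets*: species-bound sets over the three-level
identifier hierarchy gene ⊃ transcript ⊃ protein. The genome model of a
species supplies two functional maps — every transcript t has one gene
g_t, every protein p one transcript t_p, and a transcript codes for at
most one protein — so the upward closure of any identifier is unique.

The core invariant is **transitive consistency**:

    p ∈ S ⇒ t_p ∈ S        t ∈ S ⇒ g_t ∈ S

The reverse is deliberately not implied: a gene can be a member without
any of its isoforms, which is what lets a set express "this gene, and
specifically this splice variant". Consequences that follow mechanically
from the invariant and that the code enforces:

- `add` inserts an entity together with its upward closure; adding a
  gene adds nothing below it.
- `extend` is the downward closure of the gene projection (all
  transcripts of member genes, all their proteins).
- `union` and `intersection` act element-wise per level and take no
  level parameter; both closure properties are preserved automatically
  (the intersection of two upward-closed sets is upward-closed because
  the parent maps are functions).
- `minus` and the comparisons are *level-aware*: they act on the
  projection at a chosen level. Minus cascades downward — removing a
  gene removes its member transcripts and their proteins — because
  keeping them would violate the invariant, and refusing the removal
  would make gene-level editing impossible.
- Cross-species operations are hard errors; moving a set across species
  is an explicit, lossy orthology translation, never a coercion.

Sets are immutable values; every operation returns a new set and
validates members against the genome model at mutation time.

## Version trees and the history oracle

A *container* is a species-bound collection of snapshot trees; a
*snapshot* is one versioned set state. A child snapshot starts as a
copy of its parent (immutability makes sharing safe), so any older
state can seed a new analysis branch. Removal is restricted to leaves:
no reparenting rule would keep the recorded lineage meaningful.

Every mutating operation appends exactly one history entry recording
the logical action with **fully resolved parameters**: for binary set
operations the other operand's member lists are frozen into the entry,
not referenced. This makes a snapshot's lineage self-contained, and
`Workspace.replay` — recompute a snapshot purely from its recorded
lineage, replaying the parent only up to the child's creation entry —
is the correctness oracle used throughout the tests. Timestamps come
from an injectable clock and are excluded from equality checks.

Workspaces persist as diffable plain text (TSV tables, level-sorted id
lists per snapshot, JSON-encoded action parameters), written atomically
per file (temp + rename).

## The parent–child-union enrichment test

Annotations are true-path propagated: propagated(t) = direct(t) ∪
⋃_child propagated(child), traversing `is_a` and `part_of` (the
relation set is a parameter). For a term t with parent set P(t), let

    U_t = ⋃_{q ∈ P(t)} propagated(q)      (for a root: all annotated units)
    N_t = |U_t|,  m_t = |propagated(t)|,
    n_t = |study ∩ U_t|,  k_t = |study ∩ propagated(t)|

The reported p-value is the upper hypergeometric tail P(X ≥ k_t) with
population N_t, m_t successes and n_t draws, computed with
`scipy.stats.hypergeom.sf`. Conditioning the population on the parents
asks whether a term is enriched *beyond what its parents already
explain*, which suppresses the cascade of trivially significant
ancestors the classic term-for-term test produces. N_t = 0 is defined
as p = 1, and k_t = 0 always yields p = 1.

Displayed per-node counts distinguish direct from subtree membership:
direct-in-set, direct-in-genome, subtree-in-set (propagated), and the
study-set size. Unannotated study members count toward the set total
but can never contribute hits — the universe is not silently shrunk.
Enrichment defaults to the protein level; at gene (or transcript) level
each unit inherits the union of its proteins' direct terms and the same
machinery runs on re-keyed tables. Results sort by (p-value, term id)
so output is bit-deterministic; an optional Benjamini–Hochberg column
is available behind a flag, off by default, since the raw per-node
p-value is the primary statistic of this test.

The display tree renders the DAG restricted to scored terms: a term
with several retained parents is replicated under each, and match-free
subtrees vanish because unscored terms carry no row. Retention is
upward-closed (a parent's subtree count dominates its children's), so
the copy count of a term equals the number of root-to-term chains —
the property the tests check against a DFS path-count oracle.

## Networks, pathways, associations, translation

Network expansion is multi-source BFS on the protein interaction graph
out to a hop count (default 1). The default `any` semantics adds every
protein within reach of *some* seed; `all` is the common-neighbor query
(adjacent to every seed, single hop only). Seed proteins without any
edge are omitted from the network view but never from the snapshot.
Scores live in [0, 1000] (STRING-like); an optional threshold filters
edges at query or at load time, default off, and unscored edges are
dropped only when a threshold is active. Added nodes re-enter snapshots
through the ordinary `add` path, so gene and transcript bookkeeping
follows from the transitive rule.

Pathways are EC-number sets. Classification against a snapshot is a
three-way partition per EC: carried by a snapshot protein, carried only
elsewhere in the genome, or absent from the species. A `-` component in
a pathway EC is a wildcard matching any value at that position.

Association tables (miRNA targets, disease genes, drug targets) key off
genes; forward lookup lists each key intersecting the snapshot's gene
projection with its hit genes (sorted by hit count, then key), reverse
lookup returns a key's full gene set for addition.

Orthology translation operates on the gene projection only: every
ortholog of every source gene lands in the target set (many-to-many
pairs expand), transcripts and proteins are never carried across, and
unmapped genes are dropped from the result but listed in the report —
translation is lossy by design, never an error. For a strictly
one-to-one orthology the round trip A→B→A is the identity on the
mapped genes.

## Collaboration model

Every user owns one private pool; groups own group pools. Two access
levels: NORMAL reads, COORDINATOR additionally publishes and manages
membership; public groups are readable by anyone, and a group always
keeps at least one coordinator. Published entries are deep copies
frozen at publish time — the copy/curate/republish workflow is only
coherent with copies, not live references. There is no authentication
layer: users are workspace identities (`--as USER`); authentication is
a deployment concern outside the library.

## Synthetic reference bundles

The generator emulates the *relational structure* of real reference
data, not its content: gene/transcript/protein hierarchies with a
geometric transcript count (mean 1.5) and 90 % coding transcripts, a
random acyclic ontology (parents drawn only from earlier-indexed terms,
up to 3 per term), Poisson direct annotations (mean 2 per protein),
Bernoulli interaction edges (p = 0.05) with scores in [150, 1000),
partial orthology (half the genes, geometric fan-out mean 1.2), five
association keys per kind and three pathways of two ECs each, for two
species of 50 genes by default. Each file type draws from its own
seeded stream, so generated bundles are byte-reproducible and adding a
file type never perturbs existing files. What the generator does *not*
emulate: realistic coordinates or sequence, identifier vocabularies,
the scale of real genomes, annotation bias, or correlated network
topology — so passing tests demonstrate correctness of the set algebra
and statistics, not robustness to the messiness of production data.

A second, constant generator emits the small two-species worked-example
bundle (five genes with known isoform structure, three interaction
edges, a two-pair orthology) plus a replay script that exercises
upload, branching, the transitive rule, extension, network expansion
and both translation directions; the tests assert every membership that
workflow must produce.

## Numerical and procedural choices

- Coordinates are 1-based fully-closed intervals, strand ∈ {+1, −1};
  region overlap needs ≥ 1 shared base (interval-tree backed). Unknown
  chromosomes return the empty set so coordinate-free bundles still
  support all non-genomic modules.
- GAF rows with a NOT qualifier are skipped; only DB-object-id and
  GO-id columns are consumed. OBO relations other than is_a/part_of
  are ignored with a logged warning. Cycles in the ontology abort
  loading with one witness cycle.
- Ties in enrichment ranking break by term id; all listings sort by id
  so every output is deterministic byte-for-byte.
- Degenerate inputs are legal where a sensible value exists (empty
  sets, empty study, self-operations) and errors where none does
  (start > end, unknown ids, cross-species operands).
- Test problem sizes: the statistical suites run on the 50-gene
  two-species bundle (seed 42); the calibration check uses 10,000
  random study sets of size 15; fuzz suites use 1,000 action sequences,
  500 orthology round trips and 200 random DAGs. These sizes give the
  oracles full coverage of the logic at interactive runtimes.

## Known limitations

- One protein per transcript is a hard assumption of the data model;
  loaders reject polycistronic-style rows.
- No VCS-style merge of divergent snapshots: union/intersection of
  snapshots is the supported reconciliation.
- Single-process workspaces; no concurrent write access.
- Identifier namespaces are taken as-is; accession conversion between
  vocabularies is another tool's job.
- Live imports from primary databases are out of scope; all reference
  data arrives through the documented plain-text formats.
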