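# isc — species-bound gene/transcript/protein set containers

`isc` is a library and command-line tool for *explorative* gene-list
analysis: instead of pushing a fixed list through an annotation
pipeline, you keep sets of genes, transcripts and proteins in versioned
containers, edit them at any point, branch older states, and view each
state through different biological lenses — genome regions, GO
enrichment, protein interactions, pathways, miRNA/disease/drug
associations — including across species via orthology. It is aimed at
researchers (and consortia: sets and results can be shared in group
pools with two access levels) who iterate on small-to-medium gene sets
rather than run one-shot enrichment jobs.

## The model in brief

**Transitive sets.** A set S of one species satisfies

    p ∈ S ⇒ t_p ∈ S        t ∈ S ⇒ g_t ∈ S

where t_p is the protein's transcript and g_t the transcript's gene —
membership closes upward, never downward, so a set can mean "this gene,
but only this isoform". Comparisons (=, ⊂, ⊆) and set-minus operate on
a chosen level (gene / transcript / protein); union and intersection
are element-wise and preserve the invariant automatically.

**Snapshots.** Containers hold trees of snapshots; a child starts as a
copy of its parent, every action is logged, and replaying a snapshot's
history reproduces its content exactly.

**Parent–child-union enrichment.** Each GO term t is scored against
the union U_t of its parents' true-path-propagated annotation sets:
with N_t = |U_t|, m_t = |propagated(t)|, n_t = |study ∩ U_t| and
k_t = |study ∩ propagated(t)|, the p-value is the upper hypergeometric
tail

    p(t) = Σ_{i≥k_t} C(m_t, i) · C(N_t − m_t, n_t − i) / C(N_t, n_t)

which asks whether t is enriched beyond what its parents already
explain. The display tree replicates multi-parent terms under each
parent and prunes match-free subtrees.

All reference data (genome hierarchy, OBO ontology, GAF annotations,
interaction, orthology, association, pathway/EC tables) loads from
documented plain-text formats; a deterministic generator produces
complete synthetic bundles so everything is testable offline.

## Worked example

The packaged fixture is a two-species toy genome: species `spA` has
five genes (g1 carries isoforms t1_1/p1_1 and t1_2/p1_2, …), three
interaction edges, and two orthologs in species `spB` (g1↔g6, g2↔g7).
A replay script drives a full session over it:

```
$ isc fixture figure1 --out bundle
$ isc workspace init --bundle bundle
$ isc replay --script bundle/figure1.replay
```

The script uploads {g1, g2, g3} into snapshot `a`, branches `b` and
`c`, edits `b`, extends `c`, expands `d` through the interaction
network, and translates across species into `e`–`g`. Snapshot `b`
shows the transitive rule at work — adding proteins p1_1 and p4_1
pulled in t1_1, t4_1 and g4, and removing g3 at the gene level
cascaded away its members:

```
$ isc set show --snapshot b
level   id
gene    g1
gene    g2
gene    g4
transcript      t1_1
transcript      t1_2
transcript      t2_1
transcript      t4_1
protein p1_1
protein p4_1
```

The network view of snapshot `c` finds the three interaction partners
of its proteins; p2_1 is a member but edgeless, so it does not appear:

```
$ isc network --snapshot c
protein tag     hops
p1_1    seed    0
p1_2    seed    0
p3_1    seed    0
p4_1    added   1
p5_1    added   1
p5_2    added   1
edge    p1_1    p4_1    900.0
edge    p1_2    p5_1    900.0
edge    p3_1    p5_2    900.0
```

Translating snapshot `d` (all five genes) into species B keeps the two
mapped orthologs and reports g3–g5 as unmapped:

```
$ isc translate --snapshot d --target-species spB
g6
g7
```

Every step is on the record and replayable:

```
$ isc history show --snapshot s2
seq  snapshot  action           params
4    s2        snapshot.create  {"container": "c1", "label": "b", "parent": "s1"}
5    s2        set.add          {"refs": [["protein", "p1_1"], ["protein", "p4_1"]]}
6    s2        set.add          {"refs": [["transcript", "t1_2"], ["transcript", "t2_1"]]}
7    s2        set.minus        {"level": "gene", "members": ["g3"]}
```

The same session is available as library calls (`Workspace`,
`EntitySet`, `enrich`, `interaction_network`, `translate`, …); the CLI
is a thin shell over them.

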