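"""Containers, snapshot version trees, history and persistence.

A *container* is a species-bound collection of snapshots; a *snapshot*
is one versioned state of an entity set.  Snapshots form trees: a child
starts as a copy of its parent, so any older state can become the root
of a new line of analysis.  Every mutating operation appends exactly one
:class:`HistoryEntry`; replaying a snapshot's lineage onto an empty set
reproduces its content, which makes the history the correctness oracle
for the whole workspace.

History records logical actions with fully resolved parameters (member
id lists, not references to other snapshots' future states), so replay
never depends on state outside the recorded lineage.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from isc.entsets import EntityRef, EntitySet, Level
from isc.refdata import ReferenceBundle

# actions whose parameters fully determine a content change
_CONTENT_ACTIONS = {
    "set.add",
    "set.import",
    "set.extend",
    "set.clear",
    "set.union",
    "set.intersect",
    "set.minus",
}


@dataclass
class Container:
    id: str
    species: str
    name: str = ""
    description: str = ""
    color: str = "#888888"
    comments: list[tuple[str, str, str]] = field(default_factory=list)  # (ts, author, text)


@dataclass
class Snapshot:
    id: str
    container_id: str
    parent_id: str | None
    label: str
    created_at: str
    content: EntitySet


@dataclass(frozen=True)
class HistoryEntry:
    seq: int
    timestamp: str
    actor: str
    snapshot_id: str | None
    action: str
    params: dict
    delta: dict  # level -> [added, removed]


def _set_to_triple(es: EntitySet) -> dict[str, list[str]]:
    return {
        "genes": sorted(es.gene_ids),
        "transcripts": sorted(es.transcript_ids),
        "proteins": sorted(es.protein_ids),
    }


def _triple_to_set(species: str, triple: dict) -> EntitySet:
    return EntitySet(
        species,
        frozenset(triple["genes"]),
        frozenset(triple["transcripts"]),
        frozenset(triple["proteins"]),
    )


def _delta(before: EntitySet, after: EntitySet) -> dict:
    out = {}
    for lvl in Level:
        a, b = before.project(lvl), after.project(lvl)
        out[lvl.value] = [len(b - a), len(a - b)]
    return out


class Workspace:
    """All containers, snapshots and history for one reference bundle.

    ``clock`` is injectable for deterministic timestamps in tests;
    ``actor`` names the identity recorded in history entries.
    """

    def __init__(
        self,
        bundle: ReferenceBundle,
        actor: str = "user",
        clock: Callable[[], str] | None = None,
    ):
        self.bundle = bundle
        self.actor = actor
        self._clock = clock or (lambda: time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()))
        self.containers: dict[str, Container] = {}
        self.snapshots: dict[str, Snapshot] = {}
        self.history: list[HistoryEntry] = []
        self._next_container = 1
        self._next_snapshot = 1

    # -- helpers -------------------------------------------------------

    def _log(self, action: str, snapshot_id: str | None, params: dict, delta: dict | None = None):
        self.history.append(
            HistoryEntry(
                seq=len(self.history) + 1,
                timestamp=self._clock(),
                actor=self.actor,
                snapshot_id=snapshot_id,
                action=action,
                params=params,
                delta=delta or {},
            )
        )

    def container(self, container_id: str) -> Container:
        """Resolve a container by id, or by name when that is unambiguous."""
        if container_id in self.containers:
            return self.containers[container_id]
        matches = [c for c in self.containers.values() if c.name == container_id]
        if len(matches) == 1:
            return matches[0]
        if len(matches) > 1:
            raise KeyError(f"container name {container_id!r} is ambiguous")
        raise KeyError(f"unknown container {container_id!r}")

    def snapshot(self, snapshot_id: str) -> Snapshot:
        """Resolve a snapshot by id, or by label when that is unambiguous."""
        if snapshot_id in self.snapshots:
            return self.snapshots[snapshot_id]
        matches = [s for s in self.snapshots.values() if s.label == snapshot_id]
        if len(matches) == 1:
            return matches[0]
        if len(matches) > 1:
            raise KeyError(f"snapshot label {snapshot_id!r} is ambiguous")
        raise KeyError(f"unknown snapshot {snapshot_id!r}")

    def _genome(self, snapshot: Snapshot):
        return self.bundle.genome(snapshot.content.species)

    def children_of(self, snapshot_id: str) -> list[str]:
        return sorted(s.id for s in self.snapshots.values() if s.parent_id == snapshot_id)

    # -- containers ----------------------------------------------------

    def create_container(
        self, species: str, name: str = "", description: str = "", color: str = "#888888"
    ) -> Container:
        self.bundle.genome(species)  # raises on unknown species
        cid = f"c{self._next_container}"
        self._next_container += 1
        cont = Container(cid, species, name=name, description=description, color=color)
        self.containers[cid] = cont
        self._log("container.create", None, {"container": cid, "species": species, "name": name})
        return cont

    def comment_container(self, container_id: str, text: str) -> None:
        cont = self.container(container_id)
        cont.comments.append((self._clock(), self.actor, text))
        self._log("container.comment", None, {"container": container_id, "text": text})

    # -- snapshot tree -------------------------------------------------

    def create_snapshot(
        self, container_id: str, parent_id: str | None = None, label: str = ""
    ) -> Snapshot:
        cont = self.container(container_id)
        if parent_id is not None:
            parent = self.snapshot(parent_id)
            if parent.container_id != cont.id:
                raise ValueError(
                    f"parent {parent_id!r} belongs to container {parent.container_id!r}, "
                    f"not {cont.id!r}"
                )
            content = parent.content  # EntitySet is immutable: sharing == deep copy
        else:
            content = EntitySet(cont.species)
        sid = f"s{self._next_snapshot}"
        self._next_snapshot += 1
        parent_resolved = self.snapshot(parent_id).id if parent_id is not None else None
        snap = Snapshot(sid, cont.id, parent_resolved, label or sid, self._clock(), content)
        self.snapshots[sid] = snap
        self._log(
            "snapshot.create",
            sid,
            {"container": cont.id, "parent": parent_resolved, "label": snap.label},
        )
        return snap

    def copy_snapshot(self, snapshot_id: str, label: str = "") -> Snapshot:
        src = self.snapshot(snapshot_id)
        sid = f"s{self._next_snapshot}"
        self._next_snapshot += 1
        snap = Snapshot(
            sid, src.container_id, src.parent_id, label or f"copy of {src.label}",
            self._clock(), src.content,
        )
        self.snapshots[sid] = snap
        self._log("snapshot.copy", sid, {"source": src.id, "label": snap.label})
        return snap

    def clear_snapshot(self, snapshot_id: str) -> None:
        snap = self.snapshot(snapshot_id)
        before = snap.content
        snap.content = EntitySet(before.species)
        self._log("set.clear", snap.id, {}, _delta(before, snap.content))

    def remove_snapshot(self, snapshot_id: str) -> None:
        snap = self.snapshot(snapshot_id)
        children = self.children_of(snapshot_id)
        if children:
            raise ValueError(
                f"cannot remove snapshot {snapshot_id!r}: it has children {children}"
            )
        del self.snapshots[snap.id]
        self._log("snapshot.remove", snap.id, {})

    # -- set mutation --------------------------------------------------

    def _mutate(self, snapshot_id: str, action: str, params: dict, new_content: EntitySet):
        snap = self.snapshot(snapshot_id)
        delta = _delta(snap.content, new_content)
        snap.content = new_content
        self._log(action, snap.id, params, delta)

    def add_entities(self, snapshot_id: str, refs: Iterable[EntityRef]) -> Snapshot:
        snap = self.snapshot(snapshot_id)
        refs = list(refs)
        new = snap.content.add(refs, self._genome(snap))
        self._mutate(
            snapshot_id,
            "set.add",
            {"refs": [[r.level.value, r.id] for r in refs]},
            new,
        )
        return snap

    def extend_snapshot(self, snapshot_id: str) -> Snapshot:
        snap = self.snapshot(snapshot_id)
        self._mutate(snapshot_id, "set.extend", {}, snap.content.extend(self._genome(snap)))
        return snap

    def union_into(self, snapshot_id: str, other_id: str) -> Snapshot:
        snap, other = self.snapshot(snapshot_id), self.snapshot(other_id)
        new = snap.content.union(other.content)
        self._mutate(
            snapshot_id, "set.union",
            {"other": other.id, "members": _set_to_triple(other.content)}, new,
        )
        return snap

    def intersect_into(self, snapshot_id: str, other_id: str) -> Snapshot:
        snap, other = self.snapshot(snapshot_id), self.snapshot(other_id)
        new = snap.content.intersection(other.content)
        self._mutate(
            snapshot_id, "set.intersect",
            {"other": other.id, "members": _set_to_triple(other.content)}, new,
        )
        return snap

    def minus_from(self, snapshot_id: str, other_id: str, level: Level) -> Snapshot:
        snap, other = self.snapshot(snapshot_id), self.snapshot(other_id)
        new = snap.content.minus(other.content, level, self._genome(snap))
        self._mutate(
            snapshot_id, "set.minus",
            {
                "other": other.id,
                "level": level.value,
                "members": sorted(other.content.project(level)),
            },
            new,
        )
        return snap

    def remove_entities(self, snapshot_id: str, ids: Iterable[str], level: Level) -> Snapshot:
        """Set-minus against an ad-hoc id list at ``level``."""
        snap = self.snapshot(snapshot_id)
        species = snap.content.species
        ids = sorted(set(ids))
        other = EntitySet(species).add(
            [EntityRef(species, level, i) for i in ids], self._genome(snap)
        )
        new = snap.content.minus(other, level, self._genome(snap))
        self._mutate(
            snapshot_id, "set.minus", {"level": level.value, "members": ids}, new
        )
        return snap

    # -- import / export ----------------------------------------------

    def resolve_ids(self, species: str, lines: Iterable[str]) -> list[EntityRef]:
        """Resolve bare ids (with optional ``# level:`` directive lines)
        against the species' genome model; all offenders reported at once."""
        genome = self.bundle.genome(species)
        default_level: Level | None = None
        refs: list[EntityRef] = []
        bad: list[str] = []
        for raw in lines:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                directive = line.lstrip("#").strip()
                if directive.lower().startswith("level:"):
                    default_level = Level(directive.split(":", 1)[1].strip().lower())
                continue
            level = default_level or genome.level_of(line)
            if level is None or (
                default_level is not None and line not in {
                    Level.GENE: genome.genes,
                    Level.TRANSCRIPT: genome.transcripts,
                    Level.PROTEIN: genome.proteins,
                }[default_level]
            ):
                bad.append(line)
                continue
            refs.append(EntityRef(species, level, line))
        if bad:
            raise KeyError(
                f"identifier(s) not found in species {species!r}: {sorted(set(bad))}"
            )
        return refs

    def import_set(self, snapshot_id: str, list_file: str | Path) -> Snapshot:
        snap = self.snapshot(snapshot_id)
        lines = Path(list_file).read_text(encoding="utf-8").splitlines()
        refs = self.resolve_ids(snap.content.species, lines)  # raises before any mutation
        new = snap.content.add(refs, self._genome(snap))
        self._mutate(
            snapshot_id, "set.import",
            {"file": str(list_file), "refs": [[r.level.value, r.id] for r in refs]},
            new,
        )
        return snap

    def export_set(self, snapshot_id: str, level: Level, out_file: str | Path) -> None:
        snap = self.snapshot(snapshot_id)
        ids = sorted(snap.content.project(level))
        Path(out_file).write_text(
            f"# level: {level.value}\n" + "".join(i + "\n" for i in ids), encoding="utf-8"
        )

    # -- history -------------------------------------------------------

    def history_entries(
        self,
        snapshot_id: str | None = None,
        container_id: str | None = None,
        actor: str | None = None,
    ) -> list[HistoryEntry]:
        out = []
        for e in self.history:
            if snapshot_id is not None and e.snapshot_id != snapshot_id:
                continue
            if actor is not None and e.actor != actor:
                continue
            if container_id is not None:
                snap = self.snapshots.get(e.snapshot_id) if e.snapshot_id else None
                in_container = (snap is not None and snap.container_id == container_id) or (
                    e.params.get("container") == container_id
                )
                if not in_container:
                    continue
            out.append(e)
        return out

    def replay(self, snapshot_id: str, upto_seq: int | None = None) -> EntitySet:
        """Recompute a snapshot's content purely from its recorded lineage.

        The parent's state is replayed up to the child's creation entry,
        so later edits of the parent never leak into the child.
        """
        entries = [
            e
            for e in self.history
            if e.snapshot_id == snapshot_id and (upto_seq is None or e.seq <= upto_seq)
        ]
        if not entries or entries[0].action not in ("snapshot.create", "snapshot.copy"):
            raise ValueError(f"no creation record for snapshot {snapshot_id!r}")
        create = entries[0]
        if create.action == "snapshot.copy":
            content = self.replay(create.params["source"], upto_seq=create.seq)
            species = content.species
        else:
            species = self.container(create.params["container"]).species
            parent = create.params.get("parent")
            content = (
                self.replay(parent, upto_seq=create.seq)
                if parent
                else EntitySet(species)
            )
        genome = self.bundle.genome(species)
        for e in entries[1:]:
            if e.action not in _CONTENT_ACTIONS:
                continue
            if e.action in ("set.add", "set.import"):
                refs = [EntityRef(species, Level(lvl), i) for lvl, i in e.params["refs"]]
                content = content.add(refs, genome)
            elif e.action == "set.extend":
                content = content.extend(genome)
            elif e.action == "set.clear":
                content = EntitySet(species)
            elif e.action == "set.union":
                content = content.union(_triple_to_set(species, e.params["members"]))
            elif e.action == "set.intersect":
                content = content.intersection(_triple_to_set(species, e.params["members"]))
            elif e.action == "set.minus":
                level = Level(e.params["level"])
                other = EntitySet(species)
                kw = {
                    Level.GENE: "gene_ids",
                    Level.TRANSCRIPT: "transcript_ids",
                    Level.PROTEIN: "protein_ids",
                }[level]
                other = EntitySet(species, **{kw: frozenset(e.params["members"])})
                content = content.minus(other, level, genome)
        return content

    # -- persistence ---------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write the workspace as plain, diffable text files (atomic per file)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "sets").mkdir(exist_ok=True)

        def write(path: Path, text: str) -> None:
            tmp = path.with_suffix(path.suffix + ".tmp")
            tmp.write_text(text, encoding="utf-8")
            os.replace(tmp, path)

        rows = ["id\tspecies\tname\tdescription\tcolor"]
        for c in sorted(self.containers.values(), key=lambda c: c.id):
            rows.append(f"{c.id}\t{c.species}\t{c.name}\t{c.description}\t{c.color}")
        write(directory / "containers.tsv", "\n".join(rows) + "\n")

        rows = ["timestamp\tauthor\tcontainer\ttext"]
        for c in sorted(self.containers.values(), key=lambda c: c.id):
            for ts, author, text in c.comments:
                rows.append(f"{ts}\t{author}\t{c.id}\t{text}")
        write(directory / "comments.tsv", "\n".join(rows) + "\n")

        rows = ["id\tcontainer\tparent\tlabel\tcreated_at"]
        for s in sorted(self.snapshots.values(), key=lambda s: int(s.id[1:])):
            rows.append(f"{s.id}\t{s.container_id}\t{s.parent_id or ''}\t{s.label}\t{s.created_at}")
        write(directory / "snapshots.tsv", "\n".join(rows) + "\n")

        for s in self.snapshots.values():
            lines = []
            for lvl in Level:
                for i in sorted(s.content.project(lvl)):
                    lines.append(f"{lvl.value}\t{i}")
            write(directory / "sets" / f"{s.id}.tsv", "".join(l + "\n" for l in lines))
        for stale in (directory / "sets").glob("*.tsv"):
            if stale.stem not in self.snapshots:
                stale.unlink()

        rows = ["seq\ttimestamp\tactor\tsnapshot\taction\tparams\tdelta"]
        for e in self.history:
            rows.append(
                f"{e.seq}\t{e.timestamp}\t{e.actor}\t{e.snapshot_id or ''}\t{e.action}\t"
                f"{json.dumps(e.params, sort_keys=True)}\t{json.dumps(e.delta, sort_keys=True)}"
            )
        write(directory / "history.tsv", "\n".join(rows) + "\n")

        write(
            directory / "meta.json",
            json.dumps(
                {
                    "next_container": self._next_container,
                    "next_snapshot": self._next_snapshot,
                    "actor": self.actor,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n",
        )

    @classmethod
    def load(
        cls,
        directory: str | Path,
        bundle: ReferenceBundle,
        clock: Callable[[], str] | None = None,
    ) -> "Workspace":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text(encoding="utf-8"))
        ws = cls(bundle, actor=meta.get("actor", "user"), clock=clock)
        ws._next_container = meta["next_container"]
        ws._next_snapshot = meta["next_snapshot"]

        def rows(name: str):
            lines = (directory / name).read_text(encoding="utf-8").splitlines()
            header = lines[0].split("\t")
            for line in lines[1:]:
                if line:
                    yield dict(zip(header, line.split("\t")))

        for r in rows("containers.tsv"):
            ws.containers[r["id"]] = Container(
                r["id"], r["species"], name=r["name"],
                description=r["description"], color=r["color"],
            )
        for r in rows("comments.tsv"):
            ws.containers[r["container"]].comments.append(
                (r["timestamp"], r["author"], r["text"])
            )
        for r in rows("snapshots.tsv"):
            species = ws.containers[r["container"]].species
            content = EntitySet(species)
            set_path = directory / "sets" / f"{r['id']}.tsv"
            genes, transcripts, proteins = set(), set(), set()
            if set_path.exists():
                for line in set_path.read_text(encoding="utf-8").splitlines():
                    lvl, i = line.split("\t")
                    {"gene": genes, "transcript": transcripts, "protein": proteins}[lvl].add(i)
            content = EntitySet(
                species, frozenset(genes), frozenset(transcripts), frozenset(proteins)
            )
            ws.snapshots[r["id"]] = Snapshot(
                r["id"], r["container"], r["parent"] or None, r["label"],
                r["created_at"], content,
            )
        for r in rows("history.tsv"):
            ws.history.append(
                HistoryEntry(
                    seq=int(r["seq"]),
                    timestamp=r["timestamp"],
                    actor=r["actor"],
                    snapshot_id=r["snapshot"] or None,
                    action=r["action"],
                    params=json.loads(r["params"]),
                    delta=json.loads(r["delta"]),
                )
            )
        return ws


# ---------------------------------------------------------------------------
# replay scripts


def run_script(
    workspace: Workspace, script: str | Path | Iterable[str]
) -> dict[str, str]:
    """Execute a replay script: one whitespace-tokenized action per line.

    Verbs: ``container NAME SPECIES`` — create a container;
    ``snapshot NAME CONTAINER`` — root snapshot; ``branch NAME PARENT``
    — child snapshot; ``add NAME level:id ...``; ``remove NAME LEVEL id
    ...``; ``extend NAME``; ``import NAME FILE``;
    ``network-add NAME SOURCE [hops] [mode]`` — add the interaction
    neighborhood of SOURCE; ``translate-add NAME SOURCE`` — add the
    orthologs of SOURCE's genes.  Returns the name -> workspace-id map.
    """
    from isc.netpath import interaction_network
    from isc.xspecies import translate

    if isinstance(script, (str, Path)) and "\n" not in str(script):
        lines = Path(script).read_text(encoding="utf-8").splitlines()
    elif isinstance(script, str):
        lines = script.splitlines()
    else:
        lines = list(script)

    names: dict[str, str] = {}  # script name -> container/snapshot id

    def snap(name: str) -> Snapshot:
        return workspace.snapshot(names[name])

    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        verb, *args = line.split()
        if verb == "container":
            name, species = args
            names[name] = workspace.create_container(species, name=name).id
        elif verb == "snapshot":
            name, container = args
            names[name] = workspace.create_snapshot(names[container], label=name).id
        elif verb == "branch":
            name, parent = args
            parent_snap = snap(parent)
            names[name] = workspace.create_snapshot(
                parent_snap.container_id, parent_id=parent_snap.id, label=name
            ).id
        elif verb == "add":
            name, *specs = args
            species = snap(name).content.species
            refs = []
            for s in specs:
                lvl, i = s.split(":", 1)
                refs.append(EntityRef(species, Level(lvl), i))
            workspace.add_entities(names[name], refs)
        elif verb == "remove":
            name, level, *ids = args
            workspace.remove_entities(names[name], ids, Level(level))
        elif verb == "extend":
            workspace.extend_snapshot(names[args[0]])
        elif verb == "import":
            name, file = args
            workspace.import_set(names[name], file)
        elif verb == "network-add":
            name, source = args[0], args[1]
            hops = int(args[2]) if len(args) > 2 else 1
            mode = args[3] if len(args) > 3 else "any"
            src = snap(source)
            graph = workspace.bundle.interaction_graph(src.content.species)
            result = interaction_network(src.content, graph, hops=hops, mode=mode)
            refs = [
                EntityRef(src.content.species, Level.PROTEIN, p) for p in sorted(result.nodes)
            ]
            workspace.add_entities(names[name], refs)
        elif verb == "translate-add":
            name, source = args
            target = snap(name)
            report = translate(
                snap(source).content,
                target.content.species,
                workspace.bundle.orthology,
                workspace.bundle.genome(target.content.species),
            )
            refs = [
                EntityRef(target.content.species, Level.GENE, g)
                for g in sorted(report.result.gene_ids)
            ]
            workspace.add_entities(names[name], refs)
        else:
            raise ValueError(f"unknown replay verb {verb!r}")
    return names
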