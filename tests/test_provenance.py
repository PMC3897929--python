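"""Containers, snapshot version trees, history replay and workspace
persistence."""

import itertools
import random

import pytest

from isc.entsets import EntityRef, EntitySet, Level
from isc.provenance import Workspace, run_script


def fixed_clock():
    counter = itertools.count()
    return lambda: f"2014-01-15T00:00:{next(counter) % 60:02d}"


@pytest.fixture()
def ws(figure1):
    return Workspace(figure1, actor="user1", clock=fixed_clock())


def add_genes(ws, sid, genes):
    species = ws.snapshot(sid).content.species
    ws.add_entities(sid, [EntityRef(species, Level.GENE, g) for g in genes])


class TestContainers:
    def test_create_empty_container(self, ws):
        cont = ws.create_container("spA", name="container I")
        assert not [s for s in ws.snapshots.values() if s.container_id == cont.id]

    def test_duplicate_names_allowed_ids_distinct(self, ws):
        a = ws.create_container("spA", name="same")
        b = ws.create_container("spA", name="same")
        assert a.id != b.id

    def test_unknown_species_refused(self, ws):
        with pytest.raises(KeyError, match="spX"):
            ws.create_container("spX")


class TestSnapshotTree:
    def test_child_copies_parent_and_stays_independent(self, ws):
        cont = ws.create_container("spA")
        parent = ws.create_snapshot(cont.id)
        add_genes(ws, parent.id, ["g1", "g2", "g3"])
        child = ws.create_snapshot(cont.id, parent_id=parent.id)
        assert child.content.gene_ids == {"g1", "g2", "g3"}
        add_genes(ws, child.id, ["g4"])
        assert ws.snapshot(parent.id).content.gene_ids == {"g1", "g2", "g3"}

    def test_root_snapshot_is_empty(self, figure1):
        ws = Workspace(figure1)
        cont = ws.create_container("spB", name="container II")
        snap = ws.create_snapshot(cont.id)
        assert snap.content == EntitySet("spB")

    def test_clearing_child_spares_parent(self, ws):
        cont = ws.create_container("spA")
        parent = ws.create_snapshot(cont.id)
        add_genes(ws, parent.id, ["g1"])
        child = ws.create_snapshot(cont.id, parent_id=parent.id)
        ws.clear_snapshot(child.id)
        assert ws.snapshot(child.id).content.is_empty()
        assert ws.snapshot(parent.id).content.gene_ids == {"g1"}

    def test_parent_from_other_container_refused(self, ws):
        c1, c2 = ws.create_container("spA"), ws.create_container("spA")
        parent = ws.create_snapshot(c1.id)
        with pytest.raises(ValueError, match="belongs to container"):
            ws.create_snapshot(c2.id, parent_id=parent.id)

    def test_copy_gives_equal_projections(self, ws):
        cont = ws.create_container("spA")
        snap = ws.create_snapshot(cont.id)
        ws.add_entities(snap.id, [EntityRef("spA", Level.PROTEIN, "p1_1")])
        dup = ws.copy_snapshot(snap.id)
        for level in Level:
            assert dup.content.project(level) == snap.content.project(level)

    def test_remove_leaf_only(self, ws):
        cont = ws.create_container("spA")
        parent = ws.create_snapshot(cont.id)
        child = ws.create_snapshot(cont.id, parent_id=parent.id)
        with pytest.raises(ValueError, match="children"):
            ws.remove_snapshot(parent.id)
        ws.remove_snapshot(child.id)
        ws.remove_snapshot(parent.id)
        assert not ws.snapshots

    def test_forest_property_no_cycles(self, ws):
        cont = ws.create_container("spA")
        sids = [ws.create_snapshot(cont.id).id]
        rng = random.Random(5)
        for _ in range(20):
            sids.append(ws.create_snapshot(cont.id, parent_id=rng.choice(sids)).id)
        for sid in sids:
            seen = set()
            cur = sid
            while cur is not None:
                assert cur not in seen
                seen.add(cur)
                cur = ws.snapshot(cur).parent_id


class TestImportExport:
    def test_import_three_genes(self, ws, tmp_path):
        cont = ws.create_container("spA")
        snap = ws.create_snapshot(cont.id, label="a")
        f = tmp_path / "genes.txt"
        f.write_text("g1\ng2\ng3\n")
        ws.import_set(snap.id, f)
        assert ws.snapshot(snap.id).content.counts()["gene"] == 3

    def test_export_import_round_trip(self, ws, tmp_path):
        cont = ws.create_container("spA")
        snap = ws.create_snapshot(cont.id)
        ws.add_entities(snap.id, [EntityRef("spA", Level.PROTEIN, "p1_1")])
        out = tmp_path / "out.txt"
        ws.export_set(snap.id, Level.GENE, out)
        fresh = ws.create_snapshot(cont.id)
        ws.import_set(fresh.id, out)
        assert ws.snapshot(fresh.id).content.compare(
            ws.snapshot(snap.id).content, Level.GENE
        ).equal

    def test_bad_id_leaves_snapshot_unchanged(self, ws, tmp_path):
        cont = ws.create_container("spA")
        snap = ws.create_snapshot(cont.id)
        f = tmp_path / "bad.txt"
        f.write_text("g1\nbogus\n")
        with pytest.raises(KeyError, match="bogus"):
            ws.import_set(snap.id, f)
        assert ws.snapshot(snap.id).content.is_empty()

    def test_level_directive_forces_level(self, ws, tmp_path):
        cont = ws.create_container("spA")
        snap = ws.create_snapshot(cont.id)
        f = tmp_path / "prot.txt"
        f.write_text("# level: protein\np1_1\n")
        ws.import_set(snap.id, f)
        assert ws.snapshot(snap.id).content.protein_ids == {"p1_1"}


class TestHistory:
    def test_fresh_workspace_has_no_history(self, figure1):
        assert Workspace(figure1).history == []

    def test_filter_by_actor(self, figure1):
        ws = Workspace(figure1, actor="user1", clock=fixed_clock())
        ws.create_container("spA")
        ws.actor = "user2"
        ws.create_container("spB")
        assert [e.actor for e in ws.history_entries(actor="user1")] == ["user1"]

    def test_every_mutation_appends_exactly_one_entry(self, ws):
        cont = ws.create_container("spA")
        n0 = len(ws.history)
        snap = ws.create_snapshot(cont.id)
        add_genes(ws, snap.id, ["g1"])
        ws.extend_snapshot(snap.id)
        ws.clear_snapshot(snap.id)
        assert len(ws.history) == n0 + 4

    def test_replay_reproduces_scripted_snapshots(self, ws, figure1_dir):
        names = run_script(ws, figure1_dir / "figure1.replay")
        for sid in names.values():
            if sid not in ws.snapshots:  # container names map to container ids
                continue
            assert ws.replay(sid) == ws.snapshot(sid).content

    def test_replay_is_insensitive_to_later_parent_edits(self, ws):
        cont = ws.create_container("spA")
        parent = ws.create_snapshot(cont.id)
        add_genes(ws, parent.id, ["g1"])
        child = ws.create_snapshot(cont.id, parent_id=parent.id)
        add_genes(ws, parent.id, ["g2"])  # after the branch
        assert ws.replay(child.id).gene_ids == {"g1"}


class TestPersistence:
    def read_all(self, directory):
        return {
            p.relative_to(directory): p.read_text()
            for p in sorted(directory.rglob("*"))
            if p.is_file()
        }

    def test_save_load_save_round_trip(self, figure1, figure1_dir, tmp_path):
        ws = Workspace(figure1, actor="user1", clock=fixed_clock())
        run_script(ws, figure1_dir / "figure1.replay")
        d1, d2 = tmp_path / "w1", tmp_path / "w2"
        ws.save(d1)
        loaded = Workspace.load(d1, figure1)
        loaded.save(d2)
        assert self.read_all(d1) == self.read_all(d2)

    def test_loaded_workspace_equals_original(self, figure1, figure1_dir, tmp_path):
        ws = Workspace(figure1, clock=fixed_clock())
        names = run_script(ws, figure1_dir / "figure1.replay")
        ws.save(tmp_path / "w")
        loaded = Workspace.load(tmp_path / "w", figure1)
        assert set(loaded.snapshots) == set(ws.snapshots)
        for sid in ws.snapshots:
            assert loaded.snapshot(sid).content == ws.snapshot(sid).content
        assert [e.action for e in loaded.history] == [e.action for e in ws.history]
        # replay still works after a reload
        sid = names["b"]
        assert loaded.replay(sid) == loaded.snapshot(sid).content


class TestScriptScenario:
    """The scripted two-species workflow reproduces every expected
    membership (the same script the acceptance checks replay)."""

    @pytest.fixture()
    def played(self, figure1, figure1_dir):
        ws = Workspace(figure1, clock=fixed_clock())
        names = run_script(ws, figure1_dir / "figure1.replay")
        return ws, names

    def test_uploaded_genes(self, played):
        ws, names = played
        assert ws.snapshot(names["a"]).content.gene_ids == {"g1", "g2", "g3"}

    def test_branch_b_memberships(self, played):
        ws, names = played
        b = ws.snapshot(names["b"]).content
        assert b.gene_ids == {"g1", "g2", "g4"}
        assert b.transcript_ids == {"t1_1", "t1_2", "t2_1", "t4_1"}
        assert b.protein_ids == {"p1_1", "p4_1"}

    def test_extension_snapshot_c(self, played):
        ws, names = played
        c = ws.snapshot(names["c"]).content
        assert c.transcript_ids == {"t1_1", "t1_2", "t2_1", "t3_1"}
        assert c.protein_ids == {"p1_1", "p1_2", "p2_1", "p3_1"}

    def test_network_snapshot_d(self, played):
        ws, names = played
        d = ws.snapshot(names["d"]).content
        assert d.protein_ids == {"p1_1", "p1_2", "p2_1", "p3_1", "p4_1", "p5_1", "p5_2"}
        assert d.gene_ids == {"g1", "g2", "g3", "g4", "g5"}

    def test_translation_snapshots(self, played):
        ws, names = played
        assert ws.snapshot(names["e"]).content.gene_ids == {"g6", "g7"}
        assert ws.snapshot(names["f"]).content.gene_ids == {"g6", "g8", "g9"}
        assert ws.snapshot(names["g"]).content.gene_ids == {"g1"}
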