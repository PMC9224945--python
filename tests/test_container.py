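"""Container hierarchy: layout naming, editing, validation, pack/unpack."""

import random
import struct

import pytest

from genovault import container as cont
from genovault import fixtures as fx
from genovault import metadata as md
from genovault import protection as prot
from genovault.errors import BoxFormatError, ContainerError


class TestCreation:
    def test_empty_container_has_header_file_and_no_groups(self, tmp_path):
        c = cont.create_container(tmp_path / "box")
        assert c.dataset_groups == []
        assert (tmp_path / "box" / "flhd").exists()
        assert cont.validate(c) == []

    def test_create_at_occupied_path_refused(self, tmp_path):
        (tmp_path / "busy").mkdir()
        (tmp_path / "busy" / "junk").write_text("x")
        with pytest.raises(ContainerError):
            cont.create_container(tmp_path / "busy")

    def test_round_trip_of_fresh_container(self, tmp_path):
        c = cont.create_container(tmp_path / "box", brand="b")
        c2 = cont.unpack(cont.pack(c), tmp_path / "box2")
        assert c2 == c


class TestHierarchyEditing:
    def test_directory_naming_follows_the_layout_convention(self, tmp_path):
        c = cont.create_container(tmp_path / "box")
        cont.add_dataset_group(c, 0)
        cont.add_dataset(c, 0, 0)
        cont.add_access_unit(c, 0, 0, 0)
        cont.add_block(c, 0, 0, 0, b"x")
        root = tmp_path / "box"
        assert (root / "dg_0" / "dghd").exists()
        assert (root / "dg_0" / "dt_0" / "dthd").exists()
        assert (root / "dg_0" / "dt_0" / "au_0" / "auhd").exists()
        assert (root / "dg_0" / "dt_0" / "au_0" / "block_0").exists()

    def test_duplicate_ids_rejected_and_order_preserved(self, tmp_path):
        c = cont.create_container(tmp_path / "box")
        cont.add_dataset_group(c, 0)
        cont.add_dataset_group(c, 1)
        with pytest.raises(ContainerError):
            cont.add_dataset_group(c, 0)
        assert [dg.dg_id for dg in c.dataset_groups] == [0, 1]

    def test_missing_parent_rejected(self, tmp_path):
        c = cont.create_container(tmp_path / "box")
        with pytest.raises(ContainerError):
            cont.add_dataset(c, 99, 0)

    def test_empty_payload_block_accepted(self, tmp_path):
        c = cont.create_container(tmp_path / "box")
        cont.add_dataset_group(c, 0)
        cont.add_dataset(c, 0, 0)
        cont.add_access_unit(c, 0, 0, 0)
        b = cont.add_block(c, 0, 0, 0, b"")
        assert b.payload == b"" and b.block_id == 0

    def test_2x2x2_tree_enumerates_8_blocks(self, tmp_path):
        c = cont.create_container(tmp_path / "box")
        for dg in range(2):
            cont.add_dataset_group(c, dg)
            for dt in range(2):
                cont.add_dataset(c, dg, dt)
                cont.add_access_unit(c, dg, dt, 0)
                for _ in range(2):
                    cont.add_block(c, dg, dt, 0, b"p")
        blocks = [
            b
            for g in c.dataset_groups
            for d in g.datasets
            for a in d.access_units
            for b in a.blocks
        ]
        assert len(blocks) == 8

    def test_delete_removes_subtree_recursively(self, tmp_path):
        c = cont.create_container(tmp_path / "box")
        cont.add_dataset_group(c, 0)
        cont.add_dataset(c, 0, 0)
        cont.add_dataset(c, 0, 1)
        cont.delete_element(c, "dg_0/dt_0")
        assert [d.dt_id for d in c.group(0).datasets] == [1]
        assert not (tmp_path / "box" / "dg_0" / "dt_0").exists()
        cont.delete_element(c, "dg_0")
        assert c.dataset_groups == []
        assert not (tmp_path / "box" / "dg_0").exists()
        with pytest.raises(ContainerError):
            cont.delete_element(c, "dg_0")

    def test_edit_header_persists_through_pack_unpack(self, tmp_path):
        c = cont.create_container(tmp_path / "box")
        cont.add_dataset_group(c, 0)
        cont.edit_element(c, "dg_0", note="edited")
        cont.edit_element(c, "", brand="newbrand")
        c2 = cont.unpack(cont.pack(c), tmp_path / "box2")
        assert c2.group(0).header["note"] == "edited"
        assert c2.file_header.brand == "newbrand"


class TestMetadataAndProtectionFiles:
    def test_metadata_file_names_per_level(self, small_container):
        root = small_container.root_path
        assert (root / "dg_0" / "dgmd").exists()
        assert (root / "dg_0" / "dt_0" / "dtmd").exists()

    def test_attach_twice_keeps_latest(self, tmp_path):
        c = cont.create_container(tmp_path / "box")
        cont.add_dataset_group(c, 0)
        cont.attach_metadata(c, "dg_0", md.MetadataRecord(title="one"))
        cont.attach_metadata(c, "dg_0", md.MetadataRecord(title="two"))
        reloaded = cont.load_container(tmp_path / "box")
        assert reloaded.group(0).metadata.title == "two"

    def test_attach_then_read_back_equal(self, tmp_path):
        c = cont.create_container(tmp_path / "box")
        cont.add_dataset_group(c, 0)
        record = md.MetadataRecord(title="t", extensions={"IsTumor": "no"})
        cont.attach_metadata(c, "dg_0", record)
        assert cont.load_container(tmp_path / "box").group(0).metadata == record

    def test_protection_file_names_including_access_unit_level(self, tmp_path):
        c = cont.create_container(tmp_path / "box")
        cont.add_dataset_group(c, 0)
        cont.add_dataset(c, 0, 0)
        cont.add_access_unit(c, 0, 0, 0)
        box = prot.ProtectionBox(policy=fx.policy_from_template("all-permit"))
        cont.attach_protection(c, "dg_0", box)
        cont.attach_protection(c, "dg_0/dt_0", box)
        cont.attach_protection(c, "dg_0/dt_0/au_0", box)
        root = tmp_path / "box"
        assert (root / "dg_0" / "dgpr").exists()
        assert (root / "dg_0" / "dt_0" / "dtpr").exists()
        assert (root / "dg_0" / "dt_0" / "au_0" / "aupr").exists()
        reloaded = cont.load_container(root)
        assert reloaded.group(0).dataset(0).access_unit(0).protection == box


class TestValidation:
    def test_fixture_validates_clean(self, small_container):
        assert cont.validate(small_container) == []

    def test_duplicate_dataset_id_detected(self, small_container):
        small_container.group(0).datasets[1].dt_id = 0
        violations = cont.validate(small_container)
        assert len(violations) == 1 and "duplicate dataset ids" in violations[0]

    def test_index_referencing_missing_au_detected(self, small_container):
        small_container.group(0).dataset(0).index = {99: 0}
        violations = cont.validate(small_container)
        assert any("missing access units" in v for v in violations)

    def test_pack_refuses_invalid_tree(self, small_container):
        small_container.group(0).datasets[1].dt_id = 0
        with pytest.raises(ContainerError):
            cont.pack(small_container)


class TestPackUnpack:
    def test_pack_is_deterministic(self, small_container):
        assert cont.pack(small_container) == cont.pack(small_container)

    def test_unpack_rejects_bad_magic(self, tmp_path):
        with pytest.raises(BoxFormatError, match="magic"):
            cont.unpack(b"NOTMAGIC" + b"\x00" * 32, tmp_path / "out")

    def test_unpack_rejects_truncation(self, small_container, tmp_path):
        data = cont.pack(small_container)
        with pytest.raises(BoxFormatError, match="truncated"):
            cont.unpack(data[:-4], tmp_path / "out")

    def test_unpack_rejects_unknown_top_level_box(self, tmp_path):
        c = cont.create_container(tmp_path / "box")
        data = cont.pack(c) + b"zzzz" + struct.pack(">Q", 0)
        with pytest.raises(BoxFormatError, match="unknown top-level box"):
            cont.unpack(data, tmp_path / "out")

    def test_descriptor_stream_box_rejected(self, tmp_path):
        c = cont.create_container(tmp_path / "box")
        data = cont.pack(c) + b"dscn" + struct.pack(">Q", 0)
        with pytest.raises(BoxFormatError, match="descriptor-stream"):
            cont.unpack(data, tmp_path / "out")

    def test_round_trip_identity_on_100_seeded_random_trees(self, tmp_path):
        """pack->unpack reproduces the tree and the bytes, 100 random trees."""
        for seed in range(100):
            c = fx.generate_random_container(seed, tmp_path / f"t{seed}")
            data = cont.pack(c)
            c2 = cont.unpack(data, tmp_path / f"u{seed}")
            assert c2 == c, f"tree mismatch at seed {seed}"
            assert cont.pack(c2) == data, f"byte mismatch at seed {seed}"

    def test_random_corruption_is_detected_or_yields_valid_tree(self, tmp_path):
        """Fuzz: single byte flips either raise a specific error or still
        parse into a validating tree (flips inside opaque payloads)."""
        c = fx.generate_random_container(3, tmp_path / "orig")
        data = bytearray(cont.pack(c))
        rng = random.Random(99)
        for trial in range(60):
            pos = rng.randrange(len(data))
            mutated = bytearray(data)
            mutated[pos] ^= 1 << rng.randrange(8)
            dest = tmp_path / f"fz{trial}"
            try:
                parsed = cont.unpack(bytes(mutated), dest)
            except Exception:
                continue  # detected: format, json, xml or container error
            assert cont.validate(parsed) == []
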