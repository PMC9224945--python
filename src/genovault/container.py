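"""Hierarchical protected genomic container (access-unit organisation).

The container follows the box hierarchy of hierarchical genomic file
formats: a File holds Dataset Groups, which hold Datasets, which hold
Access Units, which hold Blocks of opaque coded payload.  Metadata and
protection records can hang off the group, dataset and (protection only)
access-unit levels.

Two interchangeable representations are supported:

* a *file-system layout*, the working form: every box is a directory
  (``dg_X``, ``dt_X``, ``au_X``) with small files for headers (``flhd``,
  ``dghd``, ``dthd``, ``auhd``), metadata (``dgmd``, ``dtmd``), protection
  (``dgpr``, ``dtpr``, ``aupr``), the dataset label (``labl``), access-unit
  info (``auin``), the optional dataset index (``dtix``) and the block
  payloads (``block_X``);
* a *packed binary stream* for exchange: an 8-byte magic tag followed by
  nested boxes, each ``4-byte ASCII type + 8-byte big-endian length +
  payload``, with container boxes (``dgcn``, ``dtcn``, ``aucn``) nesting
  their children ordered by ascending id so packing is deterministic.

Only the access-unit-container organisation is supported; a packed stream
advertising the descriptor-stream organisation is rejected at parse time.
"""

from __future__ import annotations

import io
import json
import shutil
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Union

from genovault import metadata as md
from genovault import protection as prot
from genovault.errors import BoxFormatError, ContainerError

__all__ = [
    "MAGIC",
    "FileHeader",
    "Block",
    "AccessUnit",
    "Dataset",
    "DatasetGroup",
    "GenomicContainer",
    "create_container",
    "load_container",
    "add_dataset_group",
    "add_dataset",
    "add_access_unit",
    "add_block",
    "attach_metadata",
    "attach_protection",
    "edit_element",
    "delete_element",
    "pack",
    "unpack",
    "validate",
]

MAGIC = b"GIPAMS01"
VERSION = 1

_CONTAINER_BOXES = {"dgcn", "dtcn", "aucn"}
_LEAF_BOXES = {
    "flhd", "flmd", "dghd", "dgmd", "dgpr",
    "dthd", "labl", "dtmd", "dtpr", "dtix",
    "auhd", "auin", "aupr", "blck",
}


@dataclass
class FileHeader:
    magic: bytes = MAGIC
    version: int = VERSION
    brand: str = ""
    owner: str = ""  # subject id allowed to mutate the file; empty = unowned

    def to_bytes(self) -> bytes:
        return json.dumps(
            {
                "magic": self.magic.decode("ascii"),
                "version": self.version,
                "brand": self.brand,
                "owner": self.owner,
            },
            sort_keys=True,
        ).encode()

    @classmethod
    def from_bytes(cls, data: bytes) -> "FileHeader":
        obj = json.loads(data)
        return cls(
            magic=obj["magic"].encode("ascii"),
            version=obj["version"],
            brand=obj.get("brand", ""),
            owner=obj.get("owner", ""),
        )


def _header_bytes(node_id: int, fields: dict) -> bytes:
    return json.dumps({"id": node_id, **fields}, sort_keys=True).encode()


def _header_fields(data: bytes) -> tuple[int, dict]:
    obj = json.loads(data)
    node_id = obj.pop("id")
    return node_id, obj


@dataclass
class Block:
    block_id: int
    payload: bytes = b""
    encrypted: bool = False


@dataclass
class AccessUnit:
    au_id: int
    header: dict = field(default_factory=dict)
    info: Optional[bytes] = None  # auin
    protection: Optional["prot.ProtectionBox"] = None
    blocks: list[Block] = field(default_factory=list)

    def block(self, block_id: int) -> Block:
        for b in self.blocks:
            if b.block_id == block_id:
                return b
        raise ContainerError(f"no block {block_id} in access unit {self.au_id}")


@dataclass
class Dataset:
    dt_id: int
    header: dict = field(default_factory=dict)
    metadata: Optional[md.MetadataRecord] = None
    metadata_enc: Optional[bytes] = None  # ciphertext when dtmd is encrypted
    protection: Optional["prot.ProtectionBox"] = None
    label: Optional[str] = None
    index: Optional[dict[int, int]] = None  # au_id -> byte offset
    access_units: list[AccessUnit] = field(default_factory=list)

    def access_unit(self, au_id: int) -> AccessUnit:
        for au in self.access_units:
            if au.au_id == au_id:
                return au
        raise ContainerError(f"no access unit {au_id} in dataset {self.dt_id}")


@dataclass
class DatasetGroup:
    dg_id: int
    header: dict = field(default_factory=dict)
    metadata: Optional[md.MetadataRecord] = None
    metadata_enc: Optional[bytes] = None  # ciphertext when dgmd is encrypted
    protection: Optional["prot.ProtectionBox"] = None
    datasets: list[Dataset] = field(default_factory=list)

    def dataset(self, dt_id: int) -> Dataset:
        for dt in self.datasets:
            if dt.dt_id == dt_id:
                return dt
        raise ContainerError(f"no dataset {dt_id} in group {self.dg_id}")


@dataclass
class GenomicContainer:
    root_path: Path = field(compare=False)
    file_header: FileHeader = field(default_factory=FileHeader)
    file_metadata: Optional[md.MetadataRecord] = None
    dataset_groups: list[DatasetGroup] = field(default_factory=list)

    def group(self, dg_id: int) -> DatasetGroup:
        for dg in self.dataset_groups:
            if dg.dg_id == dg_id:
                return dg
        raise ContainerError(f"no dataset group {dg_id}")

    # -- path helpers -------------------------------------------------------

    def group_dir(self, dg_id: int) -> Path:
        return self.root_path / f"dg_{dg_id}"

    def dataset_dir(self, dg_id: int, dt_id: int) -> Path:
        return self.group_dir(dg_id) / f"dt_{dt_id}"

    def au_dir(self, dg_id: int, dt_id: int, au_id: int) -> Path:
        return self.dataset_dir(dg_id, dt_id) / f"au_{au_id}"

    def block_path(self, dg_id: int, dt_id: int, au_id: int, block_id: int) -> Path:
        return self.au_dir(dg_id, dt_id, au_id) / f"block_{block_id}"


PathSpec = Union[str, tuple]


def _parse_path(spec: PathSpec) -> tuple[int, ...]:
    """Normalise ``"dg_0/dt_1/au_2"`` (or an id tuple) to a tuple of ids."""
    if isinstance(spec, tuple):
        return tuple(int(x) for x in spec)
    parts = [p for p in str(spec).split("/") if p]
    expected = ("dg_", "dt_", "au_", "block_")
    ids = []
    for i, part in enumerate(parts):
        if i >= len(expected) or not part.startswith(expected[i]):
            raise ContainerError(f"malformed element path: {spec!r}")
        try:
            ids.append(int(part.removeprefix(expected[i])))
        except ValueError:
            raise ContainerError(f"malformed element path: {spec!r}") from None
    return tuple(ids)


# ---------------------------------------------------------------------------
# Creation and write-through editing
# ---------------------------------------------------------------------------


def create_container(
    root_path: Union[str, Path], brand: str = "", owner: str = ""
) -> GenomicContainer:
    """Create an empty container at ``root_path`` (must be empty or absent)."""
    root = Path(root_path)
    if root.exists():
        if not root.is_dir() or any(root.iterdir()):
            raise ContainerError(f"path exists and is not empty: {root}")
    else:
        root.mkdir(parents=True)
    c = GenomicContainer(root, FileHeader(brand=brand, owner=owner))
    (root / "flhd").write_bytes(c.file_header.to_bytes())
    return c


def add_dataset_group(c: GenomicContainer, dg_id: int, **header) -> DatasetGroup:
    if dg_id < 0:
        raise ContainerError("identifiers must be non-negative")
    if any(dg.dg_id == dg_id for dg in c.dataset_groups):
        raise ContainerError(f"duplicate dataset group id {dg_id}")
    dg = DatasetGroup(dg_id, dict(header))
    d = c.group_dir(dg_id)
    d.mkdir()
    (d / "dghd").write_bytes(_header_bytes(dg_id, dg.header))
    c.dataset_groups.append(dg)
    return dg


def add_dataset(c: GenomicContainer, dg_id: int, dt_id: int, **header) -> Dataset:
    if dt_id < 0:
        raise ContainerError("identifiers must be non-negative")
    dg = c.group(dg_id)
    if any(dt.dt_id == dt_id for dt in dg.datasets):
        raise ContainerError(f"duplicate dataset id {dt_id} in group {dg_id}")
    dt = Dataset(dt_id, dict(header))
    d = c.dataset_dir(dg_id, dt_id)
    d.mkdir()
    (d / "dthd").write_bytes(_header_bytes(dt_id, dt.header))
    dg.datasets.append(dt)
    return dt


def add_access_unit(
    c: GenomicContainer, dg_id: int, dt_id: int, au_id: int, **header
) -> AccessUnit:
    if au_id < 0:
        raise ContainerError("identifiers must be non-negative")
    dt = c.group(dg_id).dataset(dt_id)
    if any(au.au_id == au_id for au in dt.access_units):
        raise ContainerError(f"duplicate access unit id {au_id}")
    au = AccessUnit(au_id, dict(header))
    d = c.au_dir(dg_id, dt_id, au_id)
    d.mkdir()
    (d / "auhd").write_bytes(_header_bytes(au_id, au.header))
    dt.access_units.append(au)
    return au


def add_block(
    c: GenomicContainer, dg_id: int, dt_id: int, au_id: int, payload: bytes
) -> Block:
    """Append a block; block ids are assigned contiguously from 0."""
    au = c.group(dg_id).dataset(dt_id).access_unit(au_id)
    block = Block(len(au.blocks), bytes(payload))
    c.block_path(dg_id, dt_id, au_id, block.block_id).write_bytes(block.payload)
    au.blocks.append(block)
    return block


def attach_metadata(
    c: GenomicContainer, path: PathSpec, record: md.MetadataRecord
):
    """Write a ``dgmd``/``dtmd`` (or file-level ``flmd``) metadata payload.

    Replaces any metadata previously attached at the node.
    """
    ids = _parse_path(path)
    data = md.to_xml(record)
    if len(ids) == 0:
        c.file_metadata = record
        (c.root_path / "flmd").write_bytes(data)
    elif len(ids) == 1:
        dg = c.group(ids[0])
        dg.metadata = record
        (c.group_dir(ids[0]) / "dgmd").write_bytes(data)
    elif len(ids) == 2:
        dt = c.group(ids[0]).dataset(ids[1])
        dt.metadata = record
        (c.dataset_dir(*ids) / "dtmd").write_bytes(data)
    else:
        raise ContainerError("metadata attaches at file, group or dataset level")
    return record


def attach_protection(c: GenomicContainer, path: PathSpec, box: "prot.ProtectionBox"):
    """Write a ``dgpr``/``dtpr``/``aupr`` protection payload at the node."""
    ids = _parse_path(path)
    data = prot.protection_to_xml(box)
    if len(ids) == 1:
        c.group(ids[0]).protection = box
        (c.group_dir(ids[0]) / "dgpr").write_bytes(data)
    elif len(ids) == 2:
        c.group(ids[0]).dataset(ids[1]).protection = box
        (c.dataset_dir(*ids) / "dtpr").write_bytes(data)
    elif len(ids) == 3:
        c.group(ids[0]).dataset(ids[1]).access_unit(ids[2]).protection = box
        (c.au_dir(*ids) / "aupr").write_bytes(data)
    else:
        raise ContainerError("protection attaches at group, dataset or AU level")
    return box


def rewrite_protection(c: GenomicContainer, path: PathSpec):
    """Re-serialise the protection box already attached at ``path``."""
    ids = _parse_path(path)
    node = _node_at(c, ids)
    if node.protection is None:
        raise ContainerError(f"no protection box at {path!r}")
    attach_protection(c, path, node.protection)


def _node_at(c: GenomicContainer, ids: tuple[int, ...]):
    if len(ids) == 0:
        return c
    node = c.group(ids[0])
    if len(ids) >= 2:
        node = node.dataset(ids[1])
    if len(ids) >= 3:
        node = node.access_unit(ids[2])
    if len(ids) == 4:
        node = node.block(ids[3])
    return node


def edit_element(c: GenomicContainer, path: PathSpec, **fields) -> GenomicContainer:
    """Replace header fields (or file header attributes) at an element."""
    ids = _parse_path(path)
    if len(ids) == 0:
        for key, value in fields.items():
            if not hasattr(c.file_header, key) or key == "magic":
                raise ContainerError(f"cannot edit file-header field {key!r}")
            setattr(c.file_header, key, value)
        (c.root_path / "flhd").write_bytes(c.file_header.to_bytes())
        return c
    node = _node_at(c, ids)
    if isinstance(node, Block):
        raise ContainerError("blocks have no editable header")
    node.header.update(fields)
    hd_name = {1: "dghd", 2: "dthd", 3: "auhd"}[len(ids)]
    hd_dir = {1: c.group_dir, 2: c.dataset_dir, 3: c.au_dir}[len(ids)](*ids)
    (hd_dir / hd_name).write_bytes(_header_bytes(ids[-1], node.header))
    return c


def delete_element(c: GenomicContainer, path: PathSpec) -> GenomicContainer:
    """Remove an element and its whole subtree (directories included)."""
    ids = _parse_path(path)
    if len(ids) == 0:
        raise ContainerError("cannot delete the container root")
    _node_at(c, ids)  # existence check
    if len(ids) == 1:
        shutil.rmtree(c.group_dir(ids[0]))
        c.dataset_groups = [g for g in c.dataset_groups if g.dg_id != ids[0]]
    elif len(ids) == 2:
        shutil.rmtree(c.dataset_dir(*ids))
        dg = c.group(ids[0])
        dg.datasets = [d for d in dg.datasets if d.dt_id != ids[1]]
    elif len(ids) == 3:
        shutil.rmtree(c.au_dir(*ids))
        dt = c.group(ids[0]).dataset(ids[1])
        dt.access_units = [a for a in dt.access_units if a.au_id != ids[2]]
    else:
        au = c.group(ids[0]).dataset(ids[1]).access_unit(ids[2])
        if ids[3] != len(au.blocks) - 1:
            raise ContainerError("only the last block may be deleted (ids are contiguous)")
        c.block_path(*ids).unlink()
        au.blocks.pop()
    return c


# ---------------------------------------------------------------------------
# Disk loading
# ---------------------------------------------------------------------------


def _sorted_subdirs(path: Path, prefix: str) -> list[tuple[int, Path]]:
    out = []
    for child in path.iterdir():
        if child.is_dir() and child.name.startswith(prefix):
            try:
                out.append((int(child.name.removeprefix(prefix)), child))
            except ValueError:
                raise ContainerError(f"unexpected directory {child}") from None
    return sorted(out)


def _read_optional(path: Path) -> Optional[bytes]:
    return path.read_bytes() if path.exists() else None


def load_container(root_path: Union[str, Path]) -> GenomicContainer:
    """Reconstruct the in-memory tree from a file-system layout."""
    root = Path(root_path)
    flhd = root / "flhd"
    if not flhd.exists():
        raise ContainerError(f"not a container (missing flhd): {root}")
    c = GenomicContainer(root, FileHeader.from_bytes(flhd.read_bytes()))
    flmd = _read_optional(root / "flmd")
    if flmd is not None:
        c.file_metadata = md.from_xml(flmd)
    for dg_id, dg_dir in _sorted_subdirs(root, "dg_"):
        hdr_id, fields = _header_fields((dg_dir / "dghd").read_bytes())
        dg = DatasetGroup(dg_id, fields)
        if hdr_id != dg_id:
            raise ContainerError(f"header id {hdr_id} != directory id {dg_id}")
        dgpr = _read_optional(dg_dir / "dgpr")
        if dgpr is not None:
            dg.protection = prot.protection_from_xml(dgpr)
        dgmd = _read_optional(dg_dir / "dgmd")
        if dgmd is not None:
            if _metadata_encrypted(dg.protection, f"dg_{dg_id}/dgmd"):
                dg.metadata_enc = dgmd
            else:
                dg.metadata = md.from_xml(dgmd)
        for dt_id, dt_dir in _sorted_subdirs(dg_dir, "dt_"):
            hdr_id, fields = _header_fields((dt_dir / "dthd").read_bytes())
            dt = Dataset(dt_id, fields)
            if hdr_id != dt_id:
                raise ContainerError(f"header id {hdr_id} != directory id {dt_id}")
            labl = _read_optional(dt_dir / "labl")
            if labl is not None:
                dt.label = labl.decode("utf-8")
            dtpr = _read_optional(dt_dir / "dtpr")
            if dtpr is not None:
                dt.protection = prot.protection_from_xml(dtpr)
            dtmd = _read_optional(dt_dir / "dtmd")
            if dtmd is not None:
                if _metadata_encrypted(
                    dt.protection, f"dg_{dg_id}/dt_{dt_id}/dtmd"
                ):
                    dt.metadata_enc = dtmd
                else:
                    dt.metadata = md.from_xml(dtmd)
            dtix = _read_optional(dt_dir / "dtix")
            if dtix is not None:
                dt.index = {int(k): v for k, v in json.loads(dtix)["au_offsets"].items()}
            for au_id, au_dir in _sorted_subdirs(dt_dir, "au_"):
                hdr_id, fields = _header_fields((au_dir / "auhd").read_bytes())
                au = AccessUnit(au_id, fields)
                if hdr_id != au_id:
                    raise ContainerError(f"header id {hdr_id} != directory id {au_id}")
                au.info = _read_optional(au_dir / "auin")
                aupr = _read_optional(au_dir / "aupr")
                if aupr is not None:
                    au.protection = prot.protection_from_xml(aupr)
                blocks = sorted(
                    (int(p.name.removeprefix("block_")), p)
                    for p in au_dir.iterdir()
                    if p.is_file() and p.name.startswith("block_")
                )
                for block_id, bp in blocks:
                    au.blocks.append(Block(block_id, bp.read_bytes()))
                _mark_encrypted(au)
                dt.access_units.append(au)
            dg.datasets.append(dt)
        c.dataset_groups.append(dg)
    return c


def _metadata_encrypted(box, target: str) -> bool:
    if box is None:
        return False
    return any(e.target == target for e in box.encryption_entries)


def _mark_encrypted(au: AccessUnit) -> None:
    # The encrypted flag is derived from the AU protection box so it cannot
    # drift from the recorded encryption entries.
    targets = set()
    if au.protection is not None:
        targets = {e.target.rsplit("/", 1)[-1] for e in au.protection.encryption_entries}
    for b in au.blocks:
        b.encrypted = f"block_{b.block_id}" in targets


# ---------------------------------------------------------------------------
# Packed binary stream
# ---------------------------------------------------------------------------


def _box(box_type: str, payload: bytes) -> bytes:
    return box_type.encode("ascii") + struct.pack(">Q", len(payload)) + payload


def _iter_boxes(data: bytes, offset: int = 0, end: Optional[int] = None):
    end = len(data) if end is None else end
    while offset < end:
        if offset + 12 > end:
            raise BoxFormatError("truncated box header")
        box_type = data[offset : offset + 4].decode("ascii", errors="replace")
        (length,) = struct.unpack(">Q", data[offset + 4 : offset + 12])
        payload_start = offset + 12
        if payload_start + length > end:
            raise BoxFormatError(f"truncated {box_type} box payload")
        yield box_type, payload_start, payload_start + length
        offset = payload_start + length


def pack(c: GenomicContainer) -> bytes:
    """Serialise the container to a single deterministic byte stream."""
    violations = validate(c)
    if violations:
        raise ContainerError("container does not validate: " + "; ".join(violations))
    out = io.BytesIO()
    out.write(MAGIC)
    out.write(_box("flhd", c.file_header.to_bytes()))
    if c.file_metadata is not None:
        out.write(_box("flmd", md.to_xml(c.file_metadata)))
    for dg in sorted(c.dataset_groups, key=lambda g: g.dg_id):
        body = io.BytesIO()
        body.write(_box("dghd", _header_bytes(dg.dg_id, dg.header)))
        if dg.metadata_enc is not None:
            body.write(_box("dgmd", dg.metadata_enc))
        elif dg.metadata is not None:
            body.write(_box("dgmd", md.to_xml(dg.metadata)))
        if dg.protection is not None:
            body.write(_box("dgpr", prot.protection_to_xml(dg.protection)))
        for dt in sorted(dg.datasets, key=lambda d: d.dt_id):
            dt_body = io.BytesIO()
            dt_body.write(_box("dthd", _header_bytes(dt.dt_id, dt.header)))
            if dt.label is not None:
                dt_body.write(_box("labl", dt.label.encode("utf-8")))
            if dt.metadata_enc is not None:
                dt_body.write(_box("dtmd", dt.metadata_enc))
            elif dt.metadata is not None:
                dt_body.write(_box("dtmd", md.to_xml(dt.metadata)))
            if dt.protection is not None:
                dt_body.write(_box("dtpr", prot.protection_to_xml(dt.protection)))
            if dt.index is not None:
                payload = json.dumps(
                    {"au_offsets": {str(k): v for k, v in sorted(dt.index.items())}},
                    sort_keys=True,
                ).encode()
                dt_body.write(_box("dtix", payload))
            for au in sorted(dt.access_units, key=lambda a: a.au_id):
                au_body = io.BytesIO()
                au_body.write(_box("auhd", _header_bytes(au.au_id, au.header)))
                if au.info is not None:
                    au_body.write(_box("auin", au.info))
                if au.protection is not None:
                    au_body.write(_box("aupr", prot.protection_to_xml(au.protection)))
                for block in au.blocks:  # contiguous ids, already ordered
                    au_body.write(_box("blck", block.payload))
                dt_body.write(_box("aucn", au_body.getvalue()))
            body.write(_box("dtcn", dt_body.getvalue()))
        out.write(_box("dgcn", body.getvalue()))
    return out.getvalue()


def unpack(data: bytes, dest: Union[str, Path]) -> GenomicContainer:
    """Rebuild the file-system layout at ``dest`` from a packed stream."""
    if data[: len(MAGIC)] != MAGIC:
        raise BoxFormatError(
            f"bad magic: expected {MAGIC!r}, got {bytes(data[:len(MAGIC)])!r}"
        )
    root = Path(dest)
    if root.exists() and any(root.iterdir()):
        raise ContainerError(f"destination not empty: {root}")
    root.mkdir(parents=True, exist_ok=True)

    seen_flhd = False
    for box_type, start, end in _iter_boxes(data, len(MAGIC)):
        payload = data[start:end]
        if box_type == "flhd":
            FileHeader.from_bytes(payload)  # validates JSON
            (root / "flhd").write_bytes(payload)
            seen_flhd = True
        elif box_type == "flmd":
            (root / "flmd").write_bytes(payload)
        elif box_type == "dgcn":
            _unpack_group(data, start, end, root)
        elif box_type == "dscn":
            raise BoxFormatError(
                "descriptor-stream organisation (dscn) is not supported; "
                "only access-unit containers can be unpacked"
            )
        else:
            raise BoxFormatError(f"unknown top-level box type {box_type!r}")
    if not seen_flhd:
        raise BoxFormatError("packed stream has no flhd box")
    return load_container(root)


def _unpack_leaf_dir(data, start, end, out_dir: Path, id_prefix: str, hd_name: str,
                     allowed: dict, container: Optional[tuple] = None) -> None:
    """Write one box directory from the children of a container box."""
    node_id = None
    blocks = 0
    for box_type, s, e in _iter_boxes(data, start, end):
        payload = data[s:e]
        if box_type == hd_name:
            node_id, _ = _header_fields(payload)
            out_dir.mkdir(parents=True, exist_ok=True)
            (out_dir / hd_name).write_bytes(payload)
        elif node_id is None:
            raise BoxFormatError(f"{hd_name} must be the first box in its container")
        elif box_type in allowed:
            (out_dir / allowed[box_type]).write_bytes(payload)
        elif box_type == "blck":
            (out_dir / f"block_{blocks}").write_bytes(payload)
            blocks += 1
        elif container is not None and box_type == container[0]:
            container[1](data, s, e, out_dir)
        else:
            raise BoxFormatError(f"unexpected box {box_type!r} in {hd_name} container")
    if node_id is None:
        raise BoxFormatError(f"container without {hd_name} header box")


def _unpack_group(data, start, end, root: Path) -> None:
    # peek at dghd to learn the directory name
    node_id = _peek_id(data, start, end, "dghd")
    _unpack_leaf_dir(
        data, start, end, root / f"dg_{node_id}", "dg_", "dghd",
        {"dgmd": "dgmd", "dgpr": "dgpr"}, ("dtcn", _unpack_dataset),
    )


def _unpack_dataset(data, start, end, parent: Path) -> None:
    node_id = _peek_id(data, start, end, "dthd")
    _unpack_leaf_dir(
        data, start, end, parent / f"dt_{node_id}", "dt_", "dthd",
        {"labl": "labl", "dtmd": "dtmd", "dtpr": "dtpr", "dtix": "dtix"},
        ("aucn", _unpack_au),
    )


def _unpack_au(data, start, end, parent: Path) -> None:
    node_id = _peek_id(data, start, end, "auhd")
    _unpack_leaf_dir(
        data, start, end, parent / f"au_{node_id}", "au_", "auhd",
        {"auin": "auin", "aupr": "aupr"},
    )


def _peek_id(data, start, end, hd_name: str) -> int:
    for box_type, s, e in _iter_boxes(data, start, end):
        if box_type != hd_name:
            raise BoxFormatError(f"{hd_name} must be the first box in its container")
        node_id, _ = _header_fields(data[s:e])
        return node_id
    raise BoxFormatError(f"empty container box (missing {hd_name})")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate(c: GenomicContainer) -> list[str]:
    """Return all invariant violations (empty list == valid)."""
    out: list[str] = []
    if c.file_header.magic != MAGIC:
        out.append(f"file header magic {c.file_header.magic!r} != {MAGIC!r}")
    ids = [dg.dg_id for dg in c.dataset_groups]
    if len(ids) != len(set(ids)):
        out.append("duplicate dataset group ids")
    for dg in c.dataset_groups:
        dt_ids = [dt.dt_id for dt in dg.datasets]
        if len(dt_ids) != len(set(dt_ids)):
            out.append(f"duplicate dataset ids in group {dg.dg_id}")
        for dt in dg.datasets:
            au_ids = [au.au_id for au in dt.access_units]
            if len(au_ids) != len(set(au_ids)):
                out.append(
                    f"duplicate access unit ids in dg_{dg.dg_id}/dt_{dt.dt_id}"
                )
            if dt.index is not None:
                missing = set(dt.index) - set(au_ids)
                if missing:
                    out.append(
                        f"index in dg_{dg.dg_id}/dt_{dt.dt_id} references "
                        f"missing access units {sorted(missing)}"
                    )
            for au in dt.access_units:
                got = [b.block_id for b in au.blocks]
                if got != list(range(len(got))):
                    out.append(
                        f"non-contiguous block ids {got} in "
                        f"dg_{dg.dg_id}/dt_{dt.dt_id}/au_{au.au_id}"
                    )
                enc_targets = set()
                if au.protection is not None:
                    enc_targets = {
                        e.target.rsplit("/", 1)[-1]
                        for e in au.protection.encryption_entries
                    }
                for b in au.blocks:
                    if b.encrypted != (f"block_{b.block_id}" in enc_targets):
                        out.append(
                            f"encrypted flag inconsistent with protection entries "
                            f"for dg_{dg.dg_id}/dt_{dt.dt_id}/au_{au.au_id}/"
                            f"block_{b.block_id}"
                        )
    return out
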