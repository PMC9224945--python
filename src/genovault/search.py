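"""Metadata search with per-result authorization filtering.

An in-memory index over every populated metadata field (core fields and
extensions) at the dataset-group and dataset levels.  Queries match a
case-insensitive substring against field values, and every candidate hit
is passed through the hierarchical metadata-read authorization before it
is returned — a hit the requesting subject may not see is silently
dropped, so the result list itself leaks nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

from genovault import hierarchy_authz as ha
from genovault import policy as pol
from genovault.audit import AuditLog
from genovault.container import GenomicContainer
from genovault.metadata import MetadataRecord, _XML_TAGS

__all__ = ["IndexEntry", "MetadataIndex", "SearchHit", "index_container", "query"]


@dataclass(frozen=True)
class IndexEntry:
    path: tuple[int, ...]  # (dg_id,) or (dg_id, dt_id)
    level: str  # "dg" | "dt"
    field: str
    value: str


@dataclass
class MetadataIndex:
    entries: list[IndexEntry] = dc_field(default_factory=list)


@dataclass(frozen=True)
class SearchHit:
    path: tuple[int, ...]
    level: str
    field: str
    value: str
    authorized: bool = True


def _record_fields(record: MetadataRecord):
    for attr in _XML_TAGS:
        value = getattr(record, attr)
        if value:
            yield attr, value
    yield from record.extensions.items()


def index_container(c: GenomicContainer) -> MetadataIndex:
    """One entry per populated metadata field, rebuilt deterministically."""
    index = MetadataIndex()
    for dg in sorted(c.dataset_groups, key=lambda g: g.dg_id):
        if dg.metadata is not None:
            for name, value in _record_fields(dg.metadata):
                index.entries.append(IndexEntry((dg.dg_id,), "dg", name, value))
        for dt in sorted(dg.datasets, key=lambda d: d.dt_id):
            if dt.metadata is not None:
                for name, value in _record_fields(dt.metadata):
                    index.entries.append(
                        IndexEntry((dg.dg_id, dt.dt_id), "dt", name, value)
                    )
    return index


def query(
    c: GenomicContainer,
    index: MetadataIndex,
    field: str,
    pattern: str,
    request: pol.AuthzRequest,
    audit: Optional[AuditLog] = None,
) -> list[SearchHit]:
    """Case-insensitive substring search, filtered by metadata-read rules.

    An empty pattern matches every entry of the field; hits whose level the
    request is not authorized to read are dropped.
    """
    needle = pattern.lower()
    hits = []
    for entry in index.entries:
        if entry.field != field or needle not in entry.value.lower():
            continue
        result = ha.authorize_operation(
            c, "metadata-read", entry.path, request, audit=audit
        )
        if result.outcome is pol.Outcome.PERMIT:
            hits.append(
                SearchHit(entry.path, entry.level, entry.field, entry.value)
            )
    return hits
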