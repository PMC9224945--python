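"""Study/sample metadata records with EGA and NCBI field mapping.

The container hierarchy mirrors how public archives organise studies: a
dataset group plays the role of an EGA Study / NCBI BioProject and a dataset
the role of an EGA dataset / NCBI BioSample.  A :class:`MetadataRecord`
carries the seven core fields of that model plus free-form extension
attributes, and serialises to the XML payload stored in the ``dgmd``/``dtmd``
container files.

Mapping rules:

* EGA fields map one-to-one onto the core fields.
* NCBI has no Abstract, so :func:`map_from_ncbi` always leaves it empty, and
  the NCBI submission type is copied verbatim (no vocabulary translation).
* Extra archive attributes (study design, body site, analyte type, tumor
  status, ...) become named extensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from lxml import etree

from genovault.errors import MetadataXmlError

__all__ = [
    "MetadataRecord",
    "map_from_ega",
    "map_from_ncbi",
    "add_extension",
    "to_xml",
    "from_xml",
    "EGA_FIELD_MAP",
    "NCBI_FIELD_MAP",
    "NCBI_EXTENSION_MAP",
]

# core field (record attribute, XML tag) -> EGA source field
EGA_FIELD_MAP: dict[str, str] = {
    "title": "Study-STUDY_TITLE",
    "type": "Study-STUDY_TYPE",
    "abstract": "Study-STUDY_ABSTRACT",
    "project_centre": "Study-CENTER_PROJECT_NAME",
    "description": "Study-STUDY_DESCRIPTION",
    "sample_taxon_id": "Assembly-TAXON_ID",
    "sample_title": "Assembly-TITLE",
}

# NCBI has no abstract at all; the remaining six fields map directly.
NCBI_FIELD_MAP: dict[str, str] = {
    "title": "BioProject-Title",
    "type": "BioProject-ProjectTypeSubmission",
    "project_centre": "BioProject-Organization",
    "description": "BioProject-Description",
    "sample_taxon_id": "BioSample-TAXON_ID",
    "sample_title": "BioSample-TITLE",
}

# extension attribute name -> NCBI BioSample attribute
NCBI_EXTENSION_MAP: dict[str, str] = {
    "StudyDesign": "BioSample-Attribute-study design",
    "BodySite": "BioSample-Attribute-body site",
    "AnalyteType": "BioSample-Attribute-analyte type",
    "IsTumor": "BioSample-Attribute-is tumor",
}

_XML_TAGS: dict[str, str] = {
    "title": "Title",
    "type": "Type",
    "abstract": "Abstract",
    "project_centre": "ProjectCentre",
    "description": "Description",
    "sample_taxon_id": "SampleTaxonId",
    "sample_title": "SampleTitle",
}
_TAG_TO_FIELD = {tag: attr for attr, tag in _XML_TAGS.items()}


@dataclass
class MetadataRecord:
    """Core study/sample metadata plus ordered extension attributes."""

    title: str = ""
    type: str = ""
    abstract: str = ""
    project_centre: str = ""
    description: str = ""
    sample_taxon_id: str = ""
    sample_title: str = ""
    extensions: dict[str, str] = field(default_factory=dict)


def map_from_ega(fields: Mapping[str, str]) -> MetadataRecord:
    """Build a record from EGA Study/Assembly fields (missing keys -> empty)."""
    return MetadataRecord(
        **{attr: fields.get(src, "") for attr, src in EGA_FIELD_MAP.items()}
    )


def map_from_ncbi(fields: Mapping[str, str]) -> MetadataRecord:
    """Build a record from NCBI BioProject/BioSample fields.

    The abstract is always empty: NCBI metadata has no such field.
    """
    record = MetadataRecord(
        **{attr: fields.get(src, "") for attr, src in NCBI_FIELD_MAP.items()}
    )
    for ext_name, src in NCBI_EXTENSION_MAP.items():
        if src in fields:
            add_extension(record, ext_name, fields[src])
    return record


def add_extension(record: MetadataRecord, name: str, value: str) -> MetadataRecord:
    """Store an extension attribute; re-adding a name replaces its value."""
    if not name:
        raise ValueError("extension name must be nonempty")
    record.extensions[name] = value
    return record


def to_xml(record: MetadataRecord) -> bytes:
    """Serialise to the ``dgmd``/``dtmd`` XML payload (core fields, then
    extensions, in stable order)."""
    root = etree.Element("Metadata")
    for attr, tag in _XML_TAGS.items():
        etree.SubElement(root, tag).text = getattr(record, attr) or None
    for name, value in record.extensions.items():
        ext = etree.SubElement(root, "Extension", name=name)
        ext.text = value or None
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def from_xml(data: bytes) -> MetadataRecord:
    """Parse a metadata XML payload.

    Unknown elements are folded into extensions (keyed by tag name) rather
    than rejected, honouring the format's extension mechanism.
    """
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise MetadataXmlError(f"malformed metadata XML: {exc}") from exc
    if root.tag != "Metadata":
        raise MetadataXmlError(f"expected <Metadata> root, got <{root.tag}>")
    record = MetadataRecord()
    for child in root:
        if not isinstance(child.tag, str):
            continue  # comments / processing instructions
        text = child.text or ""
        if child.tag in _TAG_TO_FIELD:
            setattr(record, _TAG_TO_FIELD[child.tag], text)
        elif child.tag == "Extension":
            name = child.get("name")
            if not name:
                raise MetadataXmlError("<Extension> element without a name attribute")
            record.extensions[name] = text
        else:
            record.extensions[child.tag] = text
    return record
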