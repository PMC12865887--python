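"""Read and write the final annotation JSON.

One document per article, Europe PMC submission style: provider and
article identifiers at the top level, the annotations under ``anns``,
structure/UniProt associations under each annotation's ``tags``. Writing
is byte-stable (fixed key order, UTF-8) and enforces the licence rule:
for articles that are not open access, only ``residue_name_number`` and
``mutant`` annotations are recorded — emitting the 30-character context
windows for every entity type would expose large parts of a paywalled
text. A shipped JSON schema documents the dialect; documents are checked
against it on both write and read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

from .errors import ParseError, SchemaError
from .harvest import Annotation
from .jats import ArticleMetadata
from .postprocess import parse_mention

GROUNDED_TYPES = frozenset({"residue_name_number", "mutant"})


@dataclass
class AnnotationDocument:
    """An article's metadata plus its final annotations."""

    metadata: ArticleMetadata
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.metadata.licence == "closed":
            offending = [a.type for a in self.annotations if a.type not in GROUNDED_TYPES]
            if offending:
                raise ValueError(
                    "closed-licence document may only carry residue/mutant "
                    f"annotations, found {sorted(set(offending))}"
                )


# ---------------------------------------------------------------------------
# schema subset validator (type / enum / required / properties / items / oneOf)


def load_schema() -> dict:
    with resources.files("residuelink.schema").joinpath(
        "annotations.schema.json"
    ).open("rb") as fh:
        return json.load(fh)


_TYPE_CHECKS = {
    "object": lambda v: isinstance(v, dict),
    "array": lambda v: isinstance(v, list),
    "string": lambda v: isinstance(v, str),
    "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
    "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
    "boolean": lambda v: isinstance(v, bool),
    "null": lambda v: v is None,
}


def _validate(value, schema: dict, path: str) -> None:
    if "oneOf" in schema:
        for sub in schema["oneOf"]:
            try:
                _validate(value, sub, path)
                break
            except SchemaError:
                continue
        else:
            raise SchemaError(path, "matches no alternative of oneOf")
        return
    if "enum" in schema and value not in schema["enum"]:
        raise SchemaError(path, f"{value!r} not one of {schema['enum']}")
    stype = schema.get("type")
    if stype is not None:
        types = stype if isinstance(stype, list) else [stype]
        if not any(_TYPE_CHECKS[t](value) for t in types):
            raise SchemaError(path, f"expected {stype}, got {type(value).__name__}")
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                raise SchemaError(path, f"missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _validate(value[key], sub, f"{path}/{key}")
    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _validate(item, schema["items"], f"{path}/{i}")


def validate_payload(payload: dict) -> None:
    """Check a document payload against the shipped schema.

    Raises :class:`SchemaError` carrying the JSON-pointer path of the
    offending field.
    """
    _validate(payload, load_schema(), "")


# ---------------------------------------------------------------------------
# writing


def _annotation_payload(ann: Annotation) -> dict:
    return {
        "sid": ann.sid,
        "exact": ann.exact,
        "position": ann.position,
        "prefix": ann.prefix,
        "postfix": ann.postfix,
        "type": ann.type,
        "ai_score": ann.ai_score,
        "char_start": ann.char_start,
        "char_end": ann.char_end,
        "annotator": ann.annotator,
        "tags": ann.tags,
    }


def write_annotations(
    metadata: ArticleMetadata,
    annotations: list[Annotation],
    drop_unlinked: bool = False,
    blank_closed_context: bool = False,
) -> bytes:
    """Serialise a document to deterministic UTF-8 JSON bytes.

    Applies the closed-licence entity-type filter; ``drop_unlinked``
    additionally removes residue/mutant annotations whose tags are empty
    (mentions the pipeline could not ground in any structure);
    ``blank_closed_context`` blanks prefix/postfix for closed articles.
    """
    kept = list(annotations)
    if metadata.licence == "closed":
        kept = [a for a in kept if a.type in GROUNDED_TYPES]
        if blank_closed_context:
            kept = [replace(a, prefix="", postfix="") for a in kept]
    if drop_unlinked:
        kept = [a for a in kept if a.type not in GROUNDED_TYPES or a.tags]
    payload = {
        "provider": metadata.provider,
        "doi": metadata.doi,
        "pmid": metadata.pmid,
        "pmcid": metadata.pmcid,
        "publisher_id": metadata.publisher_id,
        "licence": metadata.licence,
        "pdb_ids": metadata.pdb_ids,
        "organism_names": metadata.organism_names,
        "taxonomy_ids": metadata.taxonomy_ids,
        "uniprot_accessions": metadata.uniprot_accessions,
        "anns": [_annotation_payload(a) for a in kept],
    }
    validate_payload(payload)
    return json.dumps(payload, ensure_ascii=False, indent=2).encode("utf-8")


def read_annotations(data: bytes) -> AnnotationDocument:
    """Parse and validate annotation JSON back into a document.

    The mention structure for residue/mutant annotations is re-derived
    from the exact span, so ``read(write(x)) == x`` for any document
    produced by the pipeline.
    """
    try:
        payload = json.loads(data)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed annotation JSON: {exc}") from exc
    validate_payload(payload)
    metadata = ArticleMetadata(
        doi=payload["doi"],
        pmid=payload.get("pmid"),
        pmcid=payload.get("pmcid"),
        publisher_id=payload.get("publisher_id"),
        licence=payload["licence"],
        provider=payload["provider"],
        pdb_ids=payload.get("pdb_ids", []),
        organism_names=payload.get("organism_names", []),
        taxonomy_ids=payload.get("taxonomy_ids", []),
        uniprot_accessions=payload.get("uniprot_accessions", []),
    )
    annotations = []
    for raw in payload["anns"]:
        mention = None
        if raw["type"] in GROUNDED_TYPES:
            mention = parse_mention(raw["exact"], raw["type"])
        annotations.append(
            Annotation(
                sid=raw["sid"],
                exact=raw["exact"],
                position=raw["position"],
                prefix=raw["prefix"],
                postfix=raw["postfix"],
                type=raw["type"],
                ai_score=raw["ai_score"],
                char_start=raw["char_start"],
                char_end=raw["char_end"],
                annotator=raw["annotator"],
                tags=raw["tags"],
                mention=mention,
            )
        )
    return AnnotationDocument(metadata=metadata, annotations=annotations)
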