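"""End-to-end orchestration: article in, annotation JSON out.

Wires the stages in order — JATS ingest, metadata enrichment, batched
tagging, adjacency merging, harvesting, pattern post-processing, SIFTS
resolution and validation enrichment, serialisation — under one
configuration object. Each linked PDB entry is processed independently:
a missing SIFTS file skips that entry with a warning, a missing
validation file leaves the quality fields of its tags empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from . import annotation_io, jats, postprocess, sifts, tagger, validation
from .annotation_io import GROUNDED_TYPES, AnnotationDocument
from .harvest import Annotation, harvest as build_annotations, merge_adjacent

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    backend: str = "reference"
    chunk_size: int = 8
    batch_size: int = 4
    token_limit: int = tagger.DEFAULT_TOKEN_LIMIT
    scheme_priority: tuple[str, ...] = ("pdb", "uniprot")
    bridge_whitespace: bool = True
    allow_mixed: bool = True
    drop_unlinked: bool = False
    blank_closed_context: bool = False
    licence_override: str | None = None
    default_method: str = "xray"

    def __post_init__(self) -> None:
        if self.chunk_size < 1 or self.batch_size < 1:
            raise ValueError("chunk_size and batch_size must be >= 1")


@dataclass
class PipelineResult:
    metadata: jats.ArticleMetadata
    annotations: list[Annotation]
    dropped: int = 0
    linked: int = 0
    unlinked: int = 0

    def document(self) -> AnnotationDocument:
        anns = self.annotations
        if self.metadata.licence == "closed":
            anns = [a for a in anns if a.type in GROUNDED_TYPES]
        return AnnotationDocument(metadata=self.metadata, annotations=anns)


def annotate_article(
    jats_bytes: bytes,
    sifts_files: dict[str, bytes] | None = None,
    validation_files: dict[str, bytes] | None = None,
    lookup_records: dict | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full annotation pipeline on one article.

    ``sifts_files`` and ``validation_files`` map lowercase PDB ids to
    raw XML bytes for the structures the article links to.
    """
    config = config or PipelineConfig()
    sifts_files = sifts_files or {}
    validation_files = validation_files or {}

    doc = jats.parse_jats(jats_bytes)
    if lookup_records:
        doc = jats.enrich_metadata(doc, lookup_records)
    if config.licence_override:
        doc = jats.ArticleDocument(
            metadata=replace(doc.metadata, licence=config.licence_override),
            sentences=doc.sentences,
        )

    predictions = tagger.predict_document(
        doc,
        backend=config.backend,
        chunk_size=config.chunk_size,
        batch_size=config.batch_size,
        token_limit=config.token_limit,
    )
    merged = merge_adjacent(
        predictions, doc, bridge_whitespace=config.bridge_whitespace
    )
    annotations = build_annotations(doc, merged)
    processed = postprocess.postprocess_annotations(
        annotations, allow_mixed=config.allow_mixed
    )
    dropped = len(annotations) - len(processed)

    # resolve each grounded mention against every linked structure
    mnemonics = (lookup_records or {}).get("species_mnemonics", {})
    entries: list[tuple[str, list[sifts.SiftsResidue], validation.ValidationIndex | None]] = []
    for pdb_id in doc.metadata.pdb_ids:
        raw = sifts_files.get(pdb_id)
        if raw is None:
            logger.warning("no SIFTS file for linked entry %s; skipped", pdb_id)
            continue
        residues = sifts.parse_sifts(raw)
        vindex = None
        vraw = validation_files.get(pdb_id)
        if vraw is not None:
            vindex = validation.parse_validation(vraw)
        else:
            logger.warning(
                "no validation file for %s; quality fields left empty", pdb_id
            )
        entries.append((pdb_id, residues, vindex))

    linked = unlinked = 0
    final: list[Annotation] = []
    for ann in processed:
        if ann.type not in GROUNDED_TYPES or ann.mention is None:
            final.append(ann)
            continue
        tags: list[dict] = []
        for pdb_id, residues, vindex in entries:
            hits = sifts.resolve_mention(
                ann.mention, residues, scheme_priority=config.scheme_priority
            )
            if not hits:
                continue
            method = vindex.method if vindex else config.default_method

            def lookup_quality(pid, chain, number, icode, _v=vindex):
                return _v.get(chain, number, icode) if _v else None

            tags.extend(
                sifts.build_tags(
                    ann.mention, hits, lookup_quality, method, mnemonics
                )
            )
        if tags:
            linked += 1
        else:
            unlinked += 1
            logger.info("no structure link for mention %r (sid %d)", ann.exact, ann.sid)
        final.append(replace(ann, tags=tags))

    if config.drop_unlinked:
        final = [
            a for a in final if a.type not in GROUNDED_TYPES or a.tags
        ]
    return PipelineResult(
        metadata=doc.metadata,
        annotations=final,
        dropped=dropped,
        linked=linked,
        unlinked=unlinked,
    )


def annotate_to_json(
    jats_bytes: bytes,
    sifts_files: dict[str, bytes] | None = None,
    validation_files: dict[str, bytes] | None = None,
    lookup_records: dict | None = None,
    config: PipelineConfig | None = None,
) -> bytes:
    """Convenience wrapper returning the final annotation JSON bytes."""
    config = config or PipelineConfig()
    result = annotate_article(
        jats_bytes, sifts_files, validation_files, lookup_records, config
    )
    return annotation_io.write_annotations(
        result.metadata,
        result.annotations,
        drop_unlinked=config.drop_unlinked,
        blank_closed_context=config.blank_closed_context,
    )
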