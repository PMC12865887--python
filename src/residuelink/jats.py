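"""JATS article ingestion.

Turns a full-text article in JATS XML into a *sentence dictionary*: an
ordered list of sentences, each carrying a stable 1-based identifier, its
enclosing section title, and character bounds (``char_start`` is always 0,
``char_end`` the sentence length). Downstream stages address annotations
by sentence id plus character offsets into that sentence.

Running text is taken from ``<p>`` elements of the abstract and body
``<sec>`` elements, in reading order; references, tables, figure captions
and display math are excluded by default. Inline markup (italics,
superscripts, links) is flattened to its text content, so a span written
``Glu89<sup>H_complexB</sup>`` in the source arrives here as the plain
string ``Glu89H_complexB``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace

from lxml import etree

from .errors import EmptyDocumentError, MetadataConflictError, ParseError

logger = logging.getLogger(__name__)

PDB_ID_RE = re.compile(r"^[0-9][a-z0-9]{3}$")

#: abbreviations whose trailing period never ends a sentence
DEFAULT_PROTECTED_ABBREVIATIONS: tuple[str, ...] = (
    "Fig.",
    "Figs.",
    "Eq.",
    "Eqs.",
    "Ref.",
    "Refs.",
    "No.",
    "Dr.",
    "Prof.",
    "e.g.",
    "i.e.",
    "et al.",
    "al.",
    "ca.",
    "cf.",
    "vs.",
    "approx.",
    "resp.",
)

#: JATS elements whose subtree is never running text
_EXCLUDED_TAGS = frozenset(
    {
        "table-wrap",
        "table",
        "fig",
        "caption",
        "ref-list",
        "disp-formula",
        "inline-formula",
        "xref",
    }
)


@dataclass(frozen=True)
class SentenceRecord:
    """One sentence of running text.

    ``char_start`` is always 0 and ``char_end`` the character count of
    ``text``; offsets elsewhere in the pipeline are relative to the
    sentence, not the document.
    """

    sid: int
    text: str
    section: str
    char_start: int = 0
    char_end: int = -1

    def __post_init__(self) -> None:
        if self.char_end == -1:
            object.__setattr__(self, "char_end", len(self.text))
        if self.sid < 1:
            raise ValueError(f"sentence id must be positive, got {self.sid}")
        if self.char_start != 0:
            raise ValueError("char_start must be 0")
        if self.char_end != len(self.text):
            raise ValueError("char_end must equal the sentence length")


@dataclass
class ArticleMetadata:
    """Article identifiers, licence, and linked-structure metadata."""

    doi: str = ""
    pmid: str | None = None
    pmcid: str | None = None
    publisher_id: str | None = None
    licence: str = "unknown"  # open | closed | unknown
    provider: str = "IUCr"
    pdb_ids: list[str] = field(default_factory=list)
    organism_names: list[str] = field(default_factory=list)
    taxonomy_ids: list[str] = field(default_factory=list)
    uniprot_accessions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provider:
            raise ValueError("provider must be non-empty")
        if self.licence not in ("open", "closed", "unknown"):
            raise ValueError(f"invalid licence {self.licence!r}")
        bad = [p for p in self.pdb_ids if not PDB_ID_RE.match(p)]
        if bad:
            raise ValueError(f"invalid PDB ids: {bad}")


@dataclass
class ArticleDocument:
    """An article's metadata plus its sentence dictionary."""

    metadata: ArticleMetadata
    sentences: list[SentenceRecord]

    def __post_init__(self) -> None:
        sids = [s.sid for s in self.sentences]
        if any(b <= a for a, b in zip(sids, sids[1:])):
            raise ValueError("sentence ids must be strictly increasing")

    def sentence(self, sid: int) -> SentenceRecord:
        for s in self.sentences:
            if s.sid == sid:
                return s
        raise KeyError(f"no sentence with sid {sid}")


# ---------------------------------------------------------------------------
# sentence segmentation


def _build_boundary_re() -> re.Pattern[str]:
    # terminal punctuation, optional closing quotes/brackets, whitespace,
    # then a plausible sentence opener (capital, digit, or opening mark)
    return re.compile(r"[.?!][\"'”’)\]]*\s+(?=[A-Z0-9(\"'“‘[])")


_BOUNDARY_RE = _build_boundary_re()


def segment_sentences(
    paragraph_text: str,
    protected_abbreviations: tuple[str, ...] = DEFAULT_PROTECTED_ABBREVIATIONS,
) -> list[str]:
    """Split a paragraph into sentences.

    Rule-based: a boundary is terminal punctuation ([.?!] plus any closing
    quotes/brackets) followed by whitespace and a capital letter, digit or
    opening mark. A protected-abbreviation list ("Fig.", "e.g.", "et al.",
    ...) suppresses false splits. Always returns >= 0 stripped spans whose
    non-whitespace content concatenates to the input's.
    """
    text = paragraph_text
    if not text.strip():
        return []
    cut_points: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        head = text[: m.start() + 1]  # up to and including the period
        if any(head.endswith(abbr) for abbr in protected_abbreviations):
            continue
        cut_points.append(m.end())
    spans: list[str] = []
    prev = 0
    for cut in cut_points:
        spans.append(text[prev:cut].strip())
        prev = cut
    tail = text[prev:].strip()
    if tail:
        spans.append(tail)
    return [s for s in spans if s]


# ---------------------------------------------------------------------------
# JATS parsing


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname if isinstance(el.tag, str) else ""


def _flatten_text(el: etree._Element) -> str:
    """Concatenate all text content, skipping excluded subtrees.

    Superscript/subscript content is concatenated without separators, so
    markup-decorated spans collapse into the contiguous string a reader
    would copy out of the rendered page.
    """
    parts: list[str] = []

    def walk(node: etree._Element) -> None:
        if _local(node) in _EXCLUDED_TAGS:
            if node.tail:
                parts.append(node.tail)
            return
        if node.text:
            parts.append(node.text)
        for child in node:
            walk(child)
        if node.tail:
            parts.append(node.tail)

    if el.text:
        parts.append(el.text)
    for child in el:
        walk(child)
    return "".join(parts)


def _section_title(p: etree._Element) -> str:
    anc = p.getparent()
    while anc is not None:
        name = _local(anc)
        if name == "sec":
            for child in anc:
                if _local(child) == "title":
                    return " ".join(_flatten_text(child).split())
            sec_type = anc.get("sec-type")
            if sec_type:
                return sec_type
        elif name == "abstract":
            return "Abstract"
        anc = anc.getparent()
    return ""


_XLINK_HREF = "{http://www.w3.org/1999/xlink}href"


def _extract_pdb_ids(root: etree._Element) -> list[str]:
    found: list[str] = []
    for el in root.iter():
        if _local(el) != "ext-link":
            continue
        if (el.get("ext-link-type") or "").lower() != "pdb":
            continue
        href = el.get(_XLINK_HREF) or el.get("href") or ""
        candidate = (href.rstrip("/").rsplit("/", 1)[-1] or _flatten_text(el)).strip()
        candidate = candidate.lower()
        if PDB_ID_RE.match(candidate) and candidate not in found:
            found.append(candidate)
    return found


def _extract_metadata(root: etree._Element) -> ArticleMetadata:
    doi = ""
    pmid = pmcid = publisher_id = None
    for el in root.iter():
        if _local(el) != "article-id":
            continue
        kind = (el.get("pub-id-type") or "").lower()
        value = (el.text or "").strip()
        if kind == "doi" and not doi:
            doi = value
        elif kind == "pmid" and pmid is None:
            pmid = value
        elif kind in ("pmcid", "pmc") and pmcid is None:
            pmcid = value
        elif kind == "publisher-id" and publisher_id is None:
            publisher_id = value
    licence = "unknown"
    for el in root.iter():
        if _local(el) == "license":
            ltype = (el.get("license-type") or "").lower()
            licence = "open" if "open" in ltype else "closed"
            break
    return ArticleMetadata(
        doi=doi,
        pmid=pmid,
        pmcid=pmcid,
        publisher_id=publisher_id,
        licence=licence,
        pdb_ids=_extract_pdb_ids(root),
    )


def parse_jats(
    xml_bytes: bytes,
    protected_abbreviations: tuple[str, ...] = DEFAULT_PROTECTED_ABBREVIATIONS,
) -> ArticleDocument:
    """Parse a JATS article into an :class:`ArticleDocument`.

    Raises :class:`ParseError` (naming the byte position) on malformed
    XML and :class:`EmptyDocumentError` when the article has no
    section/paragraph running text at all.
    """
    try:
        root = etree.fromstring(xml_bytes)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed JATS XML: {exc}") from exc

    metadata = _extract_metadata(root)

    paragraphs: list[tuple[str, str]] = []  # (section, text)
    seen_container = False
    for container in root.iter():
        name = _local(container)
        if name not in ("abstract", "body"):
            continue
        seen_container = True
        for p in container.iter():
            if _local(p) != "p":
                continue
            # only paragraphs under a sec or directly under abstract/body
            skip = False
            anc = p.getparent()
            while anc is not None and anc is not container:
                if _local(anc) in _EXCLUDED_TAGS:
                    skip = True
                    break
                anc = anc.getparent()
            if skip:
                continue
            text = " ".join(_flatten_text(p).split())
            if text:
                paragraphs.append((_section_title(p), text))
    if not seen_container or not paragraphs:
        raise EmptyDocumentError("article contains no <sec>/<p> running text")

    sentences: list[SentenceRecord] = []
    sid = 0
    for section, text in paragraphs:
        for span in segment_sentences(text, protected_abbreviations):
            sid += 1
            sentences.append(SentenceRecord(sid=sid, text=span, section=section))
    if not sentences:
        raise EmptyDocumentError("article paragraphs contain no sentences")
    return ArticleDocument(metadata=metadata, sentences=sentences)


# ---------------------------------------------------------------------------
# offline metadata enrichment


def enrich_metadata(doc: ArticleDocument, lookup_records: dict) -> ArticleDocument:
    """Fill metadata fields from offline lookup records.

    ``lookup_records`` may carry two maps: ``"articles"`` keyed by DOI
    (values: one record or a list of records with pmid/pmcid/
    publisher_id/licence) and ``"structures"`` keyed by lowercase PDB id
    (values: uniprot_accessions/organism_names/taxonomy_ids). Fields
    that do not resolve are left untouched, never guessed. Conflicting
    licence values across records for one DOI raise
    :class:`MetadataConflictError`.
    """
    meta = replace(
        doc.metadata,
        pdb_ids=list(doc.metadata.pdb_ids),
        organism_names=list(doc.metadata.organism_names),
        taxonomy_ids=list(doc.metadata.taxonomy_ids),
        uniprot_accessions=list(doc.metadata.uniprot_accessions),
    )
    articles = lookup_records.get("articles", {})
    raw = articles.get(meta.doi, [])
    records = raw if isinstance(raw, list) else [raw]
    licences = {r["licence"] for r in records if r.get("licence")}
    if len(licences) > 1:
        raise MetadataConflictError("licence", sorted(licences))
    for rec in records:
        if rec.get("pmid") and meta.pmid is None:
            meta.pmid = str(rec["pmid"])
        if rec.get("pmcid") and meta.pmcid is None:
            meta.pmcid = str(rec["pmcid"])
        if rec.get("publisher_id") and meta.publisher_id is None:
            meta.publisher_id = str(rec["publisher_id"])
        if rec.get("licence") and meta.licence == "unknown":
            meta.licence = rec["licence"]
    structures = lookup_records.get("structures", {})
    for pdb_id in meta.pdb_ids:
        rec = structures.get(pdb_id)
        if not rec:
            continue
        for acc in rec.get("uniprot_accessions", []):
            if acc not in meta.uniprot_accessions:
                meta.uniprot_accessions.append(acc)
        for name in rec.get("organism_names", []):
            if name not in meta.organism_names:
                meta.organism_names.append(name)
        for tax in rec.get("taxonomy_ids", []):
            if str(tax) not in meta.taxonomy_ids:
                meta.taxonomy_ids.append(str(tax))
    return ArticleDocument(metadata=meta, sentences=doc.sentences)


# ---------------------------------------------------------------------------
# sentence-dictionary JSON round trip


def document_to_json(doc: ArticleDocument) -> bytes:
    payload = {
        "metadata": {
            "doi": doc.metadata.doi,
            "pmid": doc.metadata.pmid,
            "pmcid": doc.metadata.pmcid,
            "publisher_id": doc.metadata.publisher_id,
            "licence": doc.metadata.licence,
            "provider": doc.metadata.provider,
            "pdb_ids": doc.metadata.pdb_ids,
            "organism_names": doc.metadata.organism_names,
            "taxonomy_ids": doc.metadata.taxonomy_ids,
            "uniprot_accessions": doc.metadata.uniprot_accessions,
        },
        "sentences": [
            {
                "sid": s.sid,
                "text": s.text,
                "section": s.section,
                "char_start": s.char_start,
                "char_end": s.char_end,
            }
            for s in doc.sentences
        ],
    }
    return json.dumps(payload, ensure_ascii=False, indent=2).encode("utf-8")


def document_from_json(data: bytes) -> ArticleDocument:
    try:
        payload = json.loads(data)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed sentence-dictionary JSON: {exc}") from exc
    meta = ArticleMetadata(**payload["metadata"])
    sentences = [SentenceRecord(**s) for s in payload["sentences"]]
    return ArticleDocument(metadata=meta, sentences=sentences)
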