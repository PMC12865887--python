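"""Entity tagging backends and sentence batching.

The pipeline is backend-agnostic: any callable registered in the backend
registry that maps sentence text to raw standoff predictions can drive
it. The shipped ``reference`` backend is a deterministic pattern matcher
over residue and point-mutation notation, so the full pipeline runs with
no model weights; a fine-tuned transformer can be plugged in behind the
same contract.

Sentences are grouped for prediction the way an encoder with a 512-token
window is fed: a fixed number of sentences per chunk (default 8) and
chunks per batch (default 4, i.e. 32 sentences per batch), with oversize
chunks split on a conservative token estimate.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable

from . import aa
from .errors import ConfigurationError
from .jats import ArticleDocument, SentenceRecord

logger = logging.getLogger(__name__)

#: the closed vocabulary of entity type labels
ENTITY_TYPES: frozenset[str] = frozenset(
    {
        "bond_interaction",
        "chemical",
        "complex_assembly",
        "evidence",
        "experimental_method",
        "gene",
        "mutant",
        "oligomeric_state",
        "protein",
        "protein_state",
        "protein_type",
        "ptm",
        "residue_name",
        "residue_number",
        "residue_name_number",
        "residue_range",
        "site",
        "species",
        "structure_element",
        "taxonomy_domain",
    }
)


def check_entity_type(label: str) -> str:
    if label not in ENTITY_TYPES:
        raise ValueError(f"unknown entity type label {label!r}")
    return label


@dataclass(frozen=True)
class RawPrediction:
    """One raw standoff prediction on a sentence.

    Offsets are 0-based half-open character counts into the sentence;
    ``text`` must equal the sentence substring they delimit.
    """

    sid: int
    char_start: int
    char_end: int
    text: str
    label: str
    score: float

    def __post_init__(self) -> None:
        check_entity_type(self.label)
        if not (0 <= self.char_start < self.char_end):
            raise ValueError(
                f"invalid span [{self.char_start}, {self.char_end}) for {self.text!r}"
            )
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score out of [0, 1]: {self.score}")


# ---------------------------------------------------------------------------
# batching

#: maximum encoder window, in tokens
DEFAULT_TOKEN_LIMIT = 512
#: conservative tokens-per-word factor for subword tokenisers
TOKEN_FACTOR = 1.5


def estimate_tokens(text: str) -> int:
    """Conservative subword-token estimate: whitespace words x 1.5."""
    return int(len(text.split()) * TOKEN_FACTOR)


@dataclass
class Chunk:
    sentences: list[SentenceRecord]
    truncated_sids: list[int] = field(default_factory=list)


def batch_sentences(
    doc: ArticleDocument,
    chunk_size: int = 8,
    batch_size: int = 4,
    token_limit: int = DEFAULT_TOKEN_LIMIT,
) -> list[list[Chunk]]:
    """Group a document's sentences into batches of chunks.

    Each chunk holds at most ``chunk_size`` sentences and fits within
    ``token_limit`` estimated tokens; each batch holds at most
    ``batch_size`` chunks. Every sentence lands in exactly one chunk, in
    document order. A single sentence whose own estimate exceeds the
    limit still gets a chunk but is flagged for truncated prediction
    (annotation offsets keep referring to the full sentence).
    """
    if chunk_size < 1 or batch_size < 1:
        raise ValueError("chunk_size and batch_size must be >= 1")
    chunks: list[Chunk] = []
    current = Chunk(sentences=[])
    current_tokens = 0
    for sent in doc.sentences:
        tokens = estimate_tokens(sent.text)
        oversize_alone = tokens > token_limit
        if current.sentences and (
            len(current.sentences) >= chunk_size
            or current_tokens + tokens > token_limit
        ):
            chunks.append(current)
            current = Chunk(sentences=[])
            current_tokens = 0
        current.sentences.append(sent)
        current_tokens += tokens
        if oversize_alone:
            current.truncated_sids.append(sent.sid)
            logger.warning(
                "sentence %d exceeds the %d-token limit; prediction input truncated",
                sent.sid,
                token_limit,
            )
    if current.sentences:
        chunks.append(current)
    return [chunks[i : i + batch_size] for i in range(0, len(chunks), batch_size)]


# ---------------------------------------------------------------------------
# reference pattern backend

_RESIDUE_RE = re.compile(
    rf"\b(?:{aa.THREE_LETTER_ALT}) ?[0-9]{{1,5}}\b"
)
_MUTANT1_RE = re.compile(
    rf"\b[{aa.ONE_LETTER_CLASS}][0-9]{{1,5}}[{aa.ONE_LETTER_CLASS}]\b"
)
_MUTANT3_RE = re.compile(
    rf"\b(?:{aa.THREE_LETTER_ALT})[0-9]{{1,5}}(?:{aa.THREE_LETTER_ALT})\b"
)

_PATTERNS: tuple[tuple[re.Pattern[str], str], ...] = (
    (_RESIDUE_RE, "residue_name_number"),
    (_MUTANT1_RE, "mutant"),
    (_MUTANT3_RE, "mutant"),
)


def reference_tag(sentence_text: str, sid: int = 0) -> list[RawPrediction]:
    """Deterministic rule tagger for residue and point-mutation mentions.

    Finds every maximal, non-overlapping match of three patterns:
    three-letter residue + optional space + number (residue_name_number),
    one-letter wt + number + one-letter mutant (mutant), and three-letter
    wt + number + three-letter mutant (mutant). Longer matches win
    overlaps; leftmost wins ties. Scores are fixed at 1.0 — the rules are
    certain by construction.
    """
    candidates: list[tuple[int, int, str]] = []
    for pattern, label in _PATTERNS:
        for m in pattern.finditer(sentence_text):
            candidates.append((m.start(), m.end(), label))
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    chosen: list[tuple[int, int, str]] = []
    for start, end, label in candidates:
        if any(start < e and s < end for s, e, _ in chosen):
            continue
        chosen.append((start, end, label))
    chosen.sort()
    return [
        RawPrediction(
            sid=sid,
            char_start=start,
            char_end=end,
            text=sentence_text[start:end],
            label=label,
            score=1.0,
        )
        for start, end, label in chosen
    ]


# ---------------------------------------------------------------------------
# backend registry

Backend = Callable[[str, int], list[RawPrediction]]

_BACKENDS: dict[str, Backend] = {"reference": reference_tag}


def register_backend(name: str, backend: Backend) -> None:
    _BACKENDS[name] = backend


def get_backend(name: str) -> Backend:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown tagger backend {name!r}; registered: {sorted(_BACKENDS)}"
        ) from None


def predict(backend: Backend | str, batch: list[Chunk]) -> list[RawPrediction]:
    """Run a backend over one batch of chunks, in order."""
    fn = get_backend(backend) if isinstance(backend, str) else backend
    out: list[RawPrediction] = []
    for chunk in batch:
        for sent in chunk.sentences:
            for pred in fn(sent.text, sent.sid):
                if pred.char_end > sent.char_end:
                    raise ValueError(
                        f"backend prediction exceeds sentence bounds: {pred}"
                    )
                if pred.text != sent.text[pred.char_start : pred.char_end]:
                    raise ValueError(f"backend prediction text mismatch: {pred}")
                out.append(pred)
    return out


def predict_document(
    doc: ArticleDocument,
    backend: Backend | str = "reference",
    chunk_size: int = 8,
    batch_size: int = 4,
    token_limit: int = DEFAULT_TOKEN_LIMIT,
) -> list[RawPrediction]:
    """Batch a whole document and run the backend over every batch."""
    preds: list[RawPrediction] = []
    for batch in batch_sentences(doc, chunk_size, batch_size, token_limit):
        preds.extend(predict(backend, batch))
    return preds
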