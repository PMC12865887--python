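"""Harvest raw predictions into standoff annotations.

An annotation follows the Europe PMC submission keys: the exact text
span, a ``position`` key "<sentence id>.<word index>" (so "25.18" is the
18th word of the 25th sentence), up to 30 characters of prefix/postfix
context clipped at the sentence bounds, the entity type, the tagger
confidence, and character offsets into the sentence. Before harvesting,
same-type predictions that the tagger split across directly adjacent
spans are fused back into one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any

from .jats import ArticleDocument
from .tagger import RawPrediction, check_entity_type

logger = logging.getLogger(__name__)

CONTEXT_CHARS = 30

#: sentinel confidence for annotations rewritten in post-processing
REMOVED = "removed"


@dataclass
class Annotation:
    """One standoff annotation on a sentence."""

    sid: int
    exact: str
    position: str
    prefix: str
    postfix: str
    type: str
    ai_score: float | str
    char_start: int
    char_end: int
    tags: list[dict[str, Any]] = field(default_factory=list)
    annotator: str = "model"
    mention: Any = None  # ParsedMention, attached in post-processing

    def __post_init__(self) -> None:
        check_entity_type(self.type)
        if len(self.prefix) > CONTEXT_CHARS or len(self.postfix) > CONTEXT_CHARS:
            raise ValueError("context windows are limited to 30 characters")
        if isinstance(self.ai_score, str) and self.ai_score != REMOVED:
            raise ValueError(f"string ai_score must be {REMOVED!r}")


def make_position(sid: int, char_start: int, sentence_text: str) -> str:
    """Return the "<sid>.<word index>" position key for a span start.

    The word index is 1-based over whitespace-delimited words: it equals
    one plus the number of words lying wholly before ``char_start``, so a
    span starting mid-word takes that word's index.
    """
    if not (0 <= char_start <= len(sentence_text)):
        raise ValueError(
            f"char_start {char_start} outside sentence of length {len(sentence_text)}"
        )
    words_before = 0
    in_word = False
    for i, ch in enumerate(sentence_text):
        if i >= char_start:
            break
        if ch.isspace():
            if in_word:
                words_before += 1
            in_word = False
        else:
            in_word = True
    # a word still open at char_start is the word containing the span start
    return f"{sid}.{words_before + 1}"


def merge_adjacent(
    predictions: list[RawPrediction],
    doc: ArticleDocument,
    bridge_whitespace: bool = True,
) -> list[RawPrediction]:
    """Fuse same-sentence, same-type predictions that touch or overlap.

    Runs where each next span starts at (or before) the previous end —
    or, unless ``bridge_whitespace`` is off, is separated from it by
    whitespace only — collapse to one span from the first start to the
    last end, with the minimum member score. Overlapping predictions of
    different types are left untouched and logged.
    """
    preds = sorted(predictions, key=lambda p: (p.sid, p.char_start, p.char_end))
    out: list[RawPrediction] = []
    for pred in preds:
        if out:
            prev = out[-1]
            if prev.sid == pred.sid and prev.label == pred.label:
                gap = doc.sentence(pred.sid).text[prev.char_end : pred.char_start]
                touching = pred.char_start <= prev.char_end
                bridged = bridge_whitespace and gap != "" and gap.isspace()
                if touching or bridged:
                    sent = doc.sentence(pred.sid).text
                    end = max(prev.char_end, pred.char_end)
                    out[-1] = replace(
                        prev,
                        char_end=end,
                        text=sent[prev.char_start : end],
                        score=min(prev.score, pred.score),
                    )
                    continue
            if (
                prev.sid == pred.sid
                and prev.label != pred.label
                and pred.char_start < prev.char_end
            ):
                logger.warning(
                    "overlapping predictions of different types left unmerged: "
                    "%r (%s) vs %r (%s)",
                    prev.text,
                    prev.label,
                    pred.text,
                    pred.label,
                )
        out.append(pred)
    return out


def harvest(doc: ArticleDocument, predictions: list[RawPrediction]) -> list[Annotation]:
    """Build one annotation per (merged) prediction, with context fields."""
    annotations: list[Annotation] = []
    for pred in predictions:
        sent = doc.sentence(pred.sid)
        prefix = sent.text[max(0, pred.char_start - CONTEXT_CHARS) : pred.char_start]
        postfix = sent.text[pred.char_end : pred.char_end + CONTEXT_CHARS]
        annotations.append(
            Annotation(
                sid=pred.sid,
                exact=pred.text,
                position=make_position(pred.sid, pred.char_start, sent.text),
                prefix=prefix,
                postfix=postfix,
                type=pred.label,
                ai_score=pred.score,
                char_start=pred.char_start,
                char_end=pred.char_end,
                annotator="model",
            )
        )
    return annotations
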