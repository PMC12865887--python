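"""Validate, repair, relabel or discard residue and mutation annotations.

Model output for the two grounded entity types — ``residue_name_number``
(an amino acid plus sequence position, e.g. Arg155) and ``mutant`` (a
point mutation, e.g. R155A) — is noisy in two ways: the span may carry
extra characters the tokeniser dragged in (``Glu89H_complexB``), and the
label may disagree with the notation (``Arg155`` tagged mutant). Both
are fixed against anchored regular-expression patterns over the standard
amino-acid alphabet; one-letter codes are expanded to three-letter form,
so every surviving mention normalises to ``Arg155`` / ``Arg155Ala``.
Spans that cannot be made to fit any pattern are dropped — they can
never be grounded to a structure residue downstream. Annotations of the
other 18 entity types pass through untouched.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

from . import aa
from .harvest import CONTEXT_CHARS, REMOVED, Annotation

logger = logging.getLogger(__name__)

MIN_SEQ_NUM = 1
MAX_SEQ_NUM = 99999  # PDB numbering range


@dataclass(frozen=True)
class ParsedMention:
    """A normalised residue or point-mutation mention."""

    kind: str  # "residue" | "mutant"
    wt_aa3: str
    seq_num: int
    mut_aa3: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("residue", "mutant"):
            raise ValueError(f"invalid mention kind {self.kind!r}")
        if (self.kind == "mutant") != (self.mut_aa3 is not None):
            raise ValueError("mut_aa3 present iff kind is 'mutant'")
        for code in (self.wt_aa3, self.mut_aa3):
            if code is not None and code not in aa.THREE_TO_ONE:
                raise ValueError(f"non-standard residue code {code!r}")
        if not (MIN_SEQ_NUM <= self.seq_num <= MAX_SEQ_NUM):
            raise ValueError(f"sequence number out of range: {self.seq_num}")

    @property
    def normalized(self) -> str:
        tail = self.mut_aa3 or ""
        return f"{self.wt_aa3}{self.seq_num}{tail}"

    @property
    def label(self) -> str:
        return "residue_name_number" if self.kind == "residue" else "mutant"


_NUM = r"([0-9]{1,5})"
_AA3 = rf"({aa.THREE_LETTER_ALT})"
_AA1 = rf"([{aa.ONE_LETTER_CLASS}])"

RESIDUE_FULL = re.compile(rf"{_AA3} ?{_NUM}\Z")
MUTANT1_FULL = re.compile(rf"{_AA1}{_NUM}{_AA1}\Z")
MUTANT3_FULL = re.compile(rf"{_AA3}{_NUM}{_AA3}\Z")
# mixed notation, e.g. "Arg155A": tolerated only when the tagger already
# claims a mutation — a stray capital after a residue number is otherwise
# far more likely to be a chain or complex label than a substitution
MUTANT_MIXED_FULL = re.compile(rf"{_AA3}{_NUM}{_AA1}\Z")


def _to_three(code: str) -> str | None:
    if len(code) == 1:
        return aa.ONE_TO_THREE.get(code)
    return aa.canonical_three(code)


def _try_patterns(text: str, allow_mixed: bool) -> ParsedMention | None:
    m = RESIDUE_FULL.fullmatch(text)
    if m:
        wt, num = _to_three(m.group(1)), int(m.group(2))
        if wt and MIN_SEQ_NUM <= num <= MAX_SEQ_NUM:
            return ParsedMention(kind="residue", wt_aa3=wt, seq_num=num)
    for pattern in (MUTANT1_FULL, MUTANT3_FULL) + (
        (MUTANT_MIXED_FULL,) if allow_mixed else ()
    ):
        m = pattern.fullmatch(text)
        if not m:
            continue
        wt, num, mut = _to_three(m.group(1)), int(m.group(2)), _to_three(m.group(3))
        if wt and mut and MIN_SEQ_NUM <= num <= MAX_SEQ_NUM:
            return ParsedMention(kind="mutant", wt_aa3=wt, seq_num=num, mut_aa3=mut)
    return None


def parse_mention(
    text: str, claimed_label: str, allow_mixed: bool = True
) -> ParsedMention | None:
    """Parse a mention span against the residue and mutation patterns.

    Patterns are tried in a fixed order (residue, one-letter mutation,
    three-letter mutation, then — only when the tagger claimed a
    mutation — mixed three+one-letter notation); the returned kind comes
    from the pattern that matched, not from ``claimed_label``, which is
    how wrong labels get detected. Returns None when nothing matches.
    """
    if claimed_label not in ("residue_name_number", "mutant"):
        raise ValueError(f"unsupported label for mention parsing: {claimed_label!r}")
    return _try_patterns(text, allow_mixed and claimed_label == "mutant")


def repair_span(
    text: str, claimed_label: str = "residue_name_number", allow_mixed: bool = True
) -> list[str]:
    """Propose pattern-conformant substrings of a failed span.

    Candidates, in priority order: the longest prefix that matches a
    pattern, then the longest internal match (leftmost on ties). So
    "Glu89H_complexB" yields ["Glu89"] and "(Arg155)" yields ["Arg155"].
    Deterministic; empty when the span contains no parseable mention.
    """
    mixed = allow_mixed and claimed_label == "mutant"
    candidates: list[str] = []
    for i in range(len(text), 0, -1):
        if _try_patterns(text[:i], mixed):
            candidates.append(text[:i])
            break
    n = len(text)
    for length in range(n, 0, -1):
        found = None
        for start in range(0, n - length + 1):
            sub = text[start : start + length]
            if sub not in candidates and _try_patterns(sub, mixed):
                found = sub
                break
        if found:
            candidates.append(found)
            break
    return candidates


def _repaired_annotation(
    ann: Annotation, candidate: str, mention: ParsedMention
) -> Annotation:
    offset = ann.exact.find(candidate)
    lead, trail = ann.exact[:offset], ann.exact[offset + len(candidate) :]
    return replace(
        ann,
        exact=candidate,
        char_start=ann.char_start + offset,
        char_end=ann.char_start + offset + len(candidate),
        prefix=(ann.prefix + lead)[-CONTEXT_CHARS:],
        postfix=(trail + ann.postfix)[:CONTEXT_CHARS],
        annotator="post_processing",
        mention=mention,
    )


def postprocess_annotations(
    annotations: list[Annotation], allow_mixed: bool = True
) -> list[Annotation]:
    """Apply pattern validation, span repair and relabelling.

    Residue/mutant annotations that parse keep their span; spans that
    fail are shrunk to the best repair candidate (context windows
    adjusted accordingly) or dropped when unrepairable. When the matched
    pattern contradicts the claimed type, the label is rewritten, the
    annotator set to "post_processing" and the confidence replaced by
    the "removed" sentinel. Idempotent: a second pass is a no-op.
    """
    out: list[Annotation] = []
    for ann in annotations:
        if ann.type not in ("residue_name_number", "mutant"):
            out.append(ann)
            continue
        mention = parse_mention(ann.exact, ann.type, allow_mixed)
        if mention is None:
            repaired = None
            for candidate in repair_span(ann.exact, ann.type, allow_mixed):
                mention = parse_mention(candidate, ann.type, allow_mixed)
                if mention is not None:
                    repaired = _repaired_annotation(ann, candidate, mention)
                    logger.info(
                        "repaired span %r -> %r (sid %d)",
                        ann.exact,
                        candidate,
                        ann.sid,
                    )
                    break
            if repaired is None:
                logger.info(
                    "dropped unresolvable %s span %r (sid %d)",
                    ann.type,
                    ann.exact,
                    ann.sid,
                )
                continue
            ann = repaired
        else:
            ann = replace(ann, mention=mention)
        if mention.label != ann.type:
            logger.info(
                "relabelled %r from %s to %s (sid %d)",
                ann.exact,
                ann.type,
                mention.label,
                ann.sid,
            )
            ann = replace(
                ann, type=mention.label, annotator="post_processing", ai_score=REMOVED
            )
        out.append(ann)
    return out
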