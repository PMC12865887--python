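"""SemEval-style NER scoring.

Predicted standoff spans are scored against gold spans under the four
classic matching schemes: *strict* (boundaries and label must both
match), *exact* (boundaries only), *partial* (exact boundaries count
fully, any overlap counts half), and *type* (label must match on an
overlapping span). Each scheme classifies outcomes as COR (correct),
INC (incorrect), PAR (partial), MIS (missed gold) and SPU (spurious
prediction), from which

    possible  = COR + INC + PAR + MIS
    actual    = COR + INC + PAR + SPU
    precision = (COR + 0.5 * PAR) / actual
    recall    = (COR + 0.5 * PAR) / possible
    F1        = 2 * P * R / (P + R)        (0 when P + R == 0)

Gold/pred pairing is one-to-one and greedy by overlap length within a
sentence (leftmost wins ties); unpaired gold spans are MIS, unpaired
predictions SPU, in every scheme. Results are broken down per entity
type, with micro (pooled counts, the default) and macro (mean over
types) averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError
from .harvest import Annotation

SCHEMES = ("strict", "exact", "partial", "type")
COUNT_KEYS = ("COR", "INC", "PAR", "MIS", "SPU")


@dataclass(frozen=True)
class Span:
    """One standoff span for evaluation."""

    sid: int
    char_start: int
    char_end: int
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.char_start < self.char_end):
            raise ValueError(f"invalid span bounds [{self.char_start},{self.char_end})")

    def overlap(self, other: "Span") -> int:
        if self.sid != other.sid:
            return 0
        return max(
            0, min(self.char_end, other.char_end) - max(self.char_start, other.char_start)
        )


def annotations_to_spans(annotations: list[Annotation]) -> list[Span]:
    return [
        Span(sid=a.sid, char_start=a.char_start, char_end=a.char_end, label=a.type)
        for a in annotations
    ]


@dataclass
class MatchCounts:
    COR: int = 0
    INC: int = 0
    PAR: int = 0
    MIS: int = 0
    SPU: int = 0

    @property
    def possible(self) -> int:
        return self.COR + self.INC + self.PAR + self.MIS

    @property
    def actual(self) -> int:
        return self.COR + self.INC + self.PAR + self.SPU

    def add(self, other: "MatchCounts") -> None:
        for key in COUNT_KEYS:
            setattr(self, key, getattr(self, key) + getattr(other, key))


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float


@dataclass
class EvaluationResult:
    """Per-scheme counts, overall and by entity type."""

    overall: dict[str, MatchCounts]
    by_type: dict[str, dict[str, MatchCounts]] = field(default_factory=dict)


def _check_no_overlaps(spans: list[Span], name: str) -> None:
    by_sid: dict[int, list[Span]] = {}
    for span in spans:
        by_sid.setdefault(span.sid, []).append(span)
    for sid, group in by_sid.items():
        group = sorted(group, key=lambda s: (s.char_start, s.char_end))
        for a, b in zip(group, group[1:]):
            if b.char_start < a.char_end:
                raise InputError(
                    f"{name} spans overlap within sentence {sid}: {a} vs {b}"
                )


def pair_spans(gold: list[Span], pred: list[Span]) -> list[tuple[Span, Span]]:
    """Greedy one-to-one pairing by maximal overlap, leftmost tie-break."""
    candidates = []
    for gi, g in enumerate(gold):
        for pi, p in enumerate(pred):
            ov = g.overlap(p)
            if ov > 0:
                candidates.append((-ov, g.char_start + p.char_start,
                                   g.char_start, p.char_start, gi, pi))
    candidates.sort()
    used_g: set[int] = set()
    used_p: set[int] = set()
    pairs: list[tuple[Span, Span]] = []
    for _, _, _, _, gi, pi in candidates:
        if gi in used_g or pi in used_p:
            continue
        used_g.add(gi)
        used_p.add(pi)
        pairs.append((gold[gi], pred[pi]))
    return pairs


def _classify(g: Span, p: Span, scheme: str) -> str:
    boundaries = g.char_start == p.char_start and g.char_end == p.char_end
    labels = g.label == p.label
    if scheme == "strict":
        return "COR" if boundaries and labels else "INC"
    if scheme == "exact":
        return "COR" if boundaries else "INC"
    if scheme == "partial":
        return "COR" if boundaries else "PAR"
    if scheme == "type":
        return "COR" if labels else "INC"
    raise ValueError(f"unknown scheme {scheme!r}")


def match(gold: list[Span], pred: list[Span]) -> EvaluationResult:
    """Count COR/INC/PAR/MIS/SPU under every scheme.

    Preconditions: neither span set overlaps internally within a
    sentence (raises :class:`InputError` otherwise). Per-type counts
    attribute each pair to the gold label and each spurious prediction
    to its own label.
    """
    _check_no_overlaps(gold, "gold")
    _check_no_overlaps(pred, "pred")
    pairs = pair_spans(gold, pred)
    paired_g = {id(g) for g, _ in pairs}
    paired_p = {id(p) for _, p in pairs}

    result = EvaluationResult(overall={s: MatchCounts() for s in SCHEMES})

    def bump(scheme: str, outcome: str, label: str) -> None:
        counts = result.overall[scheme]
        setattr(counts, outcome, getattr(counts, outcome) + 1)
        per = result.by_type.setdefault(label, {s: MatchCounts() for s in SCHEMES})
        setattr(per[scheme], outcome, getattr(per[scheme], outcome) + 1)

    for g, p in pairs:
        for scheme in SCHEMES:
            bump(scheme, _classify(g, p, scheme), g.label)
    for g in gold:
        if id(g) not in paired_g:
            for scheme in SCHEMES:
                bump(scheme, "MIS", g.label)
    for p in pred:
        if id(p) not in paired_p:
            for scheme in SCHEMES:
                bump(scheme, "SPU", p.label)
    return result


def metrics(counts: MatchCounts) -> Metrics:
    """Precision/recall/F1 from one scheme's counts (zero-safe)."""
    num = counts.COR + 0.5 * counts.PAR
    precision = num / counts.actual if counts.actual else 0.0
    recall = num / counts.possible if counts.possible else 0.0
    f1 = harmonic_f1(precision, recall)
    return Metrics(precision=precision, recall=recall, f1=f1)


def harmonic_f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def round_half_up(value: float, digits: int = 2) -> float:
    """Presentation rounding, half away from zero, as in printed tables."""
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def evaluate(
    gold: list[Span], pred: list[Span], average: str = "micro"
) -> dict[str, Metrics]:
    """Per-scheme metrics, micro- (pooled) or macro-averaged over types."""
    result = match(gold, pred)
    if average == "micro":
        return {scheme: metrics(result.overall[scheme]) for scheme in SCHEMES}
    if average == "macro":
        out = {}
        for scheme in SCHEMES:
            per = [metrics(c[scheme]) for c in result.by_type.values()]
            n = len(per)
            if n == 0:
                out[scheme] = Metrics(0.0, 0.0, 0.0)
            else:
                out[scheme] = Metrics(
                    precision=sum(m.precision for m in per) / n,
                    recall=sum(m.recall for m in per) / n,
                    f1=sum(m.f1 for m in per) / n,
                )
        return out
    raise ValueError(f"unknown averaging mode {average!r}")


# ---------------------------------------------------------------------------
# TSV standoff interchange (sid <TAB> start <TAB> end <TAB> label)


def spans_to_tsv(spans: list[Span]) -> str:
    lines = [f"{s.sid}\t{s.char_start}\t{s.char_end}\t{s.label}" for s in spans]
    return "\n".join(lines) + ("\n" if lines else "")


def spans_from_tsv(text: str) -> list[Span]:
    spans = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise InputError(f"TSV line {lineno}: expected 4 tab-separated fields")
        sid, start, end, label = parts
        spans.append(Span(int(sid), int(start), int(end), label))
    return spans
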