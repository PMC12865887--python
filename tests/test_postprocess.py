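"""Mention parsing, span repair and relabelling."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from residuelink import postprocess
from residuelink.harvest import Annotation
from residuelink.postprocess import (
    ParsedMention,
    parse_mention,
    postprocess_annotations,
    repair_span,
)


class TestParseMention:
    @pytest.mark.parametrize(
        "text,claimed,kind,wt,num,mut",
        [
            ("Arg155", "residue_name_number", "residue", "Arg", 155, None),
            ("R155A", "mutant", "mutant", "Arg", 155, "Ala"),
            ("Arg155Ala", "mutant", "mutant", "Arg", 155, "Ala"),
            ("Arg155", "mutant", "residue", "Arg", 155, None),  # relabel signal
            ("Phe 34", "residue_name_number", "residue", "Phe", 34, None),
            ("ARG155", "residue_name_number", "residue", "Arg", 155, None),
            ("GLU89ALA", "mutant", "mutant", "Glu", 89, "Ala"),
            ("R155A", "residue_name_number", "mutant", "Arg", 155, "Ala"),
            ("Arg155A", "mutant", "mutant", "Arg", 155, "Ala"),  # mixed notation
        ],
    )
    def test_successful_parses(self, text, claimed, kind, wt, num, mut):
        mention = parse_mention(text, claimed)
        assert mention is not None
        assert (mention.kind, mention.wt_aa3, mention.seq_num, mention.mut_aa3) == (
            kind, wt, num, mut,
        )

    @pytest.mark.parametrize(
        "text,claimed",
        [
            ("pET", "mutant"),
            ("Glu89H", "residue_name_number"),  # stray chain label
            ("Arg155A", "residue_name_number"),  # mixed only under a mutant claim
            ("Sec100", "residue_name_number"),  # non-standard residue
            ("Arg0", "residue_name_number"),  # positions are 1-based
            ("arg155", "residue_name_number"),  # lowercase never matches
            ("BRIL", "mutant"),
            ("Arg155123456", "residue_name_number"),  # number over 5 digits
        ],
    )
    def test_failures(self, text, claimed):
        assert parse_mention(text, claimed) is None

    def test_normalized_forms(self):
        assert parse_mention("R155A", "mutant").normalized == "Arg155Ala"
        assert parse_mention("Phe 34", "residue_name_number").normalized == "Phe34"

    def test_mixed_notation_configurable_off(self):
        assert parse_mention("Arg155A", "mutant", allow_mixed=False) is None

    def test_unsupported_label_rejected(self):
        with pytest.raises(ValueError):
            parse_mention("Arg155", "protein")


class TestRepairSpan:
    @pytest.mark.parametrize(
        "text,claimed,expected_first",
        [
            ("Glu89H_complexB", "residue_name_number", "Glu89"),
            ("Glu89H", "residue_name_number", "Glu89"),
            ("(Arg155)", "residue_name_number", "Arg155"),
            ("Arg155A", "residue_name_number", "Arg155"),
            ("Arg155;", "residue_name_number", "Arg155"),
        ],
    )
    def test_best_candidate(self, text, claimed, expected_first):
        candidates = repair_span(text, claimed)
        assert candidates and candidates[0] == expected_first

    def test_unrepairable_returns_empty(self):
        assert repair_span("pET", "mutant") == []

    @pytest.mark.parametrize("text", ["Glu89H_complexB", "(Arg155)", "xxArg155yy1"])
    def test_internal_candidate_agrees_with_substring_enumeration(self, text):
        candidates = repair_span(text, "residue_name_number")
        matching = [
            text[i:j]
            for i in range(len(text))
            for j in range(i + 1, len(text) + 1)
            if parse_mention(text[i:j], "residue_name_number") is not None
        ]
        longest = max(len(s) for s in matching)
        # every returned candidate parses, and the set includes a longest one
        assert all(parse_mention(c, "residue_name_number") for c in candidates)
        assert any(len(c) == longest for c in candidates)


def make_annotation(exact, label, sid=1, char_start=10, prefix="the residue ",
                    postfix=" is critical", ai_score=0.97):
    return Annotation(
        sid=sid,
        exact=exact,
        position=f"{sid}.3",
        prefix=prefix[-30:],
        postfix=postfix[:30],
        type=label,
        ai_score=ai_score,
        char_start=char_start,
        char_end=char_start + len(exact),
    )


class TestPostprocessAnnotations:
    def test_relabel_sets_postprocessing_annotator_and_removed_score(self):
        ann = make_annotation("R155A", "residue_name_number")
        [out] = postprocess_annotations([ann])
        assert out.type == "mutant"
        assert out.annotator == "post_processing"
        assert out.ai_score == "removed"
        assert out.mention == ParsedMention("mutant", "Arg", 155, "Ala")

    def test_unresolvable_span_dropped(self):
        ann = make_annotation("pET", "mutant")
        assert postprocess_annotations([ann]) == []

    def test_other_entity_types_pass_through(self):
        ann = Annotation(
            sid=1, exact="hNaa60", position="1.2", prefix="", postfix="",
            type="protein", ai_score=0.99, char_start=4, char_end=10,
        )
        assert postprocess_annotations([ann]) == [ann]

    def test_repair_shrinks_span_and_shifts_context(self):
        sentence = "In the preceding text Glu89H_complexB stabilises the dimer."
        start = sentence.index("Glu89H_complexB")
        ann = Annotation(
            sid=2, exact="Glu89H_complexB", position="2.4",
            prefix=sentence[max(0, start - 30) : start],
            postfix=sentence[start + 15 : start + 45],
            type="residue_name_number", ai_score=0.9989,
            char_start=start, char_end=start + 15,
        )
        [out] = postprocess_annotations([ann])
        assert out.exact == "Glu89"
        assert out.char_end == start + 5
        assert out.annotator == "post_processing"
        assert out.postfix == sentence[start + 5 : start + 35]
        assert out.prefix + out.exact + out.postfix in sentence

    def test_internal_repair_extends_prefix(self):
        sentence = "The pair (Arg155) anchors the loop near the active site."
        start = sentence.index("(Arg155)")
        ann = Annotation(
            sid=1, exact="(Arg155)", position="1.3",
            prefix=sentence[:start], postfix=sentence[start + 8 : start + 38],
            type="residue_name_number", ai_score=0.8,
            char_start=start, char_end=start + 8,
        )
        [out] = postprocess_annotations([ann])
        assert out.exact == "Arg155"
        assert out.char_start == start + 1
        assert out.prefix.endswith("(")
        assert out.prefix + out.exact + out.postfix in sentence

    @given(
        st.lists(
            st.sampled_from(
                [
                    ("Arg155", "residue_name_number"),
                    ("R155A", "mutant"),
                    ("Arg155", "mutant"),
                    ("Glu89H_complexB", "residue_name_number"),
                    ("pET", "mutant"),
                    ("hNaa60", "protein"),
                ]
            ),
            max_size=6,
        )
    )
    def test_idempotent(self, specs):
        anns = [make_annotation(t, l) for t, l in specs
                if l != "protein"] + [
            Annotation(sid=9, exact=t, position="9.1", prefix="", postfix="",
                       type=l, ai_score=0.5, char_start=0, char_end=len(t))
            for t, l in specs if l == "protein"
        ]
        once = postprocess_annotations(anns)
        twice = postprocess_annotations(once)
        assert once == twice

    def test_surviving_mentions_satisfy_invariants(self):
        anns = [
            make_annotation("Arg155", "residue_name_number"),
            make_annotation("R155A", "mutant"),
            make_annotation("Glu89H", "residue_name_number"),
        ]
        for out in postprocess_annotations(anns):
            mention = out.mention
            assert mention is not None
            assert mention.label == out.type
            assert (mention.kind == "mutant") == (mention.mut_aa3 is not None)
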