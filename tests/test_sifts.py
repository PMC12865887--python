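"""SIFTS parsing and mention-to-residue resolution."""

import pytest
from lxml import etree

from residuelink import sifts
from residuelink.errors import ParseError
from residuelink.postprocess import ParsedMention


def build_sifts(chains, pdb_id="1abc", uniprot_acc="P12345", offset=5,
                with_uniprot=True):
    """chains: {chain_id: [(author_num, three_letter, uni_three_or_None), ...]}"""
    entry = etree.Element("entry", attrib={"dbAccessionId": pdb_id})
    for chain_id, residues in chains.items():
        entity = etree.SubElement(entry, "entity",
                                  attrib={"type": "protein", "entityId": chain_id})
        seg = etree.SubElement(entity, "segment", attrib={"segId": f"{pdb_id}_{chain_id}_1"})
        lst = etree.SubElement(seg, "listResidue")
        for seq, (auth, name, uni_name) in enumerate(residues, start=1):
            res = etree.SubElement(
                lst, "residue",
                attrib={"dbSource": "PDBe", "dbResNum": str(seq),
                        "dbResName": name.upper()},
            )
            etree.SubElement(
                res, "crossRefDb",
                attrib={"dbSource": "PDB", "dbAccessionId": pdb_id,
                        "dbResNum": str(auth), "dbResName": name.upper(),
                        "dbChainId": chain_id},
            )
            if with_uniprot and uni_name is not None:
                etree.SubElement(
                    res, "crossRefDb",
                    attrib={"dbSource": "UniProt", "dbAccessionId": uniprot_acc,
                            "dbResNum": str(auth + offset), "dbResName": uni_name},
                )
    return etree.tostring(entry)


AA50 = ["Ala", "Gly", "Ser", "Thr", "Val"] * 10


class TestParseSifts:
    def test_fifty_residues_with_known_offset(self):
        xml = build_sifts({"A": [(i, AA50[i - 1], AA50[i - 1]) for i in range(1, 51)]})
        records = sifts.parse_sifts(xml)
        assert len(records) == 50
        assert all(r.uniprot_res_number == r.pdb_res_number + 5 for r in records)
        assert all(r.pdb_res_seq == i for i, r in enumerate(records, start=1))
        assert records[0].pdb_id == "1abc"

    def test_one_letter_uniprot_names_canonicalised(self):
        xml = build_sifts({"A": [(1, "Arg", "R")]})
        [record] = sifts.parse_sifts(xml)
        assert record.uniprot_res_name == "Arg"

    def test_residue_without_uniprot_crossref_has_absent_fields(self):
        xml = build_sifts({"A": [(1, "Arg", None)]})
        [record] = sifts.parse_sifts(xml)
        assert record.uniprot_acc is None
        assert record.uniprot_res_number is None

    def test_empty_entity_yields_no_records(self):
        assert sifts.parse_sifts(b'<entry dbAccessionId="1abc"><entity entityId="A"/></entry>') == []

    def test_unmapped_author_number_skipped_with_warning(self, caplog):
        xml = build_sifts({"A": [(1, "Arg", "R")]}).replace(
            b'dbSource="PDB" dbAccessionId="1abc" dbResNum="1"',
            b'dbSource="PDB" dbAccessionId="1abc" dbResNum="null"',
        )
        with caplog.at_level("WARNING"):
            assert sifts.parse_sifts(xml) == []
        assert "no author number" in caplog.text

    def test_malformed_xml_raises(self):
        with pytest.raises(ParseError):
            sifts.parse_sifts(b"<entry><entity>")

    def test_insertion_codes_parsed(self):
        xml = build_sifts({"A": [("100A", "Arg", None)]})
        [record] = sifts.parse_sifts(xml)
        assert (record.pdb_res_number, record.pdb_res_icode) == (100, "A")


def residue(chain, auth, name, uni_num=None, uni_name=None, icode="", seq=None):
    return sifts.SiftsResidue(
        pdb_id="1abc", chain=chain, struct_asym=chain,
        pdb_res_number=auth, pdb_res_icode=icode,
        pdb_res_seq=seq if seq is not None else max(auth, 1),
        pdb_res_name=name,
        uniprot_acc="P12345" if uni_num is not None else None,
        uniprot_res_number=uni_num,
        uniprot_res_name=uni_name,
    )


class TestResolveMention:
    ARG155 = ParsedMention("residue", "Arg", 155)

    def test_author_scheme_hit(self):
        hits = sifts.resolve_mention(self.ARG155, [residue("A", 155, "Arg")])
        assert [(r.chain, scheme) for r, scheme in hits] == [("A", "pdb")]

    def test_uniprot_scheme_fallback_when_author_numbering_shifted(self):
        shifted = [residue("A", 150, "Arg", uni_num=155, uni_name="Arg")]
        hits = sifts.resolve_mention(self.ARG155, shifted)
        assert [(r.pdb_res_number, scheme) for r, scheme in hits] == [(150, "uniprot")]

    def test_name_mismatch_in_both_schemes_is_empty(self):
        rows = [residue("A", 155, "Lys", uni_num=155, uni_name="Lys")]
        assert sifts.resolve_mention(self.ARG155, rows) == []

    def test_mutant_structure_matches_substituted_residue(self):
        mention = ParsedMention("mutant", "Arg", 155, "Ala")
        hits = sifts.resolve_mention(mention, [residue("A", 155, "Ala")])
        assert len(hits) == 1 and hits[0][1] == "pdb"

    def test_pdb_scheme_priority_suppresses_uniprot_hits(self):
        rows = [
            residue("A", 155, "Arg"),  # author hit
            residue("B", 150, "Arg", uni_num=155, uni_name="Arg"),  # uniprot hit
        ]
        hits = sifts.resolve_mention(self.ARG155, rows)
        assert {scheme for _, scheme in hits} == {"pdb"}

    def test_scheme_priority_is_configurable(self):
        rows = [
            residue("A", 155, "Arg"),
            residue("B", 150, "Arg", uni_num=155, uni_name="Arg"),
        ]
        hits = sifts.resolve_mention(self.ARG155, rows,
                                     scheme_priority=("uniprot", "pdb"))
        assert {scheme for _, scheme in hits} == {"uniprot"}

    def test_insertion_code_positions_never_match(self):
        assert sifts.resolve_mention(self.ARG155, [residue("A", 155, "Arg", icode="B")]) == []

    def test_duplicate_chain_positions_deduplicated(self):
        rows = [residue("A", 155, "Arg", seq=1), residue("A", 155, "Arg", seq=1)]
        assert len(sifts.resolve_mention(self.ARG155, rows)) == 1

    def test_agrees_with_brute_force_scan(self):
        rows = [
            residue("A", n, name, uni_num=n + 5, uni_name=name)
            for n, name in enumerate(AA50, start=1)
        ]
        for mention in (ParsedMention("residue", "Ser", 3),
                        ParsedMention("residue", "Ala", 6),
                        ParsedMention("residue", "Trp", 9)):
            expected_pdb = {
                (r.chain, r.pdb_res_number)
                for r in rows
                if r.pdb_res_number == mention.seq_num
                and r.pdb_res_name == mention.wt_aa3
            }
            expected_uni = {
                (r.chain, r.pdb_res_number)
                for r in rows
                if r.uniprot_res_number == mention.seq_num
                and r.uniprot_res_name == mention.wt_aa3
            }
            expected = expected_pdb or expected_uni
            got = {(r.chain, r.pdb_res_number)
                   for r, _ in sifts.resolve_mention(mention, rows)}
            assert got == expected

    def test_all_hits_share_one_scheme(self, default_bundle):
        rows = sifts.parse_sifts(default_bundle.sifts_xml[default_bundle.pdb_id])
        for gold in default_bundle.gold:
            mention = ParsedMention(
                "residue" if gold.label == "residue_name_number" else "mutant",
                gold.normalized[:3],
                int("".join(ch for ch in gold.normalized if ch.isdigit())),
                gold.normalized[-3:] if gold.label == "mutant" else None,
            )
            hits = sifts.resolve_mention(mention, rows)
            assert len({scheme for _, scheme in hits}) <= 1


class FakeQuality:
    ramachandran = "Favoured"
    rotamer = "m-80"
    phi_raw = "-60.0"
    psi_raw = "-45.0"
    clashes = [{"atom": "CB", "magnitude": "0.5"}]
    altconf = ""
    rscc_raw = "0.97"
    q_score_raw = "0.71"
    distances = [{"atom": "CA", "viol": "0.4"}]
    angles = []


class TestBuildTags:
    def hit(self):
        return [(residue("A", 155, "Arg", uni_num=160, uni_name="Arg"), "pdb")]

    def lookup(self, *args):
        return FakeQuality()

    def test_xray_tag_has_rscc_and_no_q_score(self):
        [tag] = sifts.build_tags(ParsedMention("residue", "Arg", 155), self.hit(),
                                 self.lookup, "xray", {"P12345": "HUMAN"})
        assert tag["rscc"] == "0.97"
        assert "q_score" not in tag
        assert tag["pdb_res"] == "Arg155"
        assert tag["pdb_res"] == tag["pdb_res_name"] + tag["pdb_res_number"]
        assert tag["uniprot_uri"].endswith(tag["uniprot_id"])
        assert tag["uniprot_name"] == "P12345_HUMAN"
        assert tag["uniprot_res"] == "Arg160"
        assert tag["wildtype_pdb_res"] == ""

    def test_em_tag_has_q_score_only(self):
        [tag] = sifts.build_tags(ParsedMention("residue", "Arg", 155), self.hit(),
                                 self.lookup, "em")
        assert tag["q_score"] == "0.71"
        assert "rscc" not in tag

    def test_nmr_tag_has_violation_lists(self):
        [tag] = sifts.build_tags(ParsedMention("residue", "Arg", 155), self.hit(),
                                 self.lookup, "nmr")
        assert tag["distances"] == [{"atom": "CA", "viol": "0.4"}]
        assert tag["angles"] == []
        assert "rscc" not in tag and "q_score" not in tag

    def test_mutant_records_wildtype(self):
        mention = ParsedMention("mutant", "Arg", 155, "Ala")
        [(res, scheme)] = [(residue("A", 155, "Ala"), "pdb")]
        [tag] = sifts.build_tags(mention, [(res, scheme)], self.lookup, "xray")
        assert tag["wildtype_pdb_res"] == "Arg155"

    def test_missing_quality_leaves_fields_empty(self):
        [tag] = sifts.build_tags(ParsedMention("residue", "Arg", 155), self.hit(),
                                 lambda *a: None, "xray")
        assert tag["ramachandran"] == "" and tag["rscc"] == "" and tag["clashes"] == []

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            sifts.build_tags(ParsedMention("residue", "Arg", 155), [], self.lookup,
                             "cryoem")
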