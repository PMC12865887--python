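"""SIFTS residue-level mapping and mention-to-structure resolution.

A SIFTS per-entry XML file lists, residue by residue, the dual numbering
of a structure: the author-assigned PDB residue number (what a paper
usually quotes, possibly offset, negative, or carrying an insertion
code) and the position in the UniProt reference sequence. A mention like
``Arg155`` resolves to a structure residue when the quoted number and
amino acid agree with either numbering scheme; author numbering is tried
first and, when it yields any hit, UniProt-scheme hits are not added.
For point mutations the deposited structure may carry either the
wild-type or the substituted residue at the position, so both names are
accepted under the author scheme; the UniProt reference sequence always
carries the wild type.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from lxml import etree

from . import aa
from .errors import ParseError
from .postprocess import ParsedMention

logger = logging.getLogger(__name__)

UNIPROT_URI_PREFIX = "https://www.uniprot.org/uniprotkb/"

_AUTH_NUM_RE = re.compile(r"^(-?[0-9]+)([A-Za-z]?)$")


@dataclass(frozen=True)
class SiftsResidue:
    """One residue's dual numbering (author PDB scheme + UniProt)."""

    pdb_id: str
    chain: str  # author chain id
    struct_asym: str  # internal chain id (entity id)
    pdb_res_number: int  # author-assigned number
    pdb_res_icode: str  # insertion code, "" when absent
    pdb_res_seq: int  # 1-based index from the first modelled residue
    pdb_res_name: str  # canonical three-letter code
    uniprot_acc: str | None = None
    uniprot_res_number: int | None = None
    uniprot_res_name: str | None = None

    def __post_init__(self) -> None:
        uniprot = (self.uniprot_acc, self.uniprot_res_number, self.uniprot_res_name)
        if any(v is None for v in uniprot) and any(v is not None for v in uniprot):
            raise ValueError("uniprot fields must be all present or all absent")
        if self.pdb_res_seq < 1:
            raise ValueError("pdb_res_seq is 1-based")


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname if isinstance(el.tag, str) else ""


def _residue_name(raw: str | None) -> str | None:
    if not raw:
        return None
    if len(raw) == 1:
        three = aa.ONE_TO_THREE.get(raw.upper())
    else:
        three = aa.canonical_three(raw) or aa.canonical_three(raw.upper().capitalize())
    return three


def parse_sifts(xml_bytes: bytes) -> list[SiftsResidue]:
    """Parse a SIFTS per-entry XML file into residue records.

    One record per ``<residue>`` element, in file order. Residues whose
    PDB cross-reference is missing or unmapped ("null" author number)
    are skipped with a warning; residues without a UniProt
    cross-reference are kept with absent UniProt fields.
    """
    try:
        root = etree.fromstring(xml_bytes)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed SIFTS XML: {exc}") from exc
    pdb_id = (root.get("dbAccessionId") or "").lower()
    records: list[SiftsResidue] = []
    for entity in root.iter():
        if _local(entity) != "entity":
            continue
        struct_asym = entity.get("entityId") or ""
        for residue in entity.iter():
            if _local(residue) != "residue":
                continue
            res_seq_raw = residue.get("dbResNum")
            pdb_ref = None
            uni_ref = None
            for ref in residue:
                if _local(ref) != "crossRefDb":
                    continue
                source = ref.get("dbSource")
                if source == "PDB":
                    pdb_ref = ref
                elif source == "UniProt":
                    uni_ref = ref
            if pdb_ref is None:
                logger.warning(
                    "SIFTS residue %s in %s/%s lacks a PDB cross-reference; skipped",
                    res_seq_raw,
                    pdb_id,
                    struct_asym,
                )
                continue
            auth_raw = pdb_ref.get("dbResNum") or "null"
            m = _AUTH_NUM_RE.match(auth_raw)
            if auth_raw.lower() == "null" or not m:
                logger.warning(
                    "SIFTS residue %s in %s/%s has no author number; skipped",
                    res_seq_raw,
                    pdb_id,
                    struct_asym,
                )
                continue
            name = _residue_name(pdb_ref.get("dbResName"))
            if name is None or res_seq_raw is None:
                logger.warning(
                    "SIFTS residue %s in %s/%s is non-standard; skipped",
                    res_seq_raw,
                    pdb_id,
                    struct_asym,
                )
                continue
            uni_fields: dict = {}
            if uni_ref is not None:
                uni_name = _residue_name(uni_ref.get("dbResName"))
                uni_num = uni_ref.get("dbResNum")
                if uni_name and uni_num:
                    uni_fields = dict(
                        uniprot_acc=uni_ref.get("dbAccessionId"),
                        uniprot_res_number=int(uni_num),
                        uniprot_res_name=uni_name,
                    )
            records.append(
                SiftsResidue(
                    pdb_id=pdb_id,
                    chain=pdb_ref.get("dbChainId") or struct_asym,
                    struct_asym=struct_asym,
                    pdb_res_number=int(m.group(1)),
                    pdb_res_icode=m.group(2),
                    pdb_res_seq=int(res_seq_raw),
                    pdb_res_name=name,
                    **uni_fields,
                )
            )
    return records


def resolve_mention(
    mention: ParsedMention,
    sifts_residues: list[SiftsResidue],
    scheme_priority: tuple[str, ...] = ("pdb", "uniprot"),
) -> list[tuple[SiftsResidue, str]]:
    """Find every structure residue a mention can refer to.

    Under the ``pdb`` scheme the author residue number must equal the
    quoted position (blank insertion code only — written mentions never
    carry icodes) and the structure residue name must equal the
    wild-type (or, for mutations, the substituted) amino acid. Under the
    ``uniprot`` scheme the UniProt position and wild-type name must
    agree. Schemes are tried in priority order and the first scheme with
    any hit wins, so one result never mixes numbering schemes. Residues
    are deduplicated on (chain, author number) across models/segments.
    An empty list — no link established — is a valid outcome.
    """
    accepted_names = {mention.wt_aa3}
    if mention.mut_aa3:
        accepted_names.add(mention.mut_aa3)
    by_scheme: dict[str, list[SiftsResidue]] = {"pdb": [], "uniprot": []}
    seen: dict[str, set] = {"pdb": set(), "uniprot": set()}
    for res in sifts_residues:
        if (
            res.pdb_res_number == mention.seq_num
            and res.pdb_res_icode == ""
            and res.pdb_res_name in accepted_names
        ):
            key = (res.chain, res.pdb_res_number)
            if key not in seen["pdb"]:
                seen["pdb"].add(key)
                by_scheme["pdb"].append(res)
        if (
            res.uniprot_res_number == mention.seq_num
            and res.uniprot_res_name == mention.wt_aa3
        ):
            key = (res.chain, res.pdb_res_number)
            if key not in seen["uniprot"]:
                seen["uniprot"].add(key)
                by_scheme["uniprot"].append(res)
    for scheme in scheme_priority:
        if by_scheme.get(scheme):
            others = [s for s in by_scheme if s != scheme and by_scheme[s]]
            if others:
                logger.info(
                    "mention %s resolves under %s; ignoring %s-scheme hits",
                    mention.normalized,
                    scheme,
                    "/".join(others),
                )
            return [(res, scheme) for res in by_scheme[scheme]]
    return []


def build_tags(
    mention: ParsedMention,
    hits: list[tuple[SiftsResidue, str]],
    quality_lookup,
    method: str,
    species_mnemonics: dict[str, str] | None = None,
) -> list[dict]:
    """Assemble one structure tag per resolved residue.

    ``quality_lookup`` maps (pdb_id, chain, author number, icode) to a
    :class:`~residuelink.validation.ResidueQuality`-like object (or
    returns None); missing quality leaves the metric fields empty. The
    method-specific field group — ``rscc`` for X-ray, ``q_score`` for
    cryo-EM, ``distances``/``angles`` for NMR — is chosen by ``method``.
    """
    if method not in ("xray", "em", "nmr"):
        raise ValueError(f"unknown experimental method {method!r}")
    mnemonics = species_mnemonics or {}
    tags: list[dict] = []
    for res, scheme in hits:
        quality = quality_lookup(res.pdb_id, res.chain, res.pdb_res_number,
                                 res.pdb_res_icode)
        if quality is None:
            logger.info(
                "no validation record for %s %s/%s%s",
                res.pdb_id,
                res.chain,
                res.pdb_res_number,
                res.pdb_res_icode,
            )
        tag = {
            "pdb_id": res.pdb_id,
            "pdb_res_name": res.pdb_res_name,
            "pdb_res_number": str(res.pdb_res_number) + res.pdb_res_icode,
            "pdb_res_seq": res.pdb_res_seq,
            "pdb_res": f"{res.pdb_res_name}{res.pdb_res_number}{res.pdb_res_icode}",
            "pdb_chain": res.chain,
            "numbering_scheme": scheme,
            "ramachandran": quality.ramachandran if quality else "",
            "rotamer": quality.rotamer if quality else "",
            "phi": quality.phi_raw if quality else "",
            "psi": quality.psi_raw if quality else "",
            "clashes": list(quality.clashes) if quality else [],
            "altconf": quality.altconf if quality else "",
            "wildtype_pdb_res": (
                f"{mention.wt_aa3}{res.pdb_res_number}{res.pdb_res_icode}"
                if mention.kind == "mutant"
                else ""
            ),
        }
        if res.uniprot_acc is not None:
            mnemonic = mnemonics.get(res.uniprot_acc)
            tag.update(
                uniprot_id=res.uniprot_acc,
                uniprot_name=(
                    f"{res.uniprot_acc}_{mnemonic}" if mnemonic else res.uniprot_acc
                ),
                uniprot_res=f"{res.uniprot_res_name}{res.uniprot_res_number}",
                uniprot_uri=UNIPROT_URI_PREFIX + res.uniprot_acc,
            )
        else:
            tag.update(uniprot_id="", uniprot_name="", uniprot_res="", uniprot_uri="")
        if method == "xray":
            tag["rscc"] = quality.rscc_raw if quality else ""
        elif method == "em":
            tag["q_score"] = quality.q_score_raw if quality else ""
        else:
            tag["distances"] = list(quality.distances) if quality else []
            tag["angles"] = list(quality.angles) if quality else []
        tags.append(tag)
    return tags
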