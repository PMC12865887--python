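"""Synthetic article + structure bundles with planted ground truth.

Every stage of the pipeline reads a standard format — JATS full text,
SIFTS residue mapping XML, wwPDB validation XML — for which no small
public test corpus exists. This module generates coherent synthetic
triplets: an article whose sentences mention residues and point
mutations, a structure whose chains actually contain those residues
under author and UniProt numbering (with a configurable offset between
the two), and a validation report with a quality record for every
mapped residue. The generator also emits the gold standard: every
planted mention with its span, label, normalised form, and the
numbering scheme under which it must resolve ("pdb", "uniprot", or
"none" for mentions quoting a numbering matching neither resource).

Amino-acid identities are consistent across the three files by
construction, so with the rule-based tagger and no unmatchable
mentions the end-to-end pipeline must recover the gold exactly.
Everything is deterministic for a seed.
"""

from __future__ import annotations

import json
import random
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

from lxml import etree

from . import aa
from .errors import FixtureSpecError

XLINK_NS = "http://www.w3.org/1999/xlink"

#: sentence templates carrying exactly one mention slot
MENTION_TEMPLATES: tuple[str, ...] = (
    "Mutation of {m} abolished substrate binding in all complexes.",
    "{m} forms a salt bridge with the neighbouring subunit.",
    "The side chain of {m} points into the hydrophobic core.",
    "Density for {m} was well resolved in the final map.",
    "Catalysis depends on the protonation state of {m}.",
    "A hydrogen bond anchors {m} to the backbone of the loop.",
    "Substituting {m} reduced thermal stability of the dimer.",
    "The conserved {m} coordinates the catalytic metal ion.",
)

#: filler sentences with no taggable content
FILLER_SENTENCES: tuple[str, ...] = (
    "The overall fold resembles that of related enzymes.",
    "Crystals grew within two weeks at room temperature.",
    "Data were collected at a synchrotron beamline.",
    "The refined model shows good stereochemistry throughout.",
    "The dimer interface buries a large surface area.",
    "Purification yielded a monodisperse sample.",
    "The loop adopts a closed conformation upon ligand binding.",
    "Sequence conservation across homologues is high in this region.",
)

_AA_LIST = sorted(aa.THREE_TO_ONE)

_RAMA_CLASSES = ("Favoured", "Favoured", "Favoured", "Allowed", "OUTLIER")
_ROTAMERS = ("m-80", "t80", "p90", "m-170", "OUTLIER")


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic bundle."""

    seed: int = 0
    n_sentences: int = 40
    mention_rate: float = 0.5
    mutant_fraction: float = 0.3
    spaced_fraction: float = 0.2
    n_chains: int = 2
    chain_length: int = 120
    uniprot_offset: int = 10
    unmatchable_fraction: float = 0.0
    uniprot_numbered_fraction: float = 0.2
    method: str = "xray"  # xray | em | nmr
    licence: str = "open"  # open | closed
    sentences_per_paragraph: int = 4

    def __post_init__(self) -> None:
        for name in (
            "mention_rate",
            "mutant_fraction",
            "spaced_fraction",
            "unmatchable_fraction",
            "uniprot_numbered_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise FixtureSpecError(f"{name} must be in [0, 1], got {value}")
        if self.method not in ("xray", "em", "nmr"):
            raise FixtureSpecError(f"unknown method {self.method!r}")
        if self.licence not in ("open", "closed"):
            raise FixtureSpecError(f"licence must be open or closed")
        if self.n_sentences < 1 or self.n_chains < 1:
            raise FixtureSpecError("n_sentences and n_chains must be >= 1")
        if self.chain_length < 10:
            raise FixtureSpecError("chain_length must be >= 10")
        if self.uniprot_offset < 0:
            raise FixtureSpecError("uniprot_offset must be >= 0")


@dataclass(frozen=True)
class GoldMention:
    """One planted mention and its expected pipeline outcome."""

    sid: int
    char_start: int
    char_end: int
    text: str
    label: str  # residue_name_number | mutant
    normalized: str
    expected_scheme: str  # pdb | uniprot | none
    chain: str
    author_number: int | None


@dataclass
class FixtureBundle:
    """A coherent (article, SIFTS, validation, lookup, gold) bundle."""

    spec: FixtureSpec
    pdb_id: str
    uniprot_acc: str
    jats_xml: bytes
    sifts_xml: dict[str, bytes]
    validation_xml: dict[str, bytes]
    lookup: dict
    gold: list[GoldMention] = field(default_factory=list)


def _make_pdb_id(rng: random.Random) -> str:
    # digit + three lowercase alphanumerics, avoiding an amino-acid spelling
    while True:
        candidate = rng.choice("123456789") + "".join(
            rng.choices(string.ascii_lowercase + string.digits, k=3)
        )
        if aa.canonical_three(candidate[1:].capitalize()) is None:
            return candidate


def _plan_counts(spec: FixtureSpec) -> tuple[int, int, int]:
    n_mentions = round(spec.mention_rate * spec.n_sentences)
    n_unmatchable = round(spec.unmatchable_fraction * n_mentions)
    n_uniprot = round(spec.uniprot_numbered_fraction * (n_mentions - n_unmatchable))
    if spec.uniprot_offset == 0:
        n_uniprot = 0  # the two schemes coincide; author numbering wins
    return n_mentions, n_unmatchable, n_uniprot


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Generate one bundle; byte-identical for identical specs."""
    rng = random.Random(spec.seed)
    n_mentions, n_unmatchable, n_uniprot = _plan_counts(spec)
    if n_mentions > spec.n_sentences:
        raise FixtureSpecError("more mentions than sentences")
    chains = [string.ascii_uppercase[i % 26] for i in range(spec.n_chains)]
    # UniProt-scheme mentions need a quoted number beyond the author range
    # so that only the reference numbering can resolve them
    uniprot_slots = spec.uniprot_offset * spec.n_chains
    if n_uniprot > uniprot_slots:
        raise FixtureSpecError(
            f"{n_uniprot} UniProt-numbered mentions need at least that many "
            f"positions in the top uniprot_offset rows of the chains "
            f"({uniprot_slots} available)"
        )

    pdb_id = _make_pdb_id(rng)
    uniprot_acc = f"P{rng.randint(10000, 99999)}"

    # structure content: per chain, the deposited residue names (author
    # numbering 1..chain_length) and the reference-sequence names
    pdb_names = {c: [rng.choice(_AA_LIST) for _ in range(spec.chain_length)] for c in chains}
    uni_names = {c: list(pdb_names[c]) for c in chains}

    # choose planted (chain, author position) slots, all distinct
    low_slots = [
        (c, p)
        for c in chains
        for p in range(1, spec.chain_length - spec.uniprot_offset + 1)
    ]
    high_slots = [
        (c, p)
        for c in chains
        for p in range(spec.chain_length - spec.uniprot_offset + 1, spec.chain_length + 1)
    ]
    rng.shuffle(low_slots)
    rng.shuffle(high_slots)
    n_linkable = n_mentions - n_unmatchable
    if n_linkable - n_uniprot > len(low_slots) or n_unmatchable > len(low_slots):
        raise FixtureSpecError("chains too short for the requested mention count")

    mention_sids = sorted(rng.sample(range(1, spec.n_sentences + 1), n_mentions))
    plans = []  # (sid, scheme, chain, pos)
    uni_taken = 0
    low_iter = iter(low_slots)
    scheme_tags = (
        ["none"] * n_unmatchable + ["uniprot"] * n_uniprot + ["pdb"] * (n_linkable - n_uniprot)
    )
    rng.shuffle(scheme_tags)
    for sid, scheme in zip(mention_sids, scheme_tags):
        if scheme == "uniprot":
            chain, pos = high_slots[uni_taken]
            uni_taken += 1
        else:
            chain, pos = next(low_iter)
        plans.append((sid, scheme, chain, pos))

    # realise each mention and patch the structure accordingly
    gold: list[GoldMention] = []
    sentences: dict[int, tuple[str, GoldMention | None]] = {}
    for sid, scheme, chain, pos in plans:
        is_mutant = rng.random() < spec.mutant_fraction
        wt = pdb_names[chain][pos - 1]
        mut = None
        if is_mutant:
            mut = rng.choice([a for a in _AA_LIST if a != wt])
            if scheme != "none":
                # deposited structure carries the substitution; the
                # reference sequence keeps the wild type
                pdb_names[chain][pos - 1] = mut
                uni_names[chain][pos - 1] = wt
        if scheme == "pdb":
            quoted = pos
        elif scheme == "uniprot":
            quoted = pos + spec.uniprot_offset
        else:
            quoted = spec.chain_length + spec.uniprot_offset + 100 + rng.randint(1, 400)
        if is_mutant:
            if rng.random() < 0.5:
                text = f"{aa.THREE_TO_ONE[wt]}{quoted}{aa.THREE_TO_ONE[mut]}"
            else:
                text = f"{wt}{quoted}{mut}"
            label = "mutant"
            normalized = f"{wt}{quoted}{mut}"
        else:
            spaced = rng.random() < spec.spaced_fraction
            text = f"{wt} {quoted}" if spaced else f"{wt}{quoted}"
            label = "residue_name_number"
            normalized = f"{wt}{quoted}"
        template = rng.choice(MENTION_TEMPLATES)
        start = template.index("{m}")
        sentence = template.replace("{m}", text)
        mention = GoldMention(
            sid=sid,
            char_start=start,
            char_end=start + len(text),
            text=text,
            label=label,
            normalized=normalized,
            expected_scheme=scheme,
            chain=chain,
            author_number=pos if scheme != "none" else None,
        )
        gold.append(mention)
        sentences[sid] = (sentence, mention)

    # a pdb-scheme mention must never be shadowed by an accidental
    # identical residue name: that is harmless (extra hits in other
    # chains share the scheme), but a uniprot-scheme quoted number never
    # exists in author numbering by construction (quoted > chain_length)

    for sid in range(1, spec.n_sentences + 1):
        if sid not in sentences:
            sentences[sid] = (FILLER_SENTENCES[(sid + spec.seed) % len(FILLER_SENTENCES)], None)

    ordered = [sentences[sid][0] for sid in range(1, spec.n_sentences + 1)]
    jats_xml = _write_jats(spec, pdb_id, ordered)
    sifts_xml = _write_sifts(spec, pdb_id, uniprot_acc, chains, pdb_names, uni_names)
    validation_xml = _write_validation(spec, pdb_id, chains, pdb_names, rng)
    doi = f"10.9999/synthetic.{spec.seed}"
    lookup = {
        "articles": {
            doi: {
                "pmid": str(30000000 + spec.seed),
                "pmcid": f"PMC{7000000 + spec.seed}",
                "licence": spec.licence,
            }
        },
        "structures": {
            pdb_id: {
                "uniprot_accessions": [uniprot_acc],
                "organism_names": ["Homo sapiens"],
                "taxonomy_ids": ["9606"],
            }
        },
        "species_mnemonics": {uniprot_acc: "HUMAN"},
    }
    return FixtureBundle(
        spec=spec,
        pdb_id=pdb_id,
        uniprot_acc=uniprot_acc,
        jats_xml=jats_xml,
        sifts_xml={pdb_id: sifts_xml},
        validation_xml={pdb_id: validation_xml},
        lookup=lookup,
        gold=gold,
    )


# ---------------------------------------------------------------------------
# writers


def _write_jats(spec: FixtureSpec, pdb_id: str, sentences: list[str]) -> bytes:
    nsmap = {"xlink": XLINK_NS}
    article = etree.Element("article", nsmap=nsmap)
    front = etree.SubElement(article, "front")
    meta = etree.SubElement(front, "article-meta")
    doi = etree.SubElement(meta, "article-id", attrib={"pub-id-type": "doi"})
    doi.text = f"10.9999/synthetic.{spec.seed}"
    permissions = etree.SubElement(meta, "permissions")
    ltype = "open-access" if spec.licence == "open" else "proprietary"
    etree.SubElement(permissions, "license", attrib={"license-type": ltype})
    body = etree.SubElement(article, "body")
    sec = etree.SubElement(body, "sec")
    title = etree.SubElement(sec, "title")
    title.text = "Results"
    for i in range(0, len(sentences), spec.sentences_per_paragraph):
        p = etree.SubElement(sec, "p")
        p.text = " ".join(sentences[i : i + spec.sentences_per_paragraph])
    dep = etree.SubElement(sec, "p")
    dep.text = "Coordinates were deposited as PDB entry "
    link = etree.SubElement(
        dep,
        "ext-link",
        attrib={
            "ext-link-type": "pdb",
            f"{{{XLINK_NS}}}href": f"https://www.ebi.ac.uk/pdbe/entry/pdb/{pdb_id}",
        },
    )
    link.text = pdb_id
    link.tail = "."
    return etree.tostring(article, xml_declaration=True, encoding="UTF-8")


def _write_sifts(
    spec: FixtureSpec,
    pdb_id: str,
    uniprot_acc: str,
    chains: list[str],
    pdb_names: dict[str, list[str]],
    uni_names: dict[str, list[str]],
) -> bytes:
    entry = etree.Element("entry", attrib={"dbAccessionId": pdb_id})
    for chain in chains:
        entity = etree.SubElement(
            entry, "entity", attrib={"type": "protein", "entityId": chain}
        )
        segment = etree.SubElement(
            entity,
            "segment",
            attrib={
                "segId": f"{pdb_id}_{chain}_1",
                "start": "1",
                "end": str(spec.chain_length),
            },
        )
        residues = etree.SubElement(segment, "listResidue")
        for pos in range(1, spec.chain_length + 1):
            residue = etree.SubElement(
                residues,
                "residue",
                attrib={
                    "dbSource": "PDBe",
                    "dbCoordSys": "PDBe",
                    "dbResNum": str(pos),
                    "dbResName": pdb_names[chain][pos - 1].upper(),
                },
            )
            etree.SubElement(
                residue,
                "crossRefDb",
                attrib={
                    "dbSource": "PDB",
                    "dbAccessionId": pdb_id,
                    "dbResNum": str(pos),
                    "dbResName": pdb_names[chain][pos - 1].upper(),
                    "dbChainId": chain,
                },
            )
            etree.SubElement(
                residue,
                "crossRefDb",
                attrib={
                    "dbSource": "UniProt",
                    "dbAccessionId": uniprot_acc,
                    "dbResNum": str(pos + spec.uniprot_offset),
                    "dbResName": aa.THREE_TO_ONE[uni_names[chain][pos - 1]],
                },
            )
    return etree.tostring(entry, xml_declaration=True, encoding="UTF-8")


_METHOD_LABELS = {
    "xray": "x-ray diffraction",
    "em": "electron microscopy",
    "nmr": "solution nmr",
}


def _write_validation(
    spec: FixtureSpec,
    pdb_id: str,
    chains: list[str],
    pdb_names: dict[str, list[str]],
    rng: random.Random,
) -> bytes:
    root = etree.Element("wwPDB_validation_information")
    etree.SubElement(
        root, "Entry", attrib={"pdbid": pdb_id, "method": _METHOD_LABELS[spec.method]}
    )
    for chain in chains:
        for pos in range(1, spec.chain_length + 1):
            attrib = {
                "model": "1",
                "chain": chain,
                "resnum": str(pos),
                "icode": " ",
                "resname": pdb_names[chain][pos - 1].upper(),
                "rama": rng.choice(_RAMA_CLASSES),
                "rota": rng.choice(_ROTAMERS),
                "phi": f"{rng.uniform(-180.0, 180.0):.1f}",
                "psi": f"{rng.uniform(-180.0, 180.0):.1f}",
                "altcode": " ",
            }
            if spec.method == "xray":
                attrib["rscc"] = f"{rng.uniform(0.55, 0.99):.2f}"
            elif spec.method == "em":
                attrib["Q_score"] = f"{rng.uniform(0.3, 0.9):.2f}"
            residue = etree.SubElement(root, "ModelledSubgroup", attrib=attrib)
            if rng.random() < 0.1:
                etree.SubElement(
                    residue,
                    "clash",
                    attrib={
                        "atom": rng.choice(("CB", "CG", "OD1", "NE2")),
                        "clashmag": f"{rng.uniform(0.3, 1.2):.2f}",
                        "dist": f"{rng.uniform(1.8, 2.6):.2f}",
                    },
                )
            if spec.method == "nmr" and rng.random() < 0.15:
                etree.SubElement(
                    residue,
                    "distance_violation",
                    attrib={
                        "atom": "CA",
                        "viol": f"{rng.uniform(0.2, 1.5):.2f}",
                    },
                )
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# persistence helpers (used by the CLI)


def gold_to_json(gold: list[GoldMention]) -> bytes:
    return json.dumps([asdict(g) for g in gold], indent=2).encode("utf-8")


def gold_from_json(data: bytes) -> list[GoldMention]:
    return [GoldMention(**g) for g in json.loads(data)]


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> None:
    """Write a bundle to disk in the layout the CLI consumes."""
    out = Path(out_dir)
    (out / "sifts").mkdir(parents=True, exist_ok=True)
    (out / "validation").mkdir(parents=True, exist_ok=True)
    (out / "article.xml").write_bytes(bundle.jats_xml)
    for pdb_id, data in bundle.sifts_xml.items():
        (out / "sifts" / f"{pdb_id}.xml").write_bytes(data)
    for pdb_id, data in bundle.validation_xml.items():
        (out / "validation" / f"{pdb_id}.xml").write_bytes(data)
    (out / "lookup.json").write_text(json.dumps(bundle.lookup, indent=2))
    (out / "gold.json").write_bytes(gold_to_json(bundle.gold))
    gold_tsv = "".join(
        f"{g.sid}\t{g.char_start}\t{g.char_end}\t{g.label}\n" for g in bundle.gold
    )
    (out / "gold.tsv").write_text(gold_tsv)
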