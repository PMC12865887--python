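"""Per-residue quality metrics from wwPDB validation report XML.

The wwPDB validation report carries, per modelled residue, geometry
metrics (Ramachandran class, rotamer class, phi/psi angles, steric
clashes, alternate conformations) plus method-specific data-fit
metrics: the real-space correlation coefficient (RSCC) for X-ray
entries, the Q-score for cryo-EM entries, and restraint-violation lists
for NMR entries. This module parses the per-residue subgroup elements
into a lookup keyed by (chain, author residue number, insertion code).

Attribute names follow the public wwPDB schema
(``ModelledSubgroup``/``chain``/``resnum``/``rama``/``rota``/...) but
are configurable, so locally archived files with dialect drift remain
ingestible. Numeric fields are carried both as the printed string (for
bit-exact re-emission into annotation tags) and as parsed floats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from lxml import etree

from .errors import ParseError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AttributeMap:
    """XML attribute/element names used by the validation dialect."""

    residue_element: str = "ModelledSubgroup"
    model: str = "model"
    chain: str = "chain"
    resnum: str = "resnum"
    icode: str = "icode"
    resname: str = "resname"
    rama: str = "rama"
    rota: str = "rota"
    phi: str = "phi"
    psi: str = "psi"
    rscc: str = "rscc"
    q_score: str = "Q_score"
    altcode: str = "altcode"
    clash_element: str = "clash"
    clash_atom: str = "atom"
    clash_magnitude: str = "clashmag"
    distance_element: str = "distance_violation"
    angle_element: str = "angle_violation"
    method: str = "method"


DEFAULT_ATTRS = AttributeMap()


@dataclass
class ResidueQuality:
    """Quality metrics for one residue; absent metrics stay empty."""

    ramachandran: str = ""
    rotamer: str = ""
    phi: float | None = None
    psi: float | None = None
    phi_raw: str = ""
    psi_raw: str = ""
    clashes: list[dict] = field(default_factory=list)
    altconf: str = ""
    rscc: float | None = None
    rscc_raw: str = ""
    q_score: float | None = None
    q_score_raw: str = ""
    distances: list[dict] = field(default_factory=list)
    angles: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rscc is not None and self.q_score is not None:
            raise ValueError("at most one of rscc/q_score may be populated")
        for angle in (self.phi, self.psi):
            if angle is not None and not (-180.0 <= angle <= 180.0):
                raise ValueError(f"dihedral angle out of range: {angle}")


@dataclass
class ValidationIndex:
    """All per-residue quality records of one entry, keyed for lookup."""

    pdb_id: str
    method: str  # xray | em | nmr
    lookup: dict[tuple[str, int, str], ResidueQuality]

    def get(self, chain: str, resnum: int, icode: str = "") -> ResidueQuality | None:
        return self.lookup.get((chain, resnum, icode))


def _norm_blank(value: str | None) -> str:
    value = (value or "").strip()
    return "" if value in (".", "-") else value


_METHOD_NAMES = {
    "xray": "xray",
    "x-ray": "xray",
    "x-ray diffraction": "xray",
    "em": "em",
    "electron microscopy": "em",
    "cryo-em": "em",
    "nmr": "nmr",
    "solution nmr": "nmr",
}


def parse_validation(
    xml_bytes: bytes,
    attrs: AttributeMap = DEFAULT_ATTRS,
    method: str | None = None,
) -> ValidationIndex:
    """Parse a validation report into a :class:`ValidationIndex`.

    The experimental method is taken from ``method`` when given, else
    from the entry element's method attribute, else inferred from which
    data-fit metrics appear (RSCC -> X-ray, Q-score -> EM, restraint
    violations or neither -> NMR). For multi-model (NMR) files only
    model 1 is indexed. Duplicate residue keys: last wins, with a
    warning. Absent attributes yield empty fields — values are never
    fabricated.
    """
    try:
        root = etree.fromstring(xml_bytes)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed validation XML: {exc}") from exc

    pdb_id = ""
    declared = None
    for el in root.iter():
        tag = el.tag if isinstance(el.tag, str) else ""
        if tag == "Entry":
            pdb_id = (el.get("pdbid") or "").lower()
            declared = _METHOD_NAMES.get((el.get(attrs.method) or "").strip().lower())
            break

    lookup: dict[tuple[str, int, str], ResidueQuality] = {}
    saw_rscc = saw_q = saw_violation = False
    for el in root.iter(attrs.residue_element):
        model = (el.get(attrs.model) or "1").strip()
        if model != "1":
            continue
        chain = el.get(attrs.chain) or ""
        resnum_raw = el.get(attrs.resnum)
        if not chain or resnum_raw is None:
            logger.warning("residue element lacking chain/resnum skipped")
            continue
        icode = _norm_blank(el.get(attrs.icode))
        phi_raw = _norm_blank(el.get(attrs.phi))
        psi_raw = _norm_blank(el.get(attrs.psi))
        rscc_raw = _norm_blank(el.get(attrs.rscc))
        q_raw = _norm_blank(el.get(attrs.q_score))
        clashes = [
            {
                "atom": _norm_blank(c.get(attrs.clash_atom)),
                "magnitude": _norm_blank(c.get(attrs.clash_magnitude)),
            }
            for c in el.iter(attrs.clash_element)
        ]
        distances = [dict(c.attrib) for c in el.iter(attrs.distance_element)]
        angles = [dict(c.attrib) for c in el.iter(attrs.angle_element)]
        saw_rscc |= bool(rscc_raw)
        saw_q |= bool(q_raw)
        saw_violation |= bool(distances or angles)
        quality = ResidueQuality(
            ramachandran=_norm_blank(el.get(attrs.rama)),
            rotamer=_norm_blank(el.get(attrs.rota)),
            phi=float(phi_raw) if phi_raw else None,
            psi=float(psi_raw) if psi_raw else None,
            phi_raw=phi_raw,
            psi_raw=psi_raw,
            clashes=clashes,
            altconf=_norm_blank(el.get(attrs.altcode)),
            rscc=float(rscc_raw) if rscc_raw else None,
            rscc_raw=rscc_raw,
            q_score=float(q_raw) if q_raw else None,
            q_score_raw=q_raw,
            distances=distances,
            angles=angles,
        )
        key = (chain, int(resnum_raw), icode)
        if key in lookup:
            logger.warning("duplicate validation record for %s; last wins", key)
        lookup[key] = quality

    if method is not None:
        resolved = _METHOD_NAMES.get(method.lower())
        if resolved is None:
            raise ValueError(f"unknown experimental method {method!r}")
    elif declared is not None:
        resolved = declared
    elif saw_rscc:
        resolved = "xray"
    elif saw_q:
        resolved = "em"
    else:
        resolved = "nmr"
    return ValidationIndex(pdb_id=pdb_id, method=resolved, lookup=lookup)
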