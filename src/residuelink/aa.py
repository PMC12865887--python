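"""Amino-acid code tables.

The 20 standard proteinogenic amino acids, as a bijection between
one-letter and three-letter codes. Non-standard residues (Sec, Pyl) and
modified residues (Mse) are deliberately excluded: the mention patterns
downstream are defined over the standard alphabet only.
"""

from __future__ import annotations

#: three-letter (capitalised) -> one-letter
THREE_TO_ONE: dict[str, str] = {
    "Ala": "A",
    "Arg": "R",
    "Asn": "N",
    "Asp": "D",
    "Cys": "C",
    "Gln": "Q",
    "Glu": "E",
    "Gly": "G",
    "His": "H",
    "Ile": "I",
    "Leu": "L",
    "Lys": "K",
    "Met": "M",
    "Phe": "F",
    "Pro": "P",
    "Ser": "S",
    "Thr": "T",
    "Trp": "W",
    "Tyr": "Y",
    "Val": "V",
}

#: one-letter -> three-letter (capitalised)
ONE_TO_THREE: dict[str, str] = {one: three for three, one in THREE_TO_ONE.items()}

#: all accepted three-letter spellings (capitalised and all-caps) -> canonical
_CANONICAL: dict[str, str] = {}
for _three in THREE_TO_ONE:
    _CANONICAL[_three] = _three
    _CANONICAL[_three.upper()] = _three


def canonical_three(code: str) -> str | None:
    """Canonicalise a three-letter code ("ARG" or "Arg" -> "Arg").

    Returns None for anything outside the 20 standard residues; matching
    is deliberately case-sensitive beyond the two accepted spellings, so
    ordinary words like "his" never canonicalise.
    """
    return _CANONICAL.get(code)


def is_one_letter(code: str) -> bool:
    """True if ``code`` is an upper-case standard one-letter residue code."""
    return code in ONE_TO_THREE


#: regex alternation fragment matching a three-letter code (Arg or ARG)
THREE_LETTER_ALT = "|".join(
    sorted({c for t in THREE_TO_ONE for c in (t, t.upper())}, reverse=True)
)

#: regex character class fragment for the 20 one-letter codes
ONE_LETTER_CLASS = "".join(sorted(ONE_TO_THREE))
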