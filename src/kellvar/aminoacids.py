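"""Amino-acid code tables shared across the package."""

from __future__ import annotations

THREE_TO_ONE: dict[str, str] = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA: frozenset[str] = frozenset(ONE_TO_THREE)


def to_one_letter(aa: str) -> str:
    """Normalize a residue name (one- or three-letter) to one-letter code.

    Raises ``KeyError`` for non-standard residues.
    """
    aa = aa.strip()
    if len(aa) == 1:
        code = aa.upper()
        if code not in STANDARD_AA:
            raise KeyError(f"unknown amino acid {aa!r}")
        return code
    code = aa.capitalize()
    if code not in THREE_TO_ONE:
        raise KeyError(f"unknown amino acid {aa!r}")
    return THREE_TO_ONE[code]


def to_three_letter(aa: str) -> str:
    return ONE_TO_THREE[to_one_letter(aa)]
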