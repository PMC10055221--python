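"""Canonical amino-acid alphabet shared by every probability table.

The 20 one-letter codes in fixed alphabetical order. Every serialized
probability vector uses this order, and it is recorded in table headers so
files are self-describing.
"""

from __future__ import annotations

CANONICAL_AA: str = "ACDEFGHIKLMNPQRSTVWY"

AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(CANONICAL_AA)}

N_AA: int = len(CANONICAL_AA)

#: Letters accepted in input sequences; sites with "X" are excluded from
#: training and evaluation but do not fail parsing.
SEQUENCE_LETTERS: frozenset[str] = frozenset(CANONICAL_AA) | {"X"}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}


def aa_index(aa: str) -> int:
    """Index of a one-letter code in the canonical order.

    Raises KeyError for anything outside the 20 canonical letters.
    """
    return AA_TO_INDEX[aa]
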