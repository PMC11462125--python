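"""IUPAC nucleotide codes: base sets, bitmasks, complements and union codes.

Shared vocabulary for every module that compares or merges bases. Inosine
('I', found in some degenerate PCR primers) is treated as matching any base;
it is legal in primer sequences only, never in templates or reads.
"""

from __future__ import annotations

import numpy as np

#: IUPAC code -> set of plain bases it stands for.
CODE_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Codes legal in templates, reads and reference sequences.
DNA_CODES = frozenset(CODE_TO_BASES)
#: Codes legal in primers (IUPAC plus inosine).
PRIMER_CODES = DNA_CODES | {"I"}
#: Two-base ambiguity codes ("wobbles"); N and three-base codes excluded.
WOBBLE_CODES = frozenset("RYSWKM")

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

#: IUPAC code -> 4-bit mask (A=1, C=2, G=4, T=8). 'I' behaves like N.
CODE_TO_MASK: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in CODE_TO_BASES.items()
}
CODE_TO_MASK["I"] = 15

#: 4-bit mask -> IUPAC code, for building union (consensus) codes.
MASK_TO_CODE: dict[int, str] = {CODE_TO_MASK[c]: c for c in CODE_TO_BASES}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N", "I": "I",
}

# uint8-indexed mask table for vectorised primer scans
_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _c, _m in CODE_TO_MASK.items():
    _MASK_TABLE[ord(_c)] = _m


def mask(code: str) -> int:
    """4-bit base-set mask for one IUPAC (or inosine) code."""
    try:
        return CODE_TO_MASK[code]
    except KeyError:
        raise ValueError(f"invalid nucleotide code {code!r}") from None


def compatible(a: str, b: str) -> bool:
    """True iff the base sets of the two codes intersect."""
    return bool(mask(a) & mask(b))


def union_code(a: str, b: str) -> str:
    """IUPAC code covering the union of two codes' base sets ('I' -> N)."""
    return MASK_TO_CODE[mask(a) | mask(b)]


def complement(code: str) -> str:
    try:
        return _COMPLEMENT[code]
    except KeyError:
        raise ValueError(f"invalid nucleotide code {code!r}") from None


def revcomp(seq: str) -> str:
    """Reverse complement, preserving ambiguity codes."""
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def mask_array(seq: str) -> np.ndarray:
    """uint8 array of 4-bit masks for a sequence (0 for invalid characters)."""
    return _MASK_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def validate(seq: str, alphabet: frozenset[str] = DNA_CODES, what: str = "sequence") -> str:
    """Return seq unchanged, or raise ValueError naming the first bad character."""
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"invalid character {sorted(bad)[0]!r} in {what}")
    return seq


def count_wobble_codes(seq: str) -> int:
    return sum(1 for c in seq if c in WOBBLE_CODES)
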