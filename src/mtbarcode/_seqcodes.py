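"""Shared nucleotide alphabet tables and integer encodings.

Bases are encoded 0..3 (A, C, G, T), IUPAC ambiguity codes 4..14, and
gap/missing characters ('-', '?', '.') as -1.  All distance and likelihood
machinery works on these integer arrays.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

#: IUPAC nucleotide codes mapped to the set of unambiguous bases they cover.
IUPAC_NUC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

GAP_CHARS = "-?."

# Deterministic code assignment: 0..3 bases, then ambiguity codes.
_AMBIG_ORDER = ["R", "Y", "S", "W", "K", "M", "B", "D", "H", "V", "N"]
CODE_OF: dict[str, int] = {b: i for i, b in enumerate(BASES)}
CODE_OF.update({c: 4 + i for i, c in enumerate(_AMBIG_ORDER)})
CODE_OF["U"] = CODE_OF["T"]
for g in GAP_CHARS:
    CODE_OF[g] = -1

#: For every non-negative code, the tuple of base codes it may resolve to.
RESOLUTIONS: tuple[tuple[int, ...], ...] = tuple(
    tuple(CODE_OF[b] for b in IUPAC_NUC[ch])
    for ch, code in sorted(
        ((c, v) for c, v in CODE_OF.items() if v >= 0 and c != "U"),
        key=lambda kv: kv[1],
    )
)

#: Base-set (as frozenset of base codes) -> IUPAC character.
IUPAC_OF_SET: dict[frozenset[int], str] = {
    frozenset(CODE_OF[b] for b in bases): ch
    for ch, bases in IUPAC_NUC.items()
    if ch != "U"
}

_LUT = np.full(256, -2, dtype=np.int8)
for ch, code in CODE_OF.items():
    _LUT[ord(ch)] = code
    _LUT[ord(ch.lower())] = code

#: True for codes whose base is a purine (A or G); transitions stay within
#: purines or within pyrimidines.
IS_PURINE = np.array([True, False, True, False])

#: Vertebrate mitochondrial stop codons.
MITO_STOPS = {"TAA", "TAG", "AGA", "AGG"}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into an int8 array of alphabet codes.

    Raises ``ValueError`` on characters outside the IUPAC + gap alphabet.
    """
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == -2).any():
        bad = sorted({seq[i] for i in np.nonzero(arr == -2)[0][:5]})
        raise ValueError(f"non-IUPAC characters in sequence: {bad}")
    return arr


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (ambiguity codes render as their IUPAC letter)."""
    inv = {v: k for k, v in CODE_OF.items() if k not in "U" + GAP_CHARS}
    inv[-1] = "-"
    return "".join(inv[int(c)] for c in codes)


def encode_matrix(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) int8 matrix."""
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences must be equal length")
    return np.vstack([encode(s) for s in seqs])


def is_transition(x: int, y: int) -> bool:
    """True when base codes x, y differ but are both purines or both pyrimidines."""
    return x != y and IS_PURINE[x] == IS_PURINE[y]
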