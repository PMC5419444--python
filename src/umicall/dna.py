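"""Small shared DNA utilities: IUPAC codes, complements, bit encoding.

Bases are encoded as bit flags (A=1, C=2, G=4, T=8) so that an IUPAC
ambiguity code matches a concrete base iff ``code_bits & base_bits != 0``.
"""

from __future__ import annotations

import numpy as np

IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
}

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# lookup tables indexed by ASCII byte value
_BITS_TABLE = np.zeros(256, dtype=np.uint8)
for _b, _v in IUPAC_BITS.items():
    _BITS_TABLE[ord(_b)] = _v
    _BITS_TABLE[ord(_b.lower())] = _v

_IDX_TABLE = np.full(256, 4, dtype=np.uint8)  # 4 == not A/C/G/T
for _b, _i in BASE_INDEX.items():
    _IDX_TABLE[ord(_b)] = _i
    _IDX_TABLE[ord(_b.lower())] = _i

_COMP_TRANS = str.maketrans(
    "".join(_COMPLEMENT) + "".join(_COMPLEMENT).lower(),
    "".join(_COMPLEMENT.values()) + "".join(_COMPLEMENT.values()).lower(),
)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMP_TRANS)[::-1]


def seq_to_bits(seq: str) -> np.ndarray:
    """Encode a sequence as an array of IUPAC bit flags (uint8)."""
    return _BITS_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def seq_to_index(seq: str) -> np.ndarray:
    """Encode a sequence as 0..3 for A/C/G/T, 4 for anything else."""
    return _IDX_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def is_iupac(seq: str) -> bool:
    return all(c.upper() in IUPAC_BITS for c in seq)


def phred_to_string(quals, cap: int = 93) -> str:
    """Phred integer scores -> Phred+33 ASCII."""
    return "".join(chr(33 + min(int(q), cap)) for q in quals)


def string_to_phred(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8).astype(np.int32) - 33
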