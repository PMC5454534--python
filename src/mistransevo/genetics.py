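"""Shared nucleotide/amino-acid encodings and the standard genetic code.

Sequences are held as numpy uint8 arrays with A,C,G,T -> 0..3, '-' -> 4,
'N' -> 5.  Codons are indexed as 16*b0 + 4*b1 + b2 and translated through a
precomputed 64-entry lookup built from Biopython's standard codon table.
Amino acids are indexed alphabetically (ACDEFGHIKLMNPQRSTVWY -> 0..19) with
20 reserved for the stop signal.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
GAP_CODE = 4
N_CODE = 5
AAS = "ACDEFGHIKLMNPQRSTVWY"
STOP_AA = 20
N_AA = 20

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("-")] = GAP_CODE

_DECODE = np.frombuffer(b"ACGT-N", dtype=np.uint8)

AA_INDEX = {aa: i for i, aa in enumerate(AAS)}


def _build_codon_table() -> np.ndarray:
    table = CodonTable.unambiguous_dna_by_id[1]
    out = np.full(64, STOP_AA, dtype=np.uint8)
    for codon, aa in table.forward_table.items():
        idx = 16 * BASES.index(codon[0]) + 4 * BASES.index(codon[1]) + BASES.index(codon[2])
        out[idx] = AA_INDEX[aa]
    # stop codons keep STOP_AA
    return out


CODON_AA = _build_codon_table()


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string (ACGT-N, case-insensitive) to uint8 codes."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def codon_indices(codes: np.ndarray) -> np.ndarray:
    """Codon lookup indices for an in-frame coding sequence (no gaps/N)."""
    codes = np.asarray(codes, dtype=np.int64)
    if codes.shape[-1] % 3:
        raise ValueError("sequence length not divisible by 3")
    tri = codes.reshape(*codes.shape[:-1], -1, 3)
    if (tri > 3).any():
        raise ValueError("cannot translate sequences containing gaps or N")
    return 16 * tri[..., 0] + 4 * tri[..., 1] + tri[..., 2]


def translate_codes(codes: np.ndarray) -> np.ndarray:
    """Translate encoded nucleotides to amino-acid indices (STOP_AA = stop)."""
    return CODON_AA[codon_indices(codes)]


def aa_letter(aa_index: int) -> str:
    return "*" if aa_index == STOP_AA else AAS[aa_index]
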