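"""Small nucleotide-string helpers used throughout the pipeline.

All sequences are uppercase strings over the alphabet {A, C, G, T, N}.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Canonical 5-letter encoding used by the vectorised matchers.  The value 5
# is reserved for padding; like N it matches nothing.
ALPHABET = "ACGTN"
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENC[ord(_b)] = _i

# Anything outside ACGTN maps to N.
_CLEAN = str.maketrans(
    {chr(c): "N" for c in range(256) if chr(c) not in set("ACGTN")}
)


def clean_sequence(seq: str) -> str:
    """Uppercase *seq* and map every non-ACGTN character to N."""
    return seq.upper().translate(_CLEAN)


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes A=0 C=1 G=2 T=3 N=4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_reads(reads: list[str], pad: int = 5) -> np.ndarray:
    """Encode a list of reads into one padded (n_reads, max_len) uint8 matrix.

    Padding uses code 5, which matches no pattern character, so matches can
    never extend past the true end of a read.
    """
    if not reads:
        return np.zeros((0, 0), dtype=np.uint8)
    width = max(len(r) for r in reads)
    out = np.full((len(reads), width), pad, dtype=np.uint8)
    for i, r in enumerate(reads):
        out[i, : len(r)] = encode(r)
    return out
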