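"""Nucleotide alphabet helpers shared across the package.

Internally sequences are handled in DNA-style uppercase with T; U is
accepted everywhere and treated as identical to T.  The integer encoding
is A=0, C=1, G=2, T/U=3, N/other ambiguity=4.
"""

from __future__ import annotations

import numpy as np

GAP_CHARS = frozenset("-.~_")
NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}

_ENCODE = np.full(256, -1, dtype=np.int8)
for _c, _i in NT_INDEX.items():
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}

# Watson-Crick plus GU wobble, on {A,C,G,T} indices
_CANONICAL_PAIRS = {(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes; raise on junk characters."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[arr]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(codes < 0)[0][:5]})
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return codes.astype(np.int8)


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT.get(c, "N") for c in reversed(seq.upper().replace("U", "T")))


def is_gap(char: str) -> bool:
    return char in GAP_CHARS


def pairs_canonically(a: str, b: str) -> bool:
    """True iff bases a,b form a Watson-Crick or GU wobble pair."""
    ia = NT_INDEX.get(a.upper().replace("U", "T"), 4)
    ib = NT_INDEX.get(b.upper().replace("U", "T"), 4)
    return (ia, ib) in _CANONICAL_PAIRS


def is_wobble(a: str, b: str) -> bool:
    ia = NT_INDEX.get(a.upper().replace("U", "T"), 4)
    ib = NT_INDEX.get(b.upper().replace("U", "T"), 4)
    return (ia, ib) in {(2, 3), (3, 2)}
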