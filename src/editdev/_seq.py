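"""Nucleotide encoding helpers shared across the package.

Sequences are held as ``uint8`` arrays with codes A=0, C=1, G=2, T=3, N=4.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4
BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _ch in enumerate(b"ACGTN"):
    _ENCODE[_ch] = _i
for _i, _ch in enumerate(b"acgtn"):
    _ENCODE[_ch] = _i
_ENCODE[ord("U")] = T
_ENCODE[ord("u")] = T

# complement in code space; N -> N
_COMP = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode an ACGTN(U) string into uint8 codes."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode("ascii")


def complement(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes]


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))
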