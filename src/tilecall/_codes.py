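"""Base-4 encoding of DNA sequences shared across the package.

Bases are coded A,C,G,T -> 0,1,2,3 so that a base triplet maps to
16*prev + 4*center + next in [0, 63] and the Watson-Crick complement
of code c is 3 - c.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}

# 256-entry lookup: ASCII byte -> base code, 255 for anything non-ACGT.
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in BASE_CODE.items():
    _LUT[ord(_b)] = _c
    _LUT[ord(_b.lower())] = _c

PROBE_LENGTH = 21
CENTER = PROBE_LENGTH // 2  # 0-based index of the central (11th) base


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 base codes (255 marks non-ACGT)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    out = np.empty(len(codes), dtype="U1")
    arr = np.asarray(codes)
    for b, c in BASE_CODE.items():
        out[arr == c] = b
    if (arr > 3).any():
        out[arr > 3] = "N"
    return "".join(out)


def complement_code(codes: np.ndarray) -> np.ndarray:
    return 3 - codes


def revcomp(seq: str) -> str:
    return decode(3 - encode(seq)[::-1])


def check_base(b: str) -> int:
    """Return the code of a single base, rejecting anything else."""
    try:
        return BASE_CODE[b.upper()]
    except (KeyError, AttributeError):
        raise ValueError(f"not a DNA base: {b!r}") from None
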