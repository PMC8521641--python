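"""Small DNA alphabet helpers shared across the pipeline.

Everything downstream of read normalization works on the strict 4-letter
alphabet {A, C, G, T}; ambiguity codes are handled (split away) at input time.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# ASCII byte -> 2-bit code; 255 marks anything outside {A,C,G,T}
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i

_BYTE = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an {A,C,G,T} string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of 2-bit codes (A=0,C=1,G=2,T=3).

    Raises ValueError if the sequence contains a character outside {A,C,G,T}.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if codes.size and codes.max() == 255:
        bad = chr(int(raw[int(np.argmax(codes == 255))]))
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _BYTE[codes].tobytes().decode("ascii")
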