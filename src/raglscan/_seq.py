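"""Small nucleotide/amino-acid sequence utilities shared across modules."""
from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans("ACGTNRYSWKMacgtnryswkm", "TGCANYRSWMKtgcanyrswmk")

# A=0, C=1, G=2, T=3; anything else (N, lowercase handled by upper()) -> 4
_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(DNA_ALPHABET):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (IUPAC-aware for common codes)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA as int8: A=0 C=1 G=2 T=3, other (N, ...) = 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[arr].tobytes().decode("ascii")


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
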