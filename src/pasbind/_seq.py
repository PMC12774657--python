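"""Low-level DNA sequence helpers shared across the package.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N, lowercase handled
upstream) maps to 4. All vectorised routines operate on int8/int64 code
matrices with one row per sequence.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
# reverse map: frozenset of bases -> IUPAC letter
IUPAC_FROM_SET = {frozenset(v): k for k, v in IUPAC.items()}

_ENCODE_LUT = np.full(256, 4, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving map)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a single sequence to an int8 code vector."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_many(reads: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences into an (n, length) int8 matrix."""
    if len(reads) == 0:
        return np.empty((0, 0), dtype=np.int8)
    length = len(reads[0])
    buf = np.frombuffer("".join(reads).encode("ascii"), dtype=np.uint8)
    if buf.size != length * len(reads):
        raise ValueError("encode_many requires equal-length sequences")
    return _ENCODE_LUT[buf].reshape(len(reads), length)


def decode(codes: np.ndarray) -> str:
    """Decode a 1-D code vector back to a string (4 -> N)."""
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.intp)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code matrix along the last axis (N stays 4)."""
    comp = np.array([3, 2, 1, 0, 4], dtype=codes.dtype)
    return comp[codes][..., ::-1]


def kmer_to_index(kmer: str) -> int:
    idx = 0
    for b in kmer:
        idx = idx * 4 + BASE_INDEX[b]
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def indices_to_kmers(indices: np.ndarray, k: int) -> list[str]:
    """Vectorised decoding of base-4 k-mer indices to strings."""
    indices = np.asarray(indices, dtype=np.int64)
    cols = np.empty((indices.size, k), dtype=np.int8)
    rem = indices.copy()
    for j in range(k - 1, -1, -1):
        cols[:, j] = rem % 4
        rem //= 4
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    flat = lut[cols.astype(np.intp)].tobytes().decode("ascii")
    return [flat[i * k:(i + 1) * k] for i in range(indices.size)]


def expand_iupac(pattern: str, limit: int = 10**7) -> list[str]:
    """Expand an IUPAC pattern to all concrete sequences.

    Raises ValueError when the expansion would exceed `limit` sequences,
    advising chunked scoring instead.
    """
    pattern = pattern.upper()
    choices = []
    n = 1
    for ch in pattern:
        if ch not in IUPAC:
            raise ValueError(f"not an IUPAC code: {ch!r}")
        opts = IUPAC[ch]
        n *= len(opts)
        if n > limit:
            raise ValueError(
                f"pattern expands to more than {limit} sequences; "
                "score it in chunks (split one N into A/C/G/T sub-patterns)"
            )
        choices.append(opts)
    return ["".join(p) for p in product(*choices)]


def iupac_code(bases: Iterable[str]) -> str:
    """IUPAC letter covering a set of bases."""
    key = frozenset(b.upper() for b in bases)
    if not key:
        raise ValueError("empty base set")
    return IUPAC_FROM_SET[key]


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
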