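"""2-bit k-mer encoding and canonicalization.

K-mers over the A/C/G/T alphabet are packed into 64-bit integers, two bits
per base (A=0, C=1, G=2, T=3), most significant bits first.  This caps k at
31 and makes hashing, reverse complementation and set membership cheap
vectorized integer operations.  Windows containing any non-ACGT symbol are
dropped; callers receive both the surviving codes and the count of valid
windows so downstream statistics use the true number of queried k-mers.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

# maps ASCII byte -> 2-bit code; 255 flags an invalid symbol
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _seq_to_codes(seq: str | bytes) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _BASE_CODE[np.frombuffer(seq, dtype=np.uint8)]


def encode_kmers(seq: str | bytes, k: int) -> np.ndarray:
    """Pack every ACGT-only window of ``seq`` into a uint64 code.

    Returns the codes of the valid windows in left-to-right order; windows
    containing an ambiguous base are omitted.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    codes_per_base = _seq_to_codes(seq)
    n = codes_per_base.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    invalid = (codes_per_base == 255).astype(np.int64)
    bad = np.cumsum(invalid)
    # window [i, i+k) is clean iff the cumulative invalid count is flat
    clean = (bad[k - 1 :] - np.concatenate(([0], bad[: n - 1]))) == 0
    vals = codes_per_base.astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for i in range(k):
            out = (out << np.uint64(2)) | vals[i : i + n]
    return out[clean]


def reverse_complement_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed k-mer codes (vectorized)."""
    codes = np.asarray(codes, dtype=np.uint64)
    out = np.zeros_like(codes)
    three = np.uint64(3)
    with np.errstate(over="ignore"):
        for i in range(k):
            base = (codes >> np.uint64(2 * i)) & three
            out = (out << np.uint64(2)) | (three ^ base)
    return out


def canonicalize(codes: np.ndarray, k: int) -> np.ndarray:
    """Replace each code by min(code, revcomp(code)): strand-agnostic form."""
    rc = reverse_complement_codes(codes, k)
    return np.minimum(codes, rc)


def canonical_codes(seq: str | bytes, k: int) -> np.ndarray:
    """Canonical packed codes of every valid k-mer window of ``seq``."""
    return canonicalize(encode_kmers(seq, k), k)


def decode_kmer(code: int, k: int) -> str:
    """Unpack a uint64 code back to its ACGT string (testing aid)."""
    bases = [(int(code) >> (2 * (k - 1 - i))) & 3 for i in range(k)]
    return bytes(_CODE_BASE[bases]).decode("ascii")


def random_kmer_codes(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random k-mer codes, e.g. negative controls for FP estimation."""
    return rng.integers(0, 1 << (2 * k), size=n, dtype=np.uint64)
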