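"""Interleaved Bloom Filter (IBF): sizing math, construction and queries.

An IBF packs one Bloom filter per reference fragment ("bin") into a single
bit matrix.  The matrix has ``bits_sbf`` rows (one per possible hash value,
i.e. the size of each single-fragment Bloom filter) and one bit per bin in
each row; a row is called a *subvector*.  Inserting a k-mer of fragment i
sets bit i of the h subvectors addressed by the h hash functions.  Querying
a k-mer fetches the same h subvectors and ANDs them, yielding the *binning
bitvector*: bit i says the k-mer is (apparently) contained in fragment i.
One set of hash evaluations therefore answers membership for every bin at
once, which is what makes streaming classification against thousands of
fragments cheap.

Sizing: for a target per-filter false-positive rate p with h hash functions
and at most ``max_kmer`` insertions, the false-positive probability of a
filter of b bits is

    p = (1 - (1 - 1/b)^(h * max_kmer))^h

and solving for the smallest adequate b gives

    b = ceil( -1 / ((1 - r)^(1 / (h * max_kmer)) - 1) ),   r = p^(1/h).

Defaults: h = 3 hash functions and p = 0.01 per bin.
"""

from __future__ import annotations

import io
import math
import struct
from dataclasses import dataclass, field

import numpy as np

from .kmers import MAX_K, canonical_codes

MAGIC = b"IBF1"
FORMAT_VERSION = 1

DEFAULT_K = 13
DEFAULT_HASHES = 3
DEFAULT_FP_RATE = 0.01
DEFAULT_FRAGMENT_SIZE = 100_000
DEFAULT_OVERLAP = 500

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


def _splitmix64(x: np.ndarray | np.uint64) -> np.ndarray | np.uint64:
    # Finalizer of the splitmix64 generator: a full-avalanche 64-bit mixer.
    with np.errstate(over="ignore"):
        z = np.uint64(x) + _GOLDEN if np.isscalar(x) or x.ndim == 0 else x + _GOLDEN
        z = (z ^ (z >> np.uint64(30))) * _MIX1
        z = (z ^ (z >> np.uint64(27))) * _MIX2
        return z ^ (z >> np.uint64(31))


def default_seeds(h: int) -> tuple[int, ...]:
    """h fixed, pairwise-distinct 64-bit hash seeds.

    Derived deterministically from the splitmix64 stream so that any h yields
    the same published constants; the seeds travel inside the index file.
    """
    seeds = []
    state = np.uint64(0)
    for _ in range(h):
        with np.errstate(over="ignore"):
            state = state + _GOLDEN
        seeds.append(int(_splitmix64(state)))
    return tuple(seeds)


# ---------------------------------------------------------------------------
# sizing math


def compute_max_kmers(F: int, k: int) -> int:
    """Number of k-mer windows in a sequence of length F: F - k + 1."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if F < k:
        raise ValueError(f"fragment length {F} is shorter than k = {k}")
    return F - k + 1


def compute_single_filter_size(max_kmer: int, h: int, p: float) -> int:
    """Smallest Bloom-filter bit count keeping the FP rate at <= p.

    Evaluated in the log domain (log1p/expm1) so the result is exact even for
    filters of millions of bits where (1-r)^(1/(h*max_kmer)) is within 1e-7
    of 1.
    """
    if not 0 < p < 1:
        raise ValueError(f"false-positive rate must be in (0, 1), got {p}")
    if max_kmer < 1 or h < 1:
        raise ValueError("max_kmer and h must be >= 1")
    r = p ** (1.0 / h)
    denom = math.expm1(math.log1p(-r) / (h * max_kmer))
    return max(1, math.ceil(-1.0 / denom))


def false_positive_rate(bits_sbf: int, h: int, n_inserted: int) -> float:
    """FP probability of one bin after n_inserted k-mers."""
    if bits_sbf < 1 or h < 1 or n_inserted < 0:
        raise ValueError("bits_sbf, h must be >= 1 and n_inserted >= 0")
    if n_inserted == 0:
        return 0.0
    if bits_sbf == 1:
        return 1.0  # the only bit is set after any insertion
    # 1 - (1 - 1/b)^(h n)  computed stably for large b
    frac_set = -math.expm1(h * n_inserted * math.log1p(-1.0 / bits_sbf))
    return frac_set**h


def compute_ibf_size(n_frag: int, bits_sbf: int) -> int:
    """Total logical size in bits: one bits_sbf-sized filter per fragment."""
    if n_frag < 1:
        raise ValueError("an IBF needs at least one bin")
    if bits_sbf < 1:
        raise ValueError("bits_sbf must be >= 1")
    return n_frag * bits_sbf


# ---------------------------------------------------------------------------
# hashing


def hash_kmer(codes: np.ndarray | int, seed: int, bits_sbf: int) -> np.ndarray | int:
    """Map packed k-mer code(s) to a subvector index in [0, bits_sbf).

    Deterministic and platform-independent: a splitmix64 finalizer applied to
    code XOR seed, reduced mod bits_sbf.  Accepts a scalar or an array.
    """
    scalar = np.isscalar(codes)
    arr = np.atleast_1d(np.asarray(codes, dtype=np.uint64))
    with np.errstate(over="ignore"):
        mixed = _splitmix64(arr ^ np.uint64(seed))
    idx = mixed % np.uint64(bits_sbf)
    return int(idx[0]) if scalar else idx


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class IbfParams:
    """Index parameters; the seeds are recorded in the index file so that a
    stored index is portable across machines."""

    k: int = DEFAULT_K
    h: int = DEFAULT_HASHES
    p: float = DEFAULT_FP_RATE
    fragment_size: int = DEFAULT_FRAGMENT_SIZE
    overlap: int = DEFAULT_OVERLAP
    seeds: tuple[int, ...] = ()

    def __post_init__(self):
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {self.k}")
        if self.h < 1:
            raise ValueError(f"h must be >= 1, got {self.h}")
        if not 0 < self.p < 1:
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        if not 0 <= self.overlap < self.fragment_size:
            raise ValueError("need 0 <= overlap < fragment_size")
        if self.k > self.fragment_size:
            raise ValueError("fragment_size must be >= k")
        if not self.seeds:
            object.__setattr__(self, "seeds", default_seeds(self.h))
        if len(self.seeds) != self.h:
            raise ValueError(f"need exactly h = {self.h} seeds")
        if len(set(self.seeds)) != self.h:
            raise ValueError("hash seeds must be pairwise distinct")


@dataclass(frozen=True)
class Fragment:
    """A half-open slice [start, end) of one reference record, owning one bin."""

    reference_id: str
    start: int
    end: int
    bin_index: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class BinningVector:
    """Per-k-mer membership: bit i = k-mer present in bin i (AND of h rows)."""

    bits: np.ndarray  # bool, length n_frag


@dataclass
class CountVector:
    """Per-bin matching-k-mer counts for one read."""

    counts: np.ndarray  # int64, length n_frag
    L_queried: int  # number of valid (ACGT-only) k-mers queried


# ---------------------------------------------------------------------------
# the filter


class InterleavedBloomFilter:
    """Bit matrix of shape (bits_sbf, bin_count_padded) packed into uint64
    words, subvector-major; bin_count_padded is n_frag rounded up to a
    multiple of 64 so the h-way AND is a word-wise operation."""

    def __init__(self, params: IbfParams, fragments: list[Fragment],
                 bits_sbf: int | None = None):
        if not fragments:
            raise ValueError("an IBF needs at least one fragment")
        self.params = params
        self.fragments = list(fragments)
        self.n_frag = len(fragments)
        if bits_sbf is None:
            max_kmer = compute_max_kmers(params.fragment_size, params.k)
            bits_sbf = compute_single_filter_size(max_kmer, params.h, params.p)
        self.bits_sbf = int(bits_sbf)
        self.bin_count_padded = -(-self.n_frag // 64) * 64
        self._words_per_row = self.bin_count_padded // 64
        self.bits = np.zeros((self.bits_sbf, self._words_per_row), dtype=np.uint64)
        self._seeds = np.asarray(params.seeds, dtype=np.uint64)

    # -- size accounting
    @property
    def logical_size_bits(self) -> int:
        return compute_ibf_size(self.n_frag, self.bits_sbf)

    @property
    def physical_size_bits(self) -> int:
        return self.bits_sbf * self.bin_count_padded

    # -- construction
    def _rows(self, codes: np.ndarray) -> np.ndarray:
        """Subvector indices for each (code, seed) pair: shape (n, h)."""
        with np.errstate(over="ignore"):
            mixed = _splitmix64(codes[:, None] ^ self._seeds[None, :])
        return (mixed % np.uint64(self.bits_sbf)).astype(np.int64)

    def insert_fragment(self, codes: np.ndarray, bin_index: int) -> None:
        """Insert packed (canonical) k-mer codes into one bin."""
        if not 0 <= bin_index < self.n_frag:
            raise IndexError(f"bin_index {bin_index} out of range [0, {self.n_frag})")
        codes = np.asarray(codes, dtype=np.uint64)
        if codes.size == 0:
            return
        rows = np.unique(self._rows(codes))
        word = bin_index // 64
        mask = np.uint64(1 << (bin_index % 64))
        self.bits[rows, word] |= mask

    # -- queries
    def _binning_words(self, codes: np.ndarray) -> np.ndarray:
        """AND of the h addressed subvectors per code: (n, words) uint64."""
        rows = self._rows(codes)
        gathered = self.bits[rows]  # (n, h, words)
        out = gathered[:, 0, :]
        for j in range(1, self.params.h):
            out = out & gathered[:, j, :]
        return out

    def query_kmer(self, code: int) -> BinningVector:
        words = self._binning_words(np.asarray([code], dtype=np.uint64))
        bits = np.unpackbits(words.view(np.uint8), bitorder="little")
        return BinningVector(bits=bits[: self.n_frag].astype(bool))

    def query_kmers(self, codes: np.ndarray) -> np.ndarray:
        """Binning bitvectors for many codes: bool matrix (n, n_frag)."""
        codes = np.asarray(codes, dtype=np.uint64)
        if codes.size == 0:
            return np.zeros((0, self.n_frag), dtype=bool)
        words = self._binning_words(codes)
        bits = np.unpackbits(words.view(np.uint8), axis=1, bitorder="little")
        return bits[:, : self.n_frag].astype(bool)

    def count_matches(self, read: str | bytes) -> CountVector:
        """Per-bin count of the read's canonical k-mers found in each bin."""
        k = self.params.k
        if len(read) < k:
            raise ValueError(f"read shorter than k = {k}")
        codes = canonical_codes(read, k)
        membership = self.query_kmers(codes)
        counts = membership.sum(axis=0).astype(np.int64)
        return CountVector(counts=counts, L_queried=int(codes.size))

    # -- serialization ------------------------------------------------------
    def write(self, path) -> None:
        with open(path, "wb") as fh:
            self._write_stream(fh)

    def _write_stream(self, fh) -> None:
        p = self.params
        fh.write(MAGIC)
        fh.write(struct.pack("<H", FORMAT_VERSION))
        fh.write(struct.pack("<BBd", p.k, p.h, p.p))
        for s in p.seeds:
            fh.write(struct.pack("<Q", s))
        fh.write(struct.pack("<QQ", p.fragment_size, p.overlap))
        fh.write(struct.pack("<QQQ", self.n_frag, self.bits_sbf, self.bin_count_padded))
        for frag in self.fragments:
            name = frag.reference_id.encode("utf-8")
            fh.write(struct.pack("<H", len(name)))
            fh.write(name)
            fh.write(struct.pack("<QQ", frag.start, frag.end))
        fh.write(self.bits.astype("<u8").tobytes())

    @classmethod
    def read(cls, path) -> "InterleavedBloomFilter":
        with open(path, "rb") as fh:
            return cls._read_stream(fh)

    @classmethod
    def _read_stream(cls, fh) -> "InterleavedBloomFilter":
        def take(n: int, what: str) -> bytes:
            buf = fh.read(n)
            if len(buf) != n:
                raise IndexFormatError(f"truncated index file while reading {what}")
            return buf

        if take(4, "magic bytes") != MAGIC:
            raise IndexFormatError("not an IBF index file (bad magic bytes)")
        (version,) = struct.unpack("<H", take(2, "format version"))
        if version != FORMAT_VERSION:
            raise IndexFormatError(
                f"unsupported index format version {version} (expected {FORMAT_VERSION})"
            )
        k, h, p = struct.unpack("<BBd", take(10, "parameters"))
        seeds = tuple(
            struct.unpack("<Q", take(8, "hash seeds"))[0] for _ in range(h)
        )
        fragment_size, overlap = struct.unpack("<QQ", take(16, "fragment geometry"))
        n_frag, bits_sbf, padded = struct.unpack("<QQQ", take(24, "filter geometry"))
        fragments = []
        for i in range(n_frag):
            (name_len,) = struct.unpack("<H", take(2, "fragment table"))
            name = take(name_len, "fragment table").decode("utf-8")
            start, end = struct.unpack("<QQ", take(16, "fragment table"))
            fragments.append(Fragment(name, start, end, i))
        params = IbfParams(k=k, h=h, p=p, fragment_size=fragment_size,
                           overlap=overlap, seeds=seeds)
        ibf = cls(params, fragments, bits_sbf=bits_sbf)
        if ibf.bin_count_padded != padded:
            raise IndexFormatError("inconsistent bin padding in index header")
        n_bytes = bits_sbf * padded // 8
        raw = take(n_bytes, "bitvector")
        ibf.bits = np.frombuffer(raw, dtype="<u8").reshape(
            bits_sbf, padded // 64
        ).astype(np.uint64)
        return ibf

    def to_bytes(self) -> bytes:
        buf = io.BytesIO()
        self._write_stream(buf)
        return buf.getvalue()


class IndexFormatError(ValueError):
    """Raised for malformed, truncated or incompatible index files."""
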