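"""Reference fragmentation and index construction.

A reference genome is cut into overlapping fragments of at most
``fragment_size`` nucleotides (consecutive fragments of one record overlap by
``overlap`` nt; fragments never span records), each fragment becomes one bin
of the interleaved Bloom filter, and every fragment's canonical k-mers are
inserted into its bin.  The overlap exists so that k-mers straddling a
fragment junction still occur intact in at least one fragment — guaranteed
whenever overlap >= k - 1.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Iterator

from .ibf import Fragment, IbfParams, InterleavedBloomFilter
from .io_utils import read_sequences
from .kmers import canonical_codes, decode_kmer, encode_kmers, canonicalize

logger = logging.getLogger(__name__)


def fragment_record(name: str, length: int, fragment_size: int, overlap: int,
                    k: int, first_bin: int) -> list[Fragment]:
    """Fragments of a single record; starts advance by fragment_size - overlap.

    The last fragment is clipped at the record end; a tail shorter than k
    (possible only when overlap < k - 1) is merged into the previous fragment.
    """
    if length < k:
        raise ValueError(
            f"record '{name}' is shorter ({length} nt) than k = {k}"
        )
    step = fragment_size - overlap
    frags: list[Fragment] = []
    start = 0
    while True:
        end = min(start + fragment_size, length)
        if frags and end - start < k:
            prev = frags.pop()
            frags.append(Fragment(name, prev.start, end, prev.bin_index))
            break
        frags.append(Fragment(name, start, end, first_bin + len(frags)))
        if end == length:
            break
        start += step
    return frags


def fragment_reference(records: Iterable[tuple[str, str]] | Iterable[tuple[str, int]],
                       fragment_size: int, overlap: int, k: int = 1) -> list[Fragment]:
    """Fragment a set of (name, sequence) or (name, length) records.

    Bin indices are assigned in record order, then position order.
    """
    if not 0 <= overlap < fragment_size:
        raise ValueError("need 0 <= overlap < fragment_size")
    if overlap < k - 1:
        warnings.warn(
            f"overlap {overlap} < k - 1 = {k - 1}: k-mers spanning fragment "
            "junctions will be lost", stacklevel=2)
    frags: list[Fragment] = []
    for name, seq in records:
        length = seq if isinstance(seq, int) else len(seq)
        frags.extend(fragment_record(name, length, fragment_size, overlap, k,
                                     first_bin=len(frags)))
    return frags


def canonical_kmers(seq: str, k: int) -> Iterator[str]:
    """Yield the canonical form of every ACGT-only k-mer window, in order."""
    codes = canonicalize(encode_kmers(seq, k), k)
    for code in codes:
        yield decode_kmer(int(code), k)


def build_index(fasta_paths: Iterable, params: IbfParams | None = None,
                records: list[tuple[str, str]] | None = None) -> InterleavedBloomFilter:
    """Build a complete IBF from one or more FASTA files (or in-memory
    records).  All records are pooled into a single index."""
    params = params or IbfParams()
    if records is None:
        records = []
        for path in fasta_paths:
            records.extend(read_sequences(path))
    if not records:
        raise ValueError("no reference records to index")
    fragments = fragment_reference(records, params.fragment_size, params.overlap,
                                   k=params.k)
    ibf = InterleavedBloomFilter(params, fragments)
    seq_by_name = dict(records)
    for frag in fragments:
        codes = canonical_codes(
            seq_by_name[frag.reference_id][frag.start:frag.end], params.k)
        ibf.insert_fragment(codes, frag.bin_index)
    logger.info(
        "built IBF: %d bins, %d bits per bin (%.2f MiB physical), k=%d h=%d p=%g",
        ibf.n_frag, ibf.bits_sbf, ibf.physical_size_bits / 8 / 2**20,
        params.k, params.h, params.p)
    return ibf
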