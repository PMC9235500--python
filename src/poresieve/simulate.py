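"""Synthetic references, nanopore-like reads and a chunked streaming session.

This module replaces the sequencer: it draws random reference genomes,
simulates error-bearing reads from them (i.i.d. substitutions plus optional
insertions/deletions — a simple error channel, not a signal-level
simulator), and replays the reads as fixed-size chunks against a decision
function, applying the decisions with real-run semantics: an ``unblock``
ends the molecule after a short ejection latency, ``stop_receiving`` keeps
the full read but streams no more chunks.

Chunk geometry follows the sequencer's cadence: at ~450 nt/s a 0.4 s data
chunk carries about 180 bases, so the first classification attempt (200 nt
minimum) typically happens after two chunks, around 360 nt.

All randomness flows through one integer seed; identical seeds give
bit-identical FASTA/FASTQ output and identical decision traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

SEQUENCING_SPEED = 450   # nt per second
CHUNK_SECONDS = 0.4


@dataclass(frozen=True)
class SimulationConfig:
    bases_per_second: int = SEQUENCING_SPEED
    chunk_seconds: float = CHUNK_SECONDS
    ejection_latency: int | None = None  # nt sequenced after an unblock; default one chunk
    substitution_rate: float = 0.06
    insertion_rate: float = 0.02
    deletion_rate: float = 0.02
    median_read_length: int = 5000
    read_length_sigma: float = 0.45  # log-normal spread
    seed: int = 0

    @property
    def chunk_size(self) -> int:
        return round(self.bases_per_second * self.chunk_seconds)

    @property
    def latency(self) -> int:
        return self.chunk_size if self.ejection_latency is None else self.ejection_latency

    def __post_init__(self):
        for rate in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0 <= rate < 1:
                raise ValueError("error rates must be in [0, 1)")


def generate_reference(n_records: int, lengths, gc: float = 0.5,
                       seed: int = 0, prefix: str = "rec") -> list[tuple[str, str]]:
    """Random reference records named ``{prefix}_0 .. {prefix}_{n-1}``."""
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if np.isscalar(lengths):
        lengths = [int(lengths)] * n_records
    if len(lengths) != n_records:
        raise ValueError("need one length per record")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    for i, length in enumerate(lengths):
        seq = BASES[rng.choice(4, size=int(length), p=probs)].tobytes().decode("ascii")
        records.append((f"{prefix}_{i}", seq))
    return records


def apply_errors(seq: str, rng: np.random.Generator, substitution_rate: float,
                 insertion_rate: float = 0.0, deletion_rate: float = 0.0) -> str:
    """Push a sequence through an i.i.d. substitution/indel channel."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = arr.size
    if substitution_rate > 0:
        hit = rng.random(n) < substitution_rate
        # substitute with one of the three *other* bases
        codes = np.searchsorted(BASES, arr[hit])
        shift = rng.integers(1, 4, size=hit.sum())
        arr[hit] = BASES[(codes + shift) % 4]
    if insertion_rate == 0.0 and deletion_rate == 0.0:
        return arr.tobytes().decode("ascii")
    keep = rng.random(n) >= deletion_rate
    ins = rng.random(n) < insertion_rate
    pieces: list[bytes] = []
    ins_bases = BASES[rng.integers(0, 4, size=int(ins.sum()))]
    ins_iter = iter(ins_bases.tobytes())
    out = bytearray()
    for i in range(n):
        if ins[i]:
            out.append(next(ins_iter))
        if keep[i]:
            out.append(arr[i])
    return out.decode("ascii")


@dataclass
class SimRead:
    read_id: str
    sequence: str
    source_record: str
    strand: str
    start: int
    true_class: str  # "target" | "deplete" | "other"


_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(seq: str) -> str:
    return seq.encode("ascii").translate(_COMP)[::-1].decode("ascii")


def simulate_reads(references: list[tuple[str, str]], n_reads: int,
                   proportions: dict[str, float] | None = None,
                   class_of: dict[str, str] | None = None,
                   config: SimulationConfig = SimulationConfig(),
                   seed: int | None = None) -> list[SimRead]:
    """Draw error-bearing reads from reference records.

    ``proportions`` maps record name -> fraction of reads (default uniform);
    ``class_of`` maps record name -> truth class ("target"/"deplete"/...).
    Read lengths are log-normal around the configured median, truncated at
    the source-record length.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = [name for name, _ in references]
    seqs = dict(references)
    if proportions is None:
        probs = np.full(len(names), 1.0 / len(names))
    else:
        probs = np.array([proportions[name] for name in names], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
    class_of = class_of or {}
    picks = rng.choice(len(names), size=n_reads, p=probs)
    lengths = np.exp(rng.normal(np.log(config.median_read_length),
                                config.read_length_sigma, size=n_reads))
    reads = []
    for i in range(n_reads):
        src = names[picks[i]]
        ref = seqs[src]
        length = int(min(max(lengths[i], 1), len(ref)))
        start = int(rng.integers(0, len(ref) - length + 1))
        frag = ref[start:start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = _revcomp(frag)
        frag = apply_errors(frag, rng, config.substitution_rate,
                            config.insertion_rate, config.deletion_rate)
        reads.append(SimRead(f"read_{i}", frag, src, strand, start,
                             class_of.get(src, "other")))
    return reads


def truth_frame(reads: list[SimRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {"read_id": [r.read_id for r in reads],
         "source_record": [r.source_record for r in reads],
         "strand": [r.strand for r in reads],
         "start": [r.start for r in reads],
         "true_class": [r.true_class for r in reads],
         "read_length": [len(r.sequence) for r in reads]})


# ---------------------------------------------------------------------------
# streaming session


@dataclass
class SessionRecord:
    read_id: str
    true_class: str
    decision: str            # unblock | stop_receiving | finished
    decision_length: int     # nt accumulated when the decision fell (0 if none)
    final_length: int        # nt actually sequenced
    chunks_seen: int


class SessionError(RuntimeError):
    """A decision function raised while handling a read."""


def run_session(reads: list[SimRead], decision_fn,
                config: SimulationConfig = SimulationConfig()) -> pd.DataFrame:
    """Feed each read chunk-by-chunk to ``decision_fn`` and apply decisions.

    ``decision_fn(read_id, chunk, chunk_index) -> "wait" | "unblock" |
    "stop_receiving"``.  Returns the session log; a ``final_sequence``
    column carries what the pore actually produced (truncated for unblocked
    reads).
    """
    chunk = config.chunk_size
    rows = []
    final_seqs = []
    for read in reads:
        seq = read.sequence
        n_chunks = -(-len(seq) // chunk)
        decision, dec_len, seen = "finished", 0, 0
        for ci in range(n_chunks):
            piece = seq[ci * chunk:(ci + 1) * chunk]
            seen += 1
            try:
                action = decision_fn(read.read_id, piece, ci)
            except Exception as exc:  # noqa: BLE001 - session must name the read
                raise SessionError(
                    f"decision function failed on read {read.read_id}") from exc
            action = getattr(action, "value", action)
            if action == "wait":
                continue
            decision = action
            dec_len = min((ci + 1) * chunk, len(seq))
            break
        if decision == "unblock":
            final_len = min(dec_len + config.latency, len(seq))
        else:  # stop_receiving or ran to the end: molecule sequences fully
            final_len = len(seq)
        rows.append(SessionRecord(read.read_id, read.true_class, decision,
                                  dec_len, final_len, seen))
        final_seqs.append(seq[:final_len])
    log = pd.DataFrame([r.__dict__ for r in rows])
    log["final_sequence"] = final_seqs
    return log
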