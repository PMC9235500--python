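"""Match-threshold statistics and the streaming accept/reject decision logic.

A read of length len(r) contains L = len(r) - k + 1 k-mers.  Under an
i.i.d. per-base substitution error rate e, a k-mer is erroneous (contains at
least one miscalled base) with probability q = 1 - (1 - e)^k, so the
expected number of erroneous k-mers is E[N_err] = L q.  Because overlapping
k-mers share bases, N_err is not binomial; its variance is

    Var(N_err) = L (1-q) (q (2k + 2/e - 1) - 2k)
               + k (k-1) (1-q)^2
               + (2 (1-q) / e^2) ((1 + (k-1)(1-q)) e - q).

The classifier accepts a read as contained in a reference bin when its
matching-k-mer count reaches the lower (1-alpha) confidence bound on the
number of error-free k-mers:

    min[N_match] = L - (E[N_err] + z_alpha * sqrt(Var(N_err))),
    z_alpha = Phi^-1(1 - alpha/2).

Defaults: 95% confidence, e = 0.10, k = 13 — tuned to CPU-basecalled
nanopore reads at roughly 90% per-base accuracy.

The decision loop mirrors adaptive sampling on a nanopore sequencer: reads
arrive as ~180 nt chunks; nothing is classified below 200 nt accumulated
(so in practice the first attempt happens at ~360 nt, two chunks); a read
matching a depletion filter is ejected from the pore (``unblock``); a read
matching a target filter keeps sequencing with no further data streamed
(``stop_receiving``); an undecided read is retried chunk by chunk until a
1500 nt cap, after which it continues as a normal read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from scipy.stats import norm

from .ibf import InterleavedBloomFilter

logger = logging.getLogger(__name__)

MIN_CLASSIFY_LENGTH = 200
MAX_CLASSIFY_LENGTH = 1500

DEFAULT_ERROR_RATE = 0.10
DEFAULT_CONFIDENCE = 0.95


def expected_erroneous_kmers(L: int, k: int, e: float) -> float:
    """E[N_err] = L q with q = 1 - (1-e)^k."""
    if L < 0 or not 0 <= e < 1:
        raise ValueError("need L >= 0 and 0 <= e < 1")
    q = 1.0 - (1.0 - e) ** k
    return L * q


def erroneous_kmer_variance(L: int, k: int, e: float) -> float:
    """Variance of the erroneous-k-mer count under i.i.d. substitutions.

    Accounts for the covariance of overlapping k-mers; reduces to the
    binomial variance L e (1-e) at k = 1 and to 0 at e = 0 (the analytic
    limit).  Small negative values from floating-point cancellation are
    clamped to 0.
    """
    if not 0 <= e < 1:
        raise ValueError(f"error rate must be in [0, 1), got {e}")
    if e == 0.0:
        return 0.0
    q = 1.0 - (1.0 - e) ** k
    var = (
        L * (1.0 - q) * (q * (2.0 * k + 2.0 / e - 1.0) - 2.0 * k)
        + k * (k - 1) * (1.0 - q) ** 2
        + (2.0 * (1.0 - q) / e**2) * ((1.0 + (k - 1) * (1.0 - q)) * e - q)
    )
    return max(var, 0.0)


def z_alpha(alpha: float) -> float:
    """Two-sided standard-normal quantile Phi^-1(1 - alpha/2)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(norm.ppf(1.0 - alpha / 2.0))


def match_threshold(read_len: int, k: int, e: float, alpha: float) -> int:
    """Minimum matching k-mers for a read of read_len nt to count as present.

    Floor of L - (E[N_err] + z_alpha sqrt(Var)), clamped to [1, L]; a
    threshold below 1 would accept every read.
    """
    if read_len < k:
        raise ValueError(f"read length {read_len} shorter than k = {k}")
    L = read_len - k + 1
    return threshold_for_kmer_count(L, k, e, alpha)


def threshold_for_kmer_count(L: int, k: int, e: float, alpha: float) -> int:
    """Same threshold expressed directly in the number of queried k-mers."""
    if L < 1:
        raise ValueError("need at least one k-mer")
    mean = expected_erroneous_kmers(L, k, e)
    sd = math.sqrt(erroneous_kmer_variance(L, k, e))
    t = math.floor(L - (mean + z_alpha(alpha) * sd))
    return int(min(max(t, 1), L))


@dataclass(frozen=True)
class ThresholdModel:
    """Bundle of (k, e, alpha) with the derived threshold machinery."""

    k: int = 13
    e: float = DEFAULT_ERROR_RATE
    alpha: float = 1.0 - DEFAULT_CONFIDENCE

    @property
    def q(self) -> float:
        return 1.0 - (1.0 - self.e) ** self.k

    @property
    def z(self) -> float:
        return z_alpha(self.alpha)

    def expected_errors(self, L: int) -> float:
        return expected_erroneous_kmers(L, self.k, self.e)

    def variance(self, L: int) -> float:
        return erroneous_kmer_variance(L, self.k, self.e)

    def threshold(self, L_queried: int) -> int:
        return threshold_for_kmer_count(L_queried, self.k, self.e, self.alpha)


# ---------------------------------------------------------------------------
# classification


@dataclass
class ClassificationResult:
    read_id: str
    matched: bool
    best_bin: int | None
    best_count: int
    threshold_used: int
    L_queried: int
    filter_role: str  # "target" | "deplete"


def classify_sequence(seq: str, ibf: InterleavedBloomFilter,
                      model: ThresholdModel, read_id: str = "",
                      filter_role: str = "deplete") -> ClassificationResult:
    """Count matching k-mers per bin and compare the best bin against the
    confidence-interval threshold at the read's actual valid-k-mer count."""
    if len(seq) < ibf.params.k:
        raise ValueError(f"sequence shorter than k = {ibf.params.k}")
    cv = ibf.count_matches(seq)
    if cv.L_queried == 0:
        return ClassificationResult(read_id, False, None, 0, 1, 0, filter_role)
    thr = model.threshold(cv.L_queried)
    best_bin = int(cv.counts.argmax())  # ties -> lowest bin index
    best_count = int(cv.counts[best_bin])
    matched = best_count >= thr
    return ClassificationResult(read_id, matched, best_bin if matched else None,
                                best_count, thr, cv.L_queried, filter_role)


# ---------------------------------------------------------------------------
# streaming decisions


class Status(str, Enum):
    PENDING = "pending"
    ONCE_SEEN = "once_seen"
    UNBLOCK = "unblock"
    STOP_RECEIVING = "stop_receiving"


class Action(str, Enum):
    WAIT = "wait"
    UNBLOCK = "unblock"
    STOP_RECEIVING = "stop_receiving"


@dataclass
class ReadState:
    """A partially sequenced read accumulating chunks."""

    read_id: str
    accumulated_sequence: str = ""
    chunks_received: int = 0
    status: Status = Status.PENDING
    decision_length: int | None = None
    matched_role: str | None = None  # which filter role decided the read

    @property
    def decided(self) -> bool:
        return self.status in (Status.UNBLOCK, Status.STOP_RECEIVING)


def decide(state: ReadState, new_chunk: str,
           deplete_ibfs: Sequence[InterleavedBloomFilter] = (),
           target_ibfs: Sequence[InterleavedBloomFilter] = (),
           model: ThresholdModel | None = None,
           min_length: int = MIN_CLASSIFY_LENGTH,
           max_length: int = MAX_CLASSIFY_LENGTH) -> tuple[ReadState, Action]:
    """Advance one read by one chunk and emit the sequencer response.

    Precedence when both filter roles match: the target filter wins, so a
    read resembling both an enrichment target and a depletion reference keeps
    sequencing.  An unmatched read below the length cap stays ``once_seen``;
    at the cap it continues as a normal read — except in target-only mode
    (no depletion filter), where anything that never matched a target is
    ejected.
    """
    if state.decided:
        logger.warning("chunk received for already-decided read %s; ignored",
                       state.read_id)
        return state, Action.WAIT
    if not deplete_ibfs and not target_ibfs:
        raise ValueError("need at least one filter (deplete and/or target)")
    model = model or ThresholdModel()
    state.accumulated_sequence += new_chunk
    state.chunks_received += 1
    seq = state.accumulated_sequence
    if len(seq) < min_length:
        state.status = Status.PENDING
        return state, Action.WAIT

    target_hit = any(
        classify_sequence(seq, ibf, model, state.read_id, "target").matched
        for ibf in target_ibfs)
    deplete_hit = not target_hit and any(
        classify_sequence(seq, ibf, model, state.read_id, "deplete").matched
        for ibf in deplete_ibfs)

    if target_hit:
        state.status = Status.STOP_RECEIVING
        state.matched_role = "target"
    elif deplete_hit:
        state.status = Status.UNBLOCK
        state.matched_role = "deplete"
    elif len(seq) >= max_length:
        # give up trying: target-only mode ejects, otherwise keep the read
        state.status = Status.UNBLOCK if (target_ibfs and not deplete_ibfs) \
            else Status.STOP_RECEIVING
    else:
        state.status = Status.ONCE_SEEN
        return state, Action.WAIT

    state.decision_length = len(seq)
    return state, Action(state.status.value)
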