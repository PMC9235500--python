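# poresieve

Alignment-free read classification and an adaptive-sampling decision engine
for nanopore sequencing, built on Interleaved Bloom Filters (IBFs).

Nanopore sequencers can eject an uninteresting DNA molecule from a pore
mid-read ("unblock"), so software that classifies a read's first few
hundred bases in real time can deplete host reads or enrich low-abundance
targets in silico. The catch: the decision must be made from a short
(~360 nt), error-prone (~10% per-base error) prefix, where long-read
aligners lose sensitivity. `poresieve` instead counts shared k-mers between
the read prefix and an indexed reference, with a statistically derived
acceptance threshold, and decides unblock / keep-sequencing per read. A
built-in stream simulator stands in for the sequencer, so the whole loop
runs at desk scale.

This package is intended for people studying alignment-free adaptive
sampling: it is a faithful, testable reimplementation of the method, not a
client for live sequencer control software.

## The method

**Index.** Each reference record is cut into overlapping fragments of at
most *F* nt (default *F* = 100 000, overlap 500 ≥ *k*−1 so junction k-mers
survive). Each fragment is one *bin*: a Bloom filter holding the fragment's
canonical k-mers (*k* = 13). The bins are stored interleaved: the bit matrix
has one row ("subvector") per hash value and one bit per bin, so the *h*
hash evaluations of a k-mer address *h* subvectors whose bitwise AND is the
*binning bitvector* — membership in every bin at once. Per-bin filter size
for a target false-positive rate *p* (default 0.01, *h* = 3):

    p = (1 − (1 − 1/Bits_SBF)^(h·max_kmer))^h,      max_kmer = F − k + 1,
    Bits_SBF = ⌈ −1 / ((1 − p^(1/h))^(1/(h·max_kmer)) − 1) ⌉,
    Bits_IBF = n_frag · Bits_SBF.

**Threshold.** A read of length len(r) has L = len(r) − k + 1 k-mers. With
i.i.d. per-base error rate *e*, a k-mer is erroneous with probability
q = 1 − (1−e)^k; the erroneous-k-mer count N_err has mean E[N_err] = L·q and
a closed-form variance that accounts for overlapping k-mers sharing bases.
A read is accepted as contained in a bin when its matching-k-mer count
reaches the lower (1−α) confidence bound on error-free k-mers:

    min[N_match] = L − (E[N_err] + z_α·√Var(N_err)),   z_α = Φ⁻¹(1 − α/2),

floored and clamped to [1, L]. Defaults: e = 0.10, α = 0.05, k = 13.

**Decision loop.** Reads arrive as ~180 nt chunks (0.4 s at 450 nt/s).
Below 200 nt accumulated nothing is classified (first attempt therefore
typically at 360 nt, two chunks). A read matching a depletion index is
ejected (`unblock`); one matching a target index keeps sequencing with no
further data streamed (`stop_receiving`); an undecided read is retried
chunk by chunk up to 1500 nt, then continues as a normal read.

## Worked example

```python
from poresieve import (IbfParams, ThresholdModel, build_index, classify_sequence,
                       generate_reference, simulate_reads, SimulationConfig,
                       match_threshold)

refs = generate_reference(1, [250_000], gc=0.5, seed=42)   # synthetic genome
index = build_index([], IbfParams(), records=refs)
print(f"index: {index.n_frag} bins x {index.bits_sbf} bits "
      f"({index.physical_size_bits / 8 / 2**20:.2f} MiB)")
print("threshold for a 360 nt read:", match_threshold(360, k=13, e=0.1, alpha=0.05))

cfg = SimulationConfig(median_read_length=2000, seed=43)    # ~10% error channel
read = simulate_reads(refs, 1, config=cfg)[0]
model = ThresholdModel(k=13, e=0.1, alpha=0.05)
print(classify_sequence(read.sequence[:360], index, model, read.read_id))
```

prints

```
index: 3 bins x 1236269 bits (9.43 MiB)
threshold for a 360 nt read: 38
ClassificationResult(read_id='read_0', matched=True, best_bin=1, best_count=148,
                     threshold_used=38, L_queried=348, filter_role='deplete')
```

The 250 kb genome becomes 3 overlapping fragments, each with a
1 236 269-bit filter (the smallest size keeping each bin's FP rate ≤ 0.01
at 99 988 inserted k-mers). A 360 nt prefix holds 348 13-mers; at 10%
error, 38 of them must match a bin. This simulated read (drawn through the
error channel, here landing on the reverse strand of fragment 1) keeps 148
matching k-mers — comfortably accepted for depletion.

The same workflow is available from the shell:

```sh
poresieve ibfbuild --input ref.fasta --output ref.ibf
poresieve classify --reads reads.fastq --deplete ref.ibf --out results.tsv
poresieve simulate --ref-out ref.fa --reads-out sim.fq --truth-out truth.tsv
poresieve target  --reads sim.fq --deplete ref.ibf --log session.tsv
poresieve evaluate --results results.tsv --truth truth.tsv --out metrics.tsv
```

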