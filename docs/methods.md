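# Methods

## The k-mer representation

A k-mer is stored as `(k, code)` with `code` an unsigned integer of exactly
2k bits, two bits per base, first base in the most significant pair. The
base map is A=00, C=01, G=10, T=11. Two constraints drove this choice:

* **Complement by NOT.** The map satisfies f(A) = ~f(T) and f(C) = ~f(G)
  over two bits, so complementing a whole k-mer is a single bitwise NOT.
  Any of the eight 2-bit assignments with this property would be
  functionally equivalent; ours additionally makes integer order on codes
  equal lexicographic order on strings (A<C<G<T), which makes sorted k-mer
  tables human-readable.
* **Reversal for free.** Since reverse = complement ∘ reverse-complement,
  and complement is NOT, reversal is the bit-inverted reverse complement.

Reverse complementation is table driven. `rc4` is a 256-entry byte array
whose entry *i* is the encoded reverse complement of the 4-mer with code
*i*; it is computed once at import time by pure bit manipulation
(complement = `~i`, reversal = swapping the four 2-bit fields). An
arbitrary k-mer is reverse complemented by slicing its code into 4-mer
chunks from the low end and OR-ing `rc4[chunk]` results together so that
the last chunk's image lands in the most significant position — the
identity revcomp(s₁‖s₂) = revcomp(s₂)‖revcomp(s₁). When k mod 4 ≠ 0 the
code is first left-shifted by the missing bases, which appends A bases at
the 3' end; their images are T bases at the 5' end of the result, removed
by masking to the low 2k bits.

k is capped at 1024 — a practical ceiling above any seeding application —
and codes wider than a machine word simply use Python's arbitrary-precision
integers; no special wide-word path exists or is needed.

Sequences (`DnaSequence`) are validated strings over {A,C,G,T,N};
soft-masked lowercase input is uppercased on construction. N survives in
sequences but can never enter a k-mer: `encode_kmer` raises on it, and the
k-merization operator skips N-containing windows while still advancing its
position grid, so positions remain comparable across reads with and
without Ns. Splitting (`split`) returns raw subsequences and keeps N.

## CpG regions and symmetric k-mers

A CpG region here is the benchmark definition, not a biological CpG-island
call: a maximal run of C/G characters containing at least one C and at
least one G ("CGC" is one region; "CCC" and "GGG" are none). Minimal
region length is therefore 2. Intervals are half-open and 0-based.

A k-mer of even k is *symmetric* when its first half equals the reverse
complement of its second half — equivalently, when the decoded string is
its own reverse complement. The 16-mer benchmark counts symmetric 16-mers
over all windows of every read; the window stride is configurable and
defaults to 1 (maximal sensitivity; non-overlapping counting is available
via `--stride 16`).

## The pattern language

Tokens are literal bases, `_` (exactly one base, N included — a wildcard
means "any base", whereas a literal is a specific call, so literals do not
match N) and `...` (zero or more bases; dot-runs must have length divisible
by three, and adjacent gaps collapse). Matching is anchored at both ends;
substring search is expressed by wrapping a pattern in gaps. More than one
gap per pattern is allowed — strictly more expressive than leading/trailing
gaps only, and backwards compatible. The engine is an NFA simulation over
token positions (the classic glob-matching DP), O(|s|·|p|) time and O(|p|)
space, so no pattern can trigger exponential backtracking.

## Pipelines, parallelism, prefetch scheduling

Serial `run` is the reference semantics: Mappers apply 1→1, Flatteners
expand 1→many, output is depth-first expansion order, and everything is a
generator — consuming m outputs pulls only the source prefix that produces
them.

`run_parallel` splits the stage list at the `PARALLEL` marker: stages
before it run serially (typically file iteration), elements are then
blocked into batches — 100,000 by default, sized so that per-task overhead
amortizes over real work — and batches are processed by a thread pool.
Only multiset equality with the serial output is promised; ordering is
explicitly unspecified because completion order depends on scheduling
(workers=1 degenerates to exact serial order, which the deterministic
tests use). Post-marker stages must be pure with respect to shared state.
The first worker exception is re-raised after in-flight batches drain.

`run_prefetch` models the software-prefetch transformation for large-index
queries. A prefetch stage is a generator function: per element it issues
an advisory hint for the index location it is about to read, yields
exactly once, then performs the access and returns its result. The
scheduler holds a ring of M slots (default 16 — large enough to saturate
memory-level parallelism in the setting this models, conservative enough
to leave prefetch bandwidth to the rest of a real system): it fills the
slots from the source, then cycles, resuming one task per visit; a
completed task emits its result and its slot is refilled. After source
exhaustion the remaining tasks drain. Invariants: every admitted element
emits exactly one result (slot conservation, including M larger than the
workload); M=1 reproduces serial order; output multiset equals serial for
any M. A stage that never suspends or suspends twice is a protocol error.
Hints are semantically inert — an instrumentation hook and per-index
counters record (prefetch, lookup) event order, which is how the tests
demonstrate that with M=2 two hints really are in flight before the first
load completes. Nested parallel/prefetch composition is out of scope; a
pipeline carries at most one `PARALLEL` marker.

## The seeding index

`build_index` records every N-free k-long window of the (concatenated)
reference at stride 1; k defaults to 20, the hash-table width of
SNAP-style seeding. Multi-contig references store per-contig offsets so
positions map back. `seed_reads` k-merizes each read at a step defaulting
to k (non-overlapping seeds; step=1 gives the dense variant), and totals
candidate loci for each k-mer and its reverse complement — the reverse
totals stand in for the half of reads sequenced off the opposite strand.
As a prefetch stage, each read-task hints the index with its first k-mer,
suspends, and performs all its lookups on resumption: one hint per task,
matching the one-suspend contract. The index persists as a versioned
sorted text table (`code TAB comma-separated-positions`). Full alignment
(extension, SAM output) and FM-indices are out of scope.

## Synthetic data

The generator emulates the *shape* of a short-read benchmark corpus, not
its biology: reads are 75 bp (the read length of the benchmark dataset
this package's benchmarks are scaled from), bases i.i.d. from a weight
vector (uniform by default), each base independently replaced by N at rate
`n_rate` (default 0; 0.005 in the end-to-end tests — a typical order for
modern short-read data), qualities the constant 'I' since no benchmark
consumes them. References are uniform ACGT. What this does **not** model:
GC skew, repeats, homopolymer structure, quality-correlated errors,
paired-end structure. Passing tests therefore certify the operators'
correctness and the schedulers' equivalences, not performance or accuracy
on real genomes. Everything is deterministic given the seed (numpy
`default_rng`).

Problem sizes in the test suite and acceptance script — 10,000 reads of
75 bp, a 100 kb reference, 100,000 pattern/sequence pairs, exhaustive
enumeration through k=8 (87,380 k-mers) — were chosen as the largest sizes
that keep a full run comfortable on a laptop-class single core while
leaving every code path (padding remainders, N handling, scheduler drain)
exercised. In the acceptance corpus one read in ten is sampled from the
reference, alternating strands, so seeding statistics are non-degenerate;
purely i.i.d. 20-mers essentially never hit a 100 kb reference
(4^20 ≈ 10^12 possible 20-mers).

## Numerical and edge-case choices

* Coordinates 0-based, intervals half-open throughout.
* `kmers`/`split` with inputs shorter than the window yield empty streams,
  not errors; `build_index` on a reference shorter than k errors.
* The empty string is its own reverse complement (`is_self_revcomp("")`
  is true); the empty pattern matches only the empty sequence.
* FASTQ is strict 4-line; text after the `+` separator is ignored; blank
  lines between records are tolerated; quality length must equal sequence
  length and quality bytes must be printable ASCII (Phred+33).
* When the reverse-complement benchmark rewrites FASTQ, the quality string
  is reversed alongside the sequence (the standard convention).
* Generator weight vectors must sum to 1 within 1e-9.
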