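# seqops

Streaming sequence operations for short-read genomics: bit-packed k-mers
with table-driven reverse complementation, a wildcard pattern language for
DNA, lazy processing pipelines with a prefetch-interleaving scheduler for
index queries, and a hash-based k-mer seeding index — plus a CLI that runs
the classic read-processing benchmarks (reverse complement, CpG regions,
symmetric 16-mers, k-nucleotide frequencies, read seeding) over FASTA/FASTQ.

## Who this is for

Anyone prototyping read-processing tools who wants the standard genomics
primitives as a small, tested library: the 2-bit k-mer representation used
by hash-table aligners, the seeding computation that precedes alignment,
and a pipeline model where reads stream through stages without ever being
materialized in memory.

## The core ideas

**2-bit k-mer packing.** A k-mer over {A, C, G, T} is an unsigned integer
of 2k bits with base map A=00, C=01, G=10, T=11 (first base in the most
significant pair, so integer order is lexicographic order). Because
f(A) = ~f(T) and f(C) = ~f(G), complementation is bitwise NOT. Reverse
complementation uses a 256-entry table `rc4` holding the reverse complement
of every 4-mer: a k-mer is sliced into 4-mer chunks, each looked up, and
the results concatenated in reverse chunk order (revcomp(s₁‖s₂) =
revcomp(s₂)‖revcomp(s₁)); k not divisible by 4 is handled by padding with
A bases and masking away the resulting leading T bases. Plain reversal
falls out for free: it is the bit-inverted reverse complement. k up to
1024 is supported.

**Pattern matching.** Patterns over `A C G T _ ...` where `_` matches any
single base and `...` matches zero or more bases, anchored at both ends;
matching is an O(|s|·|p|) NFA simulation. `match_dispatch` gives ordered
first-match dispatch over a case list.

**Pipelines.** `run` executes Mapper/Flattener stages lazily in depth-first
order. `run_parallel` blocks elements into batches (default 100,000) after
a `PARALLEL` marker and processes batches in a worker pool — output
multiset is identical to serial, order unspecified (workers=1 is exactly
serial). `run_prefetch` is the index-query scheduler: each query is a
coroutine that issues an advisory prefetch hint for the index entry it
needs, suspends, then loads it; the scheduler keeps a ring of M (default
16) suspended queries so that many hints are in flight before any load —
the software-prefetch trick that hides DRAM latency on multi-gigabyte
genomic indices, modeled here semantically and observable through event
traces.

**Seeding index.** `build_index` maps every k-mer (default k=20) of a
reference to its sorted positions; `seed_reads` k-merizes each read and
totals candidate loci for the forward k-mers and their reverse
complements, serially or through the scheduler.

## Worked example

```
$ seqops gen --kind reads --n 50 --seed 3 --out reads.fq
$ seqops cpg reads.fq
cpg_regions     314
shortest        2
longest         13
```

The 50 synthetic 75 bp reads contain 314 maximal C/G runs that include at
least one C and one G; the shortest such run is 2 bases (a bare `CG` or
`GC`), the longest 13.

```
$ seqops gen --kind reference --n 2000 --seed 4 --out ref.fa
$ seqops seed ref.fa reads.fq --k 8 --step 1 --prefetch
read    hits_forward    hits_reverse
read0   3       3
read1   0       1
read2   1       1
...
```

Each row totals, over the read's 8-mers, how many positions of the 2 kb
reference each one hits — forward and reverse-complemented. `--prefetch`
routes the queries through the M-slot scheduler; the reports are identical
either way.

From Python:

```python
>>> from seqops import encode_kmer, revcomp_kmer, decode_kmer, matches
>>> km = encode_kmer("GATTACA")       # 14-bit integer code
>>> str(decode_kmer(revcomp_kmer(km)))
'TGTAATC'
>>> matches("...A_C_G_T...", "TTAACAGATTT")   # subsequence with wildcards
True
```

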