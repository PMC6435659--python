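# Methods

## Model

`readnorm` treats read normalization as weighted set multi-cover. The
universe is the set L of labels — (k+1)-mers, the edge labels of the
k-mer de Bruijn graph — present in the input read set R; each read is the
multiset of its labels. A normalized set R′ ⊆ R is valid when every
label l satisfies

    abund(l, R′) ≥ min(t_l, abund(l, R)),
    t_l = max(1, ⌈log_b abund(l, R)⌉)

The log scaling keeps a number of copies that grows slowly with original
abundance, preserving the abundance signal DBG assemblers use to resolve
bubbles and prioritize contigs, while discarding the bulk of redundant
high-coverage reads. The `min(·, abund)` cap makes the constraint
feasible even when b is close to 1 (e.g. b = 1.1 and abundance 2 give
t = 8, more copies than exist; all copies are then kept).

The unweighted objective minimizes |R′|; the weighted objectives
minimize ΣW over the kept reads with per-read weight 1/qr (sum of phred
scores; mode `orna-q`) or 1/kr (median label abundance in the original
dataset; mode `orna-k`). Exact WSMC is NP-hard; the implementation is the
sort-once greedy: order reads once by non-decreasing weight, scan, accept
a read iff at least one of its label occurrences is still below its
threshold, and on acceptance increment the achieved count of *every*
label occurrence in the read (occurrences, not distinct labels — the
constraint counts occurrences in R′). Reads with no valid label are
rejected in every mode: they cannot contribute to the cover.

This single pass guarantees the cover invariant in any processing order:
a label could only end under-covered if a read containing it was
rejected while the label was uncovered, which the acceptance test
forbids. The ordering therefore only decides *which* valid cover is
produced, never whether the guarantee holds.

### Paired-end data

Both mate files contribute to one label universe and one threshold
table. Normalization runs in three stages: (1) pairs are scored by the
sum of the mates' scores and sorted by descending pair score (original
file order in mode `orna`, matching a streaming pass); (2) a pair is
accepted when *both* mates contain an uncovered label (all label
occurrences of both mates are then counted), *marked* when exactly one
mate qualifies (nothing is counted), rejected otherwise; (3) marked
pairs are revisited in the order first encountered and accepted — again
counting both mates — if either mate still has an uncovered label.
Counting both mates on stage-3 acceptance is our choice where the
procedure's description is silent: both reads enter R′, and the
constraint counts occurrences in R′. Output always contains whole pairs.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 22 | k-mer size; labels have length k+1 = 23. The standard working point for transcriptome assembly preprocessing. Packed 2-bit encoding supports label lengths up to 31. |
| `b` | 1.7 | log base of the threshold formula; larger b → smaller t_l → stronger reduction. 1.7 is a moderate default in the useful range (≈1.3–8); it is a tuning knob, not a constant. |
| `canonical` | on | reverse-complement-aware counting: assemblers treat strands jointly, so both orientations of a label are one graph edge. With even k (odd label length) no label is its own reverse complement. `--no-canonical` counts forward-strand labels literally. |
| `phred_offset` | 33 | Sanger/Illumina 1.8+ encoding; overridable for legacy data. Characters decoding below 0 raise an error suggesting the offset is wrong. |
| `bin_width` | 1 | `orna-k` bin size for the kr bin sort. Width 1 gives the exact descending-kr order (kr is integral under the lower-median convention). Large widths coarsen the order toward file order within bins. |

## Conventions and numerical choices

* **Thresholds.** t_l is computed as `ceil(log(a)/log(b) − 1e-9)` and
  then corrected by direct float-power comparison so the returned value
  is exactly the smallest integer t with `b**t ≥ a` (mathematically
  identical to ⌈log_b a⌉ for a ≥ 1, immune to IEEE log overshoot at
  exact powers such as log2(8)).
* **Median.** kr uses the LOWER median (sorted index ⌊(n−1)/2⌋). It
  keeps kr integral — enabling exact bin indexing — and matches the
  convention of count-based normalizers. Pinned by tests.
* **Ties and zero scores.** The counting/bin sorts are stable: equal
  scores keep file order, making every run deterministic. Reads (or
  pairs) with score 0 have undefined weight 1/0 and are ordered last.
* **Sorting.** The orderings are genuine counting/bucket sorts over the
  integer score histogram, realized in memory; the on-disk chunked merge
  used at hundred-million-read scale is replaced by an in-memory
  equivalent with the identical ordering contract (tests compare the
  permutation against a generic stable descending sort).
* **Counting.** Exact hash-free counting: labels are packed into int64
  (2 bits/base), the universe is `np.unique` of all occurrences, and
  lookups are binary searches. No probabilistic structures; counts are
  exact by construction. Windows containing non-ACGT characters are
  skipped entirely (not N-expanded), keeping the universe well defined.
* **Label count per read.** A read of length s has s−k labels of length
  k+1 (window count), which is what the implementation extracts;
  descriptions of the abundance vector sometimes state s−k+1 entries,
  an off-by-one we resolve in favour of the window count.
* **Output order.** Accepted reads are written in acceptance order
  (sorted order for the weighted modes); `--preserve-input-order`
  re-sorts by original index. Record id lines are preserved verbatim.

## Synthetic data

The generator emulates the features of RNA-seq the method exploits:
log-normal per-transcript expression (non-uniform coverage),
per-position mean phred declining along the read with gaussian spread,
an optional *low-quality-early* gradient that lowers qualities of reads
early in the file (the positional skew that makes ordering matter), and
per-base substitution errors with probability 10^(−q/10) given the
simulated phred q — so low-quality reads carry novel low-abundance
labels. Fragments for paired mode are sampled with normal length and
emitted as inward-facing mates. Randomness comes from one seed;
`SeedSequence(seed)` is split into a transcript stream and a read
stream, and all draws follow a documented order, so equal seeds give
byte-identical output.

It does **not** model indels, adapter read-through, PCR duplicates,
coverage bias along transcripts (fragmentation/GC effects), or trained
quality profiles. Passing tests therefore demonstrate the combinatorial
and ordering behaviour of the normalizer under realistic abundance and
quality *structure*, not calibration against any particular instrument.

## Problem sizes

The test suite checks the cover guarantee on 200+ simulated datasets of
50–5,000 reads (k ∈ {5, 11, 21}, b ∈ {1.3, 1.7, 2, 8}, all modes,
single and paired), exact index-for-index agreement with a naive
reference greedy (independent code path, recount per step) on 105
instances of ≤ 50 reads, sorting contracts at 10^5 reads, and a
1,000,000-read × 76 bp scale run at k = 22 with exact counting (about
1.5 minutes and < 2 GB on one CPU here). The acceptance script uses
100,000 single-end reads and 20,000 pairs. These sizes were chosen so
the whole suite completes in a few minutes while exercising every code
path at meaningfully larger-than-toy scale.

## Known limitations and observed behaviour

* Exact in-memory counting stores every distinct label; memory grows
  with the label universe (≈1M labels per 10^6 random-ish 76-mers at
  k=22 in our simulations, ~2 GB peak at the million-read scale run).
  Hundred-million-read datasets would need the disk-backed machinery
  this package deliberately replaces with an in-memory equivalent.
* With `bin_width = 1` at desk-scale coverage, the exact descending-kr
  order clusters reads of equal kr (hence similar position on their
  transcript) and processes spatial neighbourhoods at very different
  times; flanking labels are then often still uncovered, so `orna-k`
  accepts noticeably more reads than file order on small datasets. The
  mean abundance score of the kept set still improves, which is the
  property the mode optimizes; at high coverage and/or larger bin
  widths the reduction gap narrows as the order approaches file order
  within bins.
* The greedy is a heuristic: it guarantees a *valid* cover of high
  average score, not a minimum-weight one.
* Quality handling assumes a single phred offset per file; re-encoding
  between offsets is out of scope, as are SAM/BAM input and
  interleaved-pair auto-detection.
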