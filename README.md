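# readnorm

In-silico read normalization for sequencing datasets, formulated as a
weighted set multi-cover optimization.

Modern RNA-seq (and metagenomic) runs oversample highly expressed
transcripts by orders of magnitude. De Bruijn graph (DBG) assemblers pay
for that redundancy in memory and runtime without gaining information.
`readnorm` reduces a FASTQ dataset **while provably retaining every
(k+1)-mer of the original** — i.e. every edge label of the k-mer de
Bruijn graph — at a log-scaled abundance threshold, so the assembly
graph's connectivity survives normalization. Among all reads it could
keep, it preferentially keeps those of high base quality or high k-mer
abundance, which are the reads least likely to carry sequencing errors.

It is intended for people preparing large single-end or paired-end
FASTQ datasets for de novo assembly, and as a compact, exactly counted
reference implementation of weight-aware multi-cover normalization for
methods work.

## The optimization

Let R = r_1 … r_n be the input reads. Each read is viewed as the multiset
of its *labels*: substrings of length k+1, the DBG edge labels. For every
label l with abundance `abund(l, R)`, define the retention threshold

    t_l = max(1, ⌈log_b abund(l, R)⌉),       b > 1

A valid normalized set R′ ⊆ R must satisfy `abund(l, R′) ≥ t_l` for all
labels (capped at feasibility: when b is close to 1, t_l may exceed
`abund(l, R)`, in which case all copies are kept). Larger b means smaller
thresholds and stronger reduction.

The unweighted problem (mode `orna`) asks for a minimum-cardinality R′ —
a set multi-cover instance. The weighted variants assign each read the
weight

* `orna-q`: qw_i = 1 / qr_i, where qr_i = Σ_j q_i^j is the sum of the
  read's phred scores (*read quality score*), or
* `orna-k`: kw_i = 1 / kr_i, where kr_i is the median abundance of the
  read's labels in the original dataset (*read abundance score*),

and ask for a valid R′ of minimum total weight — a weighted set
multi-cover (WSMC) instance, solved by a sort-once greedy heuristic:
reads are ordered once by non-decreasing weight (a counting sort on qr,
or a bin sort on kr), then scanned; a read is accepted iff it still
contains a label below its threshold, and acceptance increments the
achieved count of every label occurrence in the read. Minimizing the
total inverse score maximizes the average score of the kept reads.
Paired-end data is handled in three stages (sort by pair score; accept
pairs where both mates are needed, mark pairs where one is; re-scan the
marked pairs), emitting whole pairs only.

## Worked example

The package ships a 4-read example that can be traced by hand. The reads
are `AAAAA, AAAAA, AAAAA, AAAAC` with quality strings
`!!!!!, IIIII, 88888, IIIII` (read quality scores 0, 200, 115, 200).
At k = 3 and forward-strand counting the label universe is
`{AAAA: 7, AAAC: 1}`; with b = 2 the thresholds are
t(AAAA) = ⌈log2 7⌉ = 3 and t(AAAC) = 1.

```python
>>> import readnorm as rn
>>> reads, params = rn.build_fixture("tiny")   # k=3, b=2, canonical off
>>> rn.normalize_single(reads, mode="orna", **params).accepted
array([0, 1, 3])
>>> rn.normalize_single(reads, mode="orna-q", **params).accepted
array([1, 3])
```

In file order (`orna`), reads 0 and 1 are accepted and push AAAA to 4
occurrences (≥ 3), read 2 is rejected, and read 3 is accepted for its
uncovered AAAC — 25% reduction. In quality order (`orna-q`) the reads
are processed as [1, 3, 2, 0]; reads 1 and 3 already cover AAAA three
times and AAAC once, so reads 2 and 0 (the qr = 0 read, ordered last)
are rejected — 50% reduction, and the kept reads are the two
highest-quality ones. Both outputs retain every label at its threshold.

The same pipeline from the shell:

```bash
readnorm simulate --fixture tiny -o demo/
readnorm normalize -i demo/tiny.fastq -o demo/tiny.norm.fastq \
    --mode orna-q -k 3 -b 2 --no-canonical
# INFO mode=orna-q n_input=4 n_accepted=2 reduction=50.00% ... cover=pass
```

Every CLI run re-verifies the cover constraint before exiting 0 and
writes a JSON run report next to the output.

## Package layout

| module | contents |
|---|---|
| `readnorm.io_fastq` | FASTQ/FASTA reading/writing (gzip-aware), phred decoding, pairing |
| `readnorm.kmer_core` | label extraction, exact 2-bit-packed counting, thresholds |
| `readnorm.scoring` | read/pair scores qr, kr and weights, dataset averages |
| `readnorm.normalize` | orderings, greedy selection, paired three-stage variant, cover verification |
| `readnorm.evaluate` | positional score profiles, before/after comparison |
| `readnorm.synthetic` | transcriptome-like simulator and seed-pinned fixtures |
| `readnorm.cli` | `readnorm normalize / evaluate / simulate` |

See `docs/methods.md` for the model, conventions (lower median, tie
handling, canonical counting) and known limitations.
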