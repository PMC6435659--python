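"""Label ((k+1)-mer) extraction, exact counting, and retention thresholds.

A *label* is a string of length k+1: the edge label of a de Bruijn graph
built on k-mers (prefix k-mer = source node, suffix k-mer = destination).
Retaining every label of a read dataset preserves the full edge set of the
assembly graph, which is the guarantee the normalizer provides.

Counting is exact and in-memory.  Labels are packed into 64-bit integers
(2 bits per base, so any k+1 <= 32 fits) with numpy, and the universe is
the sorted array of unique codes produced by ``np.unique``.  Windows
containing characters outside ``{A,C,G,T}`` are skipped entirely, matching
standard k-mer-counter behaviour and keeping the universe well defined.

Canonical (reverse-complement-aware) counting is ON by default: de Bruijn
graph assemblers treat the two strands jointly, so the two orientations of
a label are the same graph edge.  With odd label lengths (any even k, e.g.
the default k=22 giving 23-mers) no label is its own reverse complement.
A ``canonical=False`` mode counts forward-strand labels literally.

The per-label retention threshold is ``t_l = max(1, ceil(log_b a_l))``
where ``a_l`` is the label's abundance in the original dataset and b > 1
is the stringency base: larger b gives smaller thresholds and hence more
reduction.  The ceil-log is computed with an epsilon guard and verified by
direct float-power comparison, because IEEE ``log`` can overshoot exact
powers (e.g. ``log2(8)`` must give t=3, not 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, Tuple

import numpy as np

from .errors import ParameterError, StateError
from .io_fastq import Read

__all__ = [
    "revcomp",
    "extract_labels",
    "count_labels",
    "compute_thresholds",
    "threshold_for_abundance",
    "LabelCounter",
    "ThresholdTable",
    "EncodedReads",
    "encode_reads",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# 2-bit encoding; -1 marks characters that cannot appear in a label
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _BASE_CODE[ord(_c)] = _i
    _BASE_CODE[ord(_c.lower())] = _i

_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

#: largest label length representable in an int64 code
MAX_LABEL_LEN = 31

# reads are encoded in chunks to bound peak temporary memory
_ENCODE_CHUNK_BASES = 20_000_000


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_k(k: int) -> None:
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k + 1 > MAX_LABEL_LEN:
        raise ParameterError(
            f"k={k} gives labels of length {k + 1}, beyond the "
            f"supported maximum of {MAX_LABEL_LEN}"
        )


def extract_labels(seq: str, k: int, canonical: bool = True) -> list[str]:
    """All (k+1)-mer labels of ``seq`` in left-to-right order.

    Windows containing characters outside ``{A,C,G,T}`` are skipped.
    Duplicates are retained (multiplicity matters for abundance).  A
    sequence shorter than k+1 yields an empty list.

    This is the plain string-level routine used for small inputs and as a
    readable statement of the label definition; bulk counting goes through
    the packed-integer path in :func:`encode_reads`.
    """
    _check_k(k)
    width = k + 1
    seq = seq.upper()
    out: list[str] = []
    for i in range(len(seq) - width + 1):
        window = seq[i : i + width]
        if any(c not in "ACGT" for c in window):
            continue
        if canonical:
            rc = revcomp(window)
            window = window if window <= rc else rc
        out.append(window)
    return out


def _encode_block(
    seqs: Sequence[str], width: int, canonical: bool
) -> Tuple[np.ndarray, np.ndarray]:
    """Encode a block of sequences; returns (codes, labels-per-read)."""
    joined = "N".join(seqs)
    base = _BASE_CODE[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    n_win = len(joined) - width + 1
    per_read = np.zeros(len(seqs), dtype=np.int64)
    if n_win <= 0:
        return np.empty(0, dtype=np.int64), per_read

    fwd = np.zeros(n_win, dtype=np.int64)
    rc = np.zeros(n_win, dtype=np.int64) if canonical else None
    for j in range(width):
        w = base[j : j + n_win].astype(np.int64)
        fwd = (fwd << 2) + w
        if rc is not None:
            rc += (3 - w) << (2 * j)
    codes = np.minimum(fwd, rc) if rc is not None else fwd

    bad = base < 0
    bad_cum = np.concatenate(([0], np.cumsum(bad)))
    window_ok = (bad_cum[width:] - bad_cum[:-width]) == 0

    # windows of read r sit at joined positions [start_r, start_r+len_r-width]
    lens = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    starts = np.concatenate(([0], np.cumsum(lens + 1)))[:-1]
    ok_cum = np.concatenate(([0], np.cumsum(window_ok)))
    has_win = lens >= width
    lo = starts[has_win]
    hi = lo + lens[has_win] - width + 1
    per_read[has_win] = ok_cum[hi] - ok_cum[lo]
    return codes[window_ok], per_read


@dataclass(slots=True)
class EncodedReads:
    """Packed label codes of a read set.

    ``codes[offsets[i]:offsets[i+1]]`` are the (valid) labels of read i in
    left-to-right order, encoded as 2-bit-packed int64.
    """

    k: int
    canonical: bool
    codes: np.ndarray
    offsets: np.ndarray

    @property
    def n_reads(self) -> int:
        return len(self.offsets) - 1

    def labels_of(self, i: int) -> np.ndarray:
        return self.codes[self.offsets[i] : self.offsets[i + 1]]


def encode_reads(
    reads: Sequence[Read] | Sequence[str], k: int, canonical: bool = True
) -> EncodedReads:
    """Encode every read's labels into packed integers (chunked)."""
    _check_k(k)
    width = k + 1
    seqs = [r.seq if isinstance(r, Read) else r for r in reads]
    code_blocks: list[np.ndarray] = []
    per_read_blocks: list[np.ndarray] = []
    start = 0
    while start < len(seqs):
        stop, bases = start, 0
        while stop < len(seqs) and bases < _ENCODE_CHUNK_BASES:
            bases += len(seqs[stop]) + 1
            stop += 1
        codes, per_read = _encode_block(seqs[start:stop], width, canonical)
        code_blocks.append(codes)
        per_read_blocks.append(per_read)
        start = stop
    if code_blocks:
        all_codes = np.concatenate(code_blocks)
        counts = np.concatenate(per_read_blocks)
    else:
        all_codes = np.empty(0, dtype=np.int64)
        counts = np.empty(0, dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(counts)))
    return EncodedReads(k=k, canonical=canonical, codes=all_codes, offsets=offsets)


def _decode_codes(codes: np.ndarray, width: int) -> list[str]:
    if len(codes) == 0:
        return []
    shifts = 2 * np.arange(width - 1, -1, -1, dtype=np.int64)
    mat = _CODE_BASE[(codes[:, None] >> shifts[None, :]) & 3]
    return [row.tobytes().decode("ascii") for row in mat]


class LabelCounter:
    """Exact multiset of the labels of a read dataset.

    Behaves as a read-only mapping from label string to positive integer
    abundance.  Internally the universe is a sorted array of packed label
    codes with a parallel count array, which supports O(log m) lookup and
    vectorized batch lookups.
    """

    def __init__(self, k: int, canonical: bool, codes: np.ndarray, counts: np.ndarray):
        self.k = k
        self.canonical = canonical
        self._codes = codes
        self._counts = counts

    # -- construction -------------------------------------------------

    @classmethod
    def from_encoded(cls, encoded: EncodedReads) -> "LabelCounter":
        if len(encoded.codes):
            codes, counts = np.unique(encoded.codes, return_counts=True)
        else:
            codes = np.empty(0, dtype=np.int64)
            counts = np.empty(0, dtype=np.int64)
        return cls(encoded.k, encoded.canonical, codes, counts)

    # -- mapping interface --------------------------------------------

    def __len__(self) -> int:
        return len(self._codes)

    def _encode_one(self, label: str) -> int:
        if len(label) != self.k + 1:
            raise KeyError(label)
        vals = _BASE_CODE[np.frombuffer(label.upper().encode("ascii"), dtype=np.uint8)]
        if (vals < 0).any():
            raise KeyError(label)
        code = 0
        for v in vals:
            code = (code << 2) + int(v)
        if self.canonical:
            rc_label = revcomp(label.upper())
            rc_code = 0
            for c in rc_label:
                rc_code = (rc_code << 2) + int(_BASE_CODE[ord(c)])
            code = min(code, rc_code)
        return code

    def __getitem__(self, label: str) -> int:
        code = self._encode_one(label)
        i = np.searchsorted(self._codes, code)
        if i < len(self._codes) and self._codes[i] == code:
            return int(self._counts[i])
        raise KeyError(label)

    def get(self, label: str, default: int = 0) -> int:
        try:
            return self[label]
        except KeyError:
            return default

    def __contains__(self, label: str) -> bool:
        return self.get(label, 0) > 0

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels())

    def labels(self) -> list[str]:
        """All labels, lexicographically sorted (code order == lex order)."""
        return _decode_codes(self._codes, self.k + 1)

    def items(self) -> Iterator[tuple[str, int]]:
        yield from zip(self.labels(), (int(c) for c in self._counts))

    def as_dict(self) -> dict[str, int]:
        return dict(self.items())

    def total(self) -> int:
        """Total number of label occurrences counted."""
        return int(self._counts.sum())

    # -- vectorized access --------------------------------------------

    def index_of(self, codes: np.ndarray, strict: bool = True) -> np.ndarray:
        """Indices of packed codes in the universe; -1 for absent codes."""
        idx = np.searchsorted(self._codes, codes)
        idx = np.minimum(idx, max(len(self._codes) - 1, 0))
        if len(self._codes):
            present = self._codes[idx] == codes
        else:
            present = np.zeros(len(codes), dtype=bool)
        if strict and not present.all():
            raise StateError("label code not present in counter universe")
        out = np.where(present, idx, -1)
        return out

    def abundances(self, codes: np.ndarray) -> np.ndarray:
        """Abundance of each packed code (0 for codes not in the universe)."""
        idx = self.index_of(codes, strict=False)
        out = np.zeros(len(codes), dtype=np.int64)
        hit = idx >= 0
        out[hit] = self._counts[idx[hit]]
        return out

    @property
    def count_array(self) -> np.ndarray:
        return self._counts

    @property
    def code_array(self) -> np.ndarray:
        return self._codes

    # -- serialization ------------------------------------------------

    def dump(self, path) -> None:
        """Plain-text dump: one ``label<TAB>count`` line, labels sorted."""
        with open(path, "wt") as fh:
            for label, count in self.items():
                fh.write(f"{label}\t{count}\n")


def count_labels(
    reads: Sequence[Read] | Sequence[str],
    k: int,
    canonical: bool = True,
    encoded: EncodedReads | None = None,
) -> LabelCounter:
    """Count every label occurrence over a read set (exact, order-free).

    ``encoded`` may carry a precomputed :func:`encode_reads` result for the
    same reads/parameters to avoid re-encoding.
    """
    if encoded is None:
        encoded = encode_reads(reads, k, canonical)
    elif encoded.k != k or encoded.canonical != canonical:
        raise StateError("encoded reads do not match requested k/canonical")
    return LabelCounter.from_encoded(encoded)


def threshold_for_abundance(abund: np.ndarray | int, b: float) -> np.ndarray | int:
    """Retention threshold ``max(1, ceil(log_b(abund)))``, exactly.

    Computed as ceil-log with an epsilon guard, then corrected by direct
    float-power comparison so that the result is the smallest integer t
    with ``b**t >= abund`` (mathematically identical to the ceil-log,
    immune to floating-point log overshoot at exact powers).
    """
    if b <= 1:
        raise ParameterError(f"log base b must be > 1, got {b}")
    scalar = np.isscalar(abund)
    a = np.atleast_1d(np.asarray(abund, dtype=np.float64))
    if (a < 1).any():
        raise ParameterError("abundances must be >= 1")
    t = np.ceil(np.log(a) / math.log(b) - 1e-9).astype(np.int64)
    np.maximum(t, 1, out=t)
    # power-verification: enforce b**(t-1) < a <= b**t (with the t >= 1 floor)
    for _ in range(64):
        over = (t > 1) & (np.power(b, t - 1) >= a)
        if not over.any():
            break
        t[over] -= 1
    for _ in range(64):
        under = np.power(b, t) < a
        if not under.any():
            break
        t[under] += 1
    return int(t[0]) if scalar else t


class ThresholdTable:
    """Per-label retention targets ``t_l`` for a counted dataset.

    Mapping from label to the number of copies the normalized set must
    retain; aligned index-for-index with the source counter's universe.
    """

    def __init__(self, counter: LabelCounter, b: float, thresholds: np.ndarray):
        self.counter = counter
        self.b = b
        self._t = thresholds

    def __len__(self) -> int:
        return len(self._t)

    def __getitem__(self, label: str) -> int:
        code = self.counter._encode_one(label)
        idx = self.counter.index_of(np.array([code], dtype=np.int64), strict=False)[0]
        if idx < 0:
            raise KeyError(label)
        return int(self._t[idx])

    def items(self) -> Iterator[tuple[str, int]]:
        yield from zip(self.counter.labels(), (int(t) for t in self._t))

    @property
    def threshold_array(self) -> np.ndarray:
        return self._t


def compute_thresholds(counter: LabelCounter, b: float) -> ThresholdTable:
    """Build the per-label threshold table ``t_l = max(1, ceil(log_b a_l))``."""
    if b <= 1:
        raise ParameterError(f"log base b must be > 1, got {b}")
    counts = counter.count_array
    if len(counts) == 0:
        t = np.empty(0, dtype=np.int64)
    else:
        t = threshold_for_abundance(counts, b)
    return ThresholdTable(counter, b, t)
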