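"""Greedy weighted set multi-cover read selection.

The normalizer keeps a subset R' of the input reads such that every label
(k+1-mer) l of the original dataset occurs in R' at least
``min(t_l, abund(l, R))`` times, where ``t_l = max(1, ceil(log_b
abund(l, R)))``.  Three modes differ only in the order in which reads are
offered to the greedy selector:

* ``orna``    — original file order (the unweighted baseline),
* ``orna-q``  — descending read quality score qr (counting sort),
* ``orna-k``  — descending read abundance score kr, bucketed into bins of
  ``bin_width`` (bin sort; within a bin, file order is kept).

Sorting descending by score equals ascending by weight (weight = 1/score),
so each iteration processes a read of (close to) minimal weight, which is
the sort-once simplification of the classical greedy for weighted set
multi-cover.  The ordering is a stable counting/bucket sort realized in
memory; zero-score reads (undefined weight) are placed last.

A read is accepted iff at least one of its label occurrences l still has
``achieved[l] < t_l``; on acceptance the achieved count of every label
occurrence in the read is incremented.  This single pass guarantees the
cover invariant: a label could only end under-covered if some read
containing it was rejected while the label was still uncovered, which the
acceptance test forbids.

Paired-end data is normalized in three stages: (1) pairs are sorted by
descending pair score (sum of the mates' scores; original order in mode
``orna``); (2) pairs where BOTH mates contain an uncovered label are
accepted (incrementing both mates' labels), pairs where exactly one mate
qualifies are *marked* without incrementing, others are rejected; (3)
marked pairs are revisited in the order first encountered and accepted —
again incrementing both mates' labels — if either mate still has an
uncovered label.  Output always contains whole pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import InputError, ModeError, ParameterError, StateError
from .io_fastq import DEFAULT_PHRED_OFFSET, Read, ReadPair
from .kmer_core import (
    EncodedReads,
    LabelCounter,
    ThresholdTable,
    _decode_codes,
    compute_thresholds,
    count_labels,
    encode_reads,
)
from .scoring import abundance_scores, quality_scores

__all__ = [
    "MODES",
    "Ordering",
    "CoverState",
    "NormalizationResult",
    "CoverReport",
    "order_original",
    "order_random",
    "order_by_quality",
    "order_by_abundance",
    "greedy_select",
    "normalize_single",
    "normalize_paired",
    "verify_cover",
]

MODES = ("orna", "orna-q", "orna-k")

DEFAULT_K = 22
DEFAULT_B = 1.7
DEFAULT_BIN_WIDTH = 1


@dataclass(slots=True)
class Ordering:
    """A permutation of input indices plus the strategy that produced it."""

    order: np.ndarray
    strategy: str
    scores: Optional[np.ndarray] = None  # per-read scores keyed by input index

    def __post_init__(self) -> None:
        n = len(self.order)
        if n and (np.sort(self.order) != np.arange(n)).any():
            raise StateError("ordering is not a permutation of input indices")


def order_original(n: int) -> Ordering:
    """File order (the sequencer's order) — used by the unweighted mode."""
    return Ordering(order=np.arange(n, dtype=np.int64), strategy="original")


def order_random(n: int, seed: int) -> Ordering:
    """A seeded random reshuffle, for ordering-sensitivity experiments."""
    rng = np.random.default_rng(seed)
    return Ordering(order=rng.permutation(n).astype(np.int64), strategy="random-shuffle")


def _counting_sort_desc(scores: np.ndarray) -> np.ndarray:
    """Stable counting sort: indices by non-increasing integer score.

    Builds the histogram-of-scores array T over 0..max and emits index
    buckets from the highest score down; ties keep input order.  Reads
    with score 0 (undefined weight) are emitted last, which bucket 0
    already guarantees.
    """
    n = len(scores)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    smax = int(scores.max())
    buckets: list[list[int]] = [[] for _ in range(smax + 1)]
    for i, s in enumerate(scores.tolist()):
        buckets[s].append(i)
    out = np.empty(n, dtype=np.int64)
    pos = 0
    for s in range(smax, -1, -1):
        bucket = buckets[s]
        out[pos : pos + len(bucket)] = bucket
        pos += len(bucket)
    return out


def order_by_quality(
    reads: Sequence[Read], offset: int = DEFAULT_PHRED_OFFSET
) -> Ordering:
    """Counting sort on qr: non-increasing score = non-decreasing weight."""
    qr = quality_scores(reads, offset)
    return Ordering(order=_counting_sort_desc(qr), strategy="quality-sort", scores=qr)


def order_by_abundance(
    reads: Sequence[Read],
    counter: LabelCounter,
    bin_width: int = DEFAULT_BIN_WIDTH,
    encoded: Optional[EncodedReads] = None,
) -> Ordering:
    """Bin sort on kr: bin ``floor(kr / bin_width)``, highest bin first.

    Within a bin the original order is kept (the algorithm ignores
    intra-bin order; pinning file order makes runs deterministic).
    """
    if bin_width < 1:
        raise ParameterError(f"bin_width must be >= 1, got {bin_width}")
    kr = abundance_scores(reads, counter, encoded=encoded)
    bins = (kr // bin_width).astype(np.int64)
    return Ordering(
        order=_counting_sort_desc(bins), strategy="abundance-binsort", scores=kr
    )


class CoverState:
    """Achieved label coverage of the partially built output set.

    ``achieved(label)`` reports the count capped at the label's threshold
    (coverage beyond the target is not meaningful for the constraint).
    """

    def __init__(self, thresholds: ThresholdTable):
        self.thresholds = thresholds
        self._ach = np.zeros(len(thresholds), dtype=np.int64)

    def achieved(self, label: str) -> int:
        code = self.thresholds.counter._encode_one(label)
        idx = self.thresholds.counter.index_of(
            np.array([code], dtype=np.int64), strict=False
        )[0]
        if idx < 0:
            raise KeyError(label)
        return int(min(self._ach[idx], self.thresholds.threshold_array[idx]))

    @property
    def raw_counts(self) -> np.ndarray:
        return self._ach


@dataclass(slots=True)
class NormalizationResult:
    """Accepted read (or pair) indices plus run bookkeeping."""

    accepted: np.ndarray
    mode: str
    k: int
    b: float
    canonical: bool
    offset: int
    bin_width: int
    n_input: int
    n_accepted: int
    reduction_pct: float
    total_weight_selected: Optional[float] = None
    paired: bool = False

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "k": self.k,
            "b": self.b,
            "canonical": self.canonical,
            "phred_offset": self.offset,
            "bin_width": self.bin_width,
            "paired": self.paired,
            "n_input": self.n_input,
            "n_accepted": self.n_accepted,
            "reduction_pct": self.reduction_pct,
            "total_weight_selected": self.total_weight_selected,
        }


def _make_result(
    accepted: list[int],
    n_input: int,
    mode: str,
    k: int,
    b: float,
    canonical: bool,
    offset: int,
    bin_width: int,
    paired: bool = False,
    total_weight: Optional[float] = None,
) -> NormalizationResult:
    n_acc = len(accepted)
    reduction = 100.0 * (1.0 - n_acc / n_input) if n_input else 0.0
    return NormalizationResult(
        accepted=np.asarray(accepted, dtype=np.int64),
        mode=mode,
        k=k,
        b=b,
        canonical=canonical,
        offset=offset,
        bin_width=bin_width,
        n_input=n_input,
        n_accepted=n_acc,
        reduction_pct=reduction,
        total_weight_selected=total_weight,
        paired=paired,
    )


def _check_consistency(counter: LabelCounter, thresholds: ThresholdTable) -> None:
    if thresholds.counter is not counter:
        # allow an equal-universe table built separately
        if len(thresholds.counter) != len(counter) or not np.array_equal(
            thresholds.counter.code_array, counter.code_array
        ):
            raise StateError(
                "threshold table references labels absent from the counter"
            )


def greedy_select(
    reads: Sequence[Read],
    ordering: Ordering,
    counter: LabelCounter,
    thresholds: ThresholdTable,
    k: Optional[int] = None,
    canonical: Optional[bool] = None,
    *,
    encoded: Optional[EncodedReads] = None,
    mode: str = "orna",
    offset: int = DEFAULT_PHRED_OFFSET,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> NormalizationResult:
    """One greedy pass over ``reads`` in the given order.

    A read is accepted iff at least one of its label occurrences is still
    below its threshold; on acceptance every label occurrence of the read
    increments the achieved count.  Reads with no valid labels are
    rejected (they cannot contribute to the cover).  ``result.accepted``
    lists indices in acceptance order.
    """
    k = counter.k if k is None else k
    canonical = counter.canonical if canonical is None else canonical
    if k != counter.k or canonical != counter.canonical:
        raise StateError("k/canonical flags disagree with the counter")
    _check_consistency(counter, thresholds)
    if encoded is None:
        encoded = encode_reads(reads, k, canonical)
    if encoded.n_reads != len(reads):
        raise StateError("encoded read count differs from read list")

    idx_all = counter.index_of(encoded.codes)
    t = thresholds.threshold_array
    ach = np.zeros(len(counter), dtype=np.int64)
    offs = encoded.offsets
    accepted: list[int] = []
    append = accepted.append
    add_at = np.add.at
    for i in ordering.order.tolist():
        s, e = offs[i], offs[i + 1]
        if e == s:
            continue
        sl = idx_all[s:e]
        if (ach[sl] < t[sl]).any():
            append(i)
            add_at(ach, sl, 1)
    return _make_result(
        accepted, len(reads), mode, k, thresholds.b, canonical, offset, bin_width
    )


def _selected_weight(scores: np.ndarray, accepted: np.ndarray) -> float:
    """W(R'): sum of inverse scores of the accepted reads (inf if any zero)."""
    if len(accepted) == 0:
        return 0.0
    s = scores[accepted]
    if (s == 0).any():
        return float("inf")
    return float(np.sum(1.0 / s))


def normalize_single(
    reads: Sequence[Read],
    mode: str = "orna",
    k: int = DEFAULT_K,
    b: float = DEFAULT_B,
    canonical: bool = True,
    offset: int = DEFAULT_PHRED_OFFSET,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> NormalizationResult:
    """Full single-end pipeline: count labels, derive thresholds, order
    reads per mode, greedily select.  Deterministic for fixed inputs."""
    if mode not in MODES:
        raise ParameterError(f"mode must be one of {MODES}, got {mode!r}")
    if len(reads) == 0:
        raise InputError("cannot normalize an empty read set")
    if mode == "orna-q" and any(r.qual is None for r in reads):
        raise ModeError("mode orna-q requires quality strings (FASTQ input)")

    encoded = encode_reads(reads, k, canonical)
    counter = LabelCounter.from_encoded(encoded)
    thresholds = compute_thresholds(counter, b)

    if mode == "orna":
        ordering = order_original(len(reads))
    elif mode == "orna-q":
        ordering = order_by_quality(reads, offset)
    else:
        ordering = order_by_abundance(reads, counter, bin_width, encoded=encoded)

    result = greedy_select(
        reads,
        ordering,
        counter,
        thresholds,
        encoded=encoded,
        mode=mode,
        offset=offset,
        bin_width=bin_width,
    )
    if mode in ("orna-q", "orna-k"):
        result.total_weight_selected = _selected_weight(
            ordering.scores.astype(np.float64), result.accepted
        )
    return result


def normalize_paired(
    pairs: Sequence[ReadPair],
    mode: str = "orna",
    k: int = DEFAULT_K,
    b: float = DEFAULT_B,
    canonical: bool = True,
    offset: int = DEFAULT_PHRED_OFFSET,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> NormalizationResult:
    """Three-stage paired-end normalization (see module docstring).

    The label universe and thresholds are built over BOTH mate files.
    ``result.accepted`` holds pair indices; output contains whole pairs
    only.
    """
    if mode not in MODES:
        raise ParameterError(f"mode must be one of {MODES}, got {mode!r}")
    n = len(pairs)
    if n == 0:
        raise InputError("cannot normalize an empty pair set")
    left = [p.left for p in pairs]
    right = [p.right for p in pairs]
    if mode == "orna-q" and any(
        r.qual is None for r in left + right
    ):
        raise ModeError("mode orna-q requires quality strings (FASTQ input)")

    enc_l = encode_reads(left, k, canonical)
    enc_r = encode_reads(right, k, canonical)
    combined = EncodedReads(
        k=k,
        canonical=canonical,
        codes=np.concatenate([enc_l.codes, enc_r.codes]),
        offsets=np.concatenate(
            [enc_l.offsets, enc_l.offsets[-1] + enc_r.offsets[1:]]
        ),
    )
    counter = LabelCounter.from_encoded(combined)
    thresholds = compute_thresholds(counter, b)
    t = thresholds.threshold_array

    # stage 1: pair scores and ordering
    pair_scores: Optional[np.ndarray] = None
    if mode == "orna":
        order = np.arange(n, dtype=np.int64)
    else:
        if mode == "orna-q":
            s = quality_scores(left, offset) + quality_scores(right, offset)
        else:
            s = (
                abundance_scores(left, counter, encoded=enc_l)
                + abundance_scores(right, counter, encoded=enc_r)
            ).astype(np.int64)
        pair_scores = s.astype(np.float64)
        order = _counting_sort_desc(s.astype(np.int64))

    idx_l = counter.index_of(enc_l.codes)
    idx_r = counter.index_of(enc_r.codes)
    offs_l = enc_l.offsets
    offs_r = enc_r.offsets
    ach = np.zeros(len(counter), dtype=np.int64)
    add_at = np.add.at

    def mate_slices(i: int) -> tuple[np.ndarray, np.ndarray]:
        return (
            idx_l[offs_l[i] : offs_l[i + 1]],
            idx_r[offs_r[i] : offs_r[i + 1]],
        )

    accepted: list[int] = []
    marked: list[int] = []
    # stage 2: accept pairs where both mates qualify; mark single-qualifiers
    for i in order.tolist():
        sl_l, sl_r = mate_slices(i)
        ok_l = bool(sl_l.size) and bool((ach[sl_l] < t[sl_l]).any())
        ok_r = bool(sl_r.size) and bool((ach[sl_r] < t[sl_r]).any())
        if ok_l and ok_r:
            accepted.append(i)
            add_at(ach, sl_l, 1)
            add_at(ach, sl_r, 1)
        elif ok_l or ok_r:
            marked.append(i)  # counts NOT incremented for marked pairs
    # stage 3: revisit marked pairs in first-encountered order
    for i in marked:
        sl_l, sl_r = mate_slices(i)
        ok = (bool(sl_l.size) and bool((ach[sl_l] < t[sl_l]).any())) or (
            bool(sl_r.size) and bool((ach[sl_r] < t[sl_r]).any())
        )
        if ok:
            accepted.append(i)
            add_at(ach, sl_l, 1)
            add_at(ach, sl_r, 1)

    total_weight: Optional[float] = None
    if pair_scores is not None:
        total_weight = _selected_weight(
            pair_scores, np.asarray(accepted, dtype=np.int64)
        )
    return _make_result(
        accepted,
        n,
        mode,
        k,
        b,
        canonical,
        offset,
        bin_width,
        paired=True,
        total_weight=total_weight,
    )


@dataclass(slots=True)
class CoverReport:
    """Outcome of an independent recount of the cover constraint."""

    passed: bool
    n_labels: int
    n_violated: int
    violated_labels: list[str] = field(default_factory=list)


def verify_cover(
    original: Sequence[Union[Read, ReadPair]],
    result: NormalizationResult,
    k: Optional[int] = None,
    b: Optional[float] = None,
    canonical: Optional[bool] = None,
    max_reported: int = 100,
) -> CoverReport:
    """Recount labels in the accepted set and check the cover constraint.

    For every label l of the original dataset the accepted set must hold
    at least ``min(t_l, abund(l, R))`` copies — the min caps the target at
    feasibility when b near 1 makes ``t_l`` exceed the available copies.
    """
    k = result.k if k is None else k
    b = result.b if b is None else b
    canonical = result.canonical if canonical is None else canonical

    if result.paired:
        reads: list[Read] = []
        for p in original:
            reads.append(p.left)
            reads.append(p.right)
        accepted_reads = []
        for i in result.accepted.tolist():
            accepted_reads.append(original[i].left)
            accepted_reads.append(original[i].right)
    else:
        reads = list(original)
        accepted_reads = [reads[i] for i in result.accepted.tolist()]

    counter = count_labels(reads, k, canonical)
    if len(counter) == 0:
        return CoverReport(passed=True, n_labels=0, n_violated=0)
    thresholds = compute_thresholds(counter, b)
    required = np.minimum(thresholds.threshold_array, counter.count_array)

    ach = np.zeros(len(counter), dtype=np.int64)
    if accepted_reads:
        enc = encode_reads(accepted_reads, k, canonical)
        idx = counter.index_of(enc.codes)
        np.add.at(ach, idx, 1)

    bad = ach < required
    violated = np.flatnonzero(bad)
    labels = _decode_codes(counter.code_array[violated[:max_reported]], k + 1)
    return CoverReport(
        passed=not bad.any(),
        n_labels=len(counter),
        n_violated=int(bad.sum()),
        violated_labels=labels,
    )
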