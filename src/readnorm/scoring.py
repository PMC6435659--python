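"""Per-read and per-pair scores and weights.

Two read scores drive the weighted normalization modes:

* the *read quality score* ``qr = sum of phred values over the read``,
  whose inverse ``qw = 1/qr`` is the phred quality weight (mode ``orna-q``), and
* the *read abundance score* ``kr = median of the read's label abundances
  in the original dataset``, whose inverse ``kw = 1/kr`` is the label
  abundance weight (mode ``orna-k``).

Minimizing total weight of the kept set is equivalent to preferring reads
of high base quality / high k-mer abundance, which are the reads least
likely to carry sequencing errors.

Median convention: the LOWER median (element ``(n-1)//2`` of the sorted
abundance list) is used for even-length lists.  It keeps ``kr`` integral,
which makes the ``orna-k`` bin ordering exact, and matches the convention of
count-based normalizers.  Zero-score reads (``qr == 0`` or no valid
labels) have undefined weight; the ordering code places them last.

Abundances are always looked up in the ORIGINAL dataset's counter, never
in the partially built output set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

from .errors import InputError, ModeError
from .io_fastq import DEFAULT_PHRED_OFFSET, Read, phred_values
from .kmer_core import EncodedReads, LabelCounter, encode_reads

__all__ = [
    "ReadScore",
    "PairScore",
    "read_quality_score",
    "read_abundance_score",
    "pair_score",
    "dataset_average_scores",
    "total_weight",
    "quality_scores",
    "abundance_scores",
    "lower_median",
]


@dataclass(slots=True)
class ReadScore:
    """Scores and derived weights of one read.

    ``qr`` is ``None`` for quality-less input; weights are ``None`` when
    undefined (score of zero).
    """

    qr: Optional[int] = None
    kr: Optional[float] = None

    @property
    def qw(self) -> Optional[float]:
        if self.qr is None or self.qr == 0:
            return None
        return 1.0 / self.qr

    @property
    def kw(self) -> Optional[float]:
        if self.kr is None or self.kr == 0:
            return None
        return 1.0 / self.kr


class PairScore(NamedTuple):
    """Sum of the two mates' scores and its inverse (None when undefined)."""

    pair_score: float
    pair_weight: Optional[float]


def read_quality_score(read: Read, offset: int = DEFAULT_PHRED_OFFSET) -> int:
    """Sum of decoded phred values over all bases of the read."""
    if read.qual is None:
        raise ModeError(
            f"read {read.id!r} has no quality string; "
            "quality scoring requires FASTQ input"
        )
    return sum(phred_values(read.qual, offset))


def lower_median(values: Sequence[float] | np.ndarray) -> float:
    """Lower median: element at index ``(n-1)//2`` of the sorted list."""
    arr = np.asarray(values)
    if arr.size == 0:
        return 0.0
    k = (arr.size - 1) // 2
    return float(np.partition(arr, k)[k])


def read_abundance_score(read: Read, counter: LabelCounter) -> float:
    """Lower median of the read's label abundances in the original dataset.

    Returns 0 for a read with no valid labels (too short, or every window
    contains a non-ACGT character).
    """
    encoded = encode_reads([read], counter.k, counter.canonical)
    if len(encoded.codes) == 0:
        return 0.0
    return lower_median(counter.abundances(encoded.codes))


def pair_score(left_score: float, right_score: float) -> PairScore:
    """Combine two mate scores; the pair weight is the inverse of the sum.

    A zero pair score leaves the weight undefined (sorts last).
    """
    if left_score < 0 or right_score < 0:
        raise InputError("read scores must be non-negative")
    s = left_score + right_score
    return PairScore(pair_score=s, pair_weight=(1.0 / s) if s > 0 else None)


def dataset_average_scores(
    reads: Sequence[Read],
    counter: Optional[LabelCounter] = None,
    offset: int = DEFAULT_PHRED_OFFSET,
    encoded: Optional[EncodedReads] = None,
) -> tuple[Optional[float], Optional[float]]:
    """Dataset means (Q̄, K̄) of the read quality and abundance scores.

    Q̄ is ``None`` for quality-less input; K̄ is ``None`` when no counter
    is supplied.  ``encoded`` may carry precomputed labels for ``reads``.
    """
    if len(reads) == 0:
        raise InputError("cannot average scores of an empty read set")
    mean_qr: Optional[float] = None
    if all(r.qual is not None for r in reads):
        mean_qr = float(np.mean(quality_scores(reads, offset)))
    mean_kr: Optional[float] = None
    if counter is not None:
        mean_kr = float(np.mean(abundance_scores(reads, counter, encoded=encoded)))
    return mean_qr, mean_kr


def total_weight(scores: Iterable[ReadScore], mode: str) -> float:
    """Total selected weight W(R'): sum of qw (quality) or kw (abundance).

    Any read with undefined weight makes the total infinite; a warning
    lists how many reads were affected.
    """
    if mode not in ("quality", "abundance"):
        raise InputError(f"mode must be 'quality' or 'abundance', got {mode!r}")
    total = 0.0
    undefined = 0
    for s in scores:
        w = s.qw if mode == "quality" else s.kw
        if w is None:
            undefined += 1
        else:
            total += w
    if undefined:
        warnings.warn(
            f"{undefined} read(s) have undefined {mode} weight (zero score); "
            "total weight is infinite",
            stacklevel=2,
        )
        return math.inf
    return total


# -- bulk helpers used by the normalizer ------------------------------


def quality_scores(
    reads: Sequence[Read], offset: int = DEFAULT_PHRED_OFFSET
) -> np.ndarray:
    """Vector of qr values for a read set (validates the encoding once)."""
    out = np.empty(len(reads), dtype=np.int64)
    min_char = None
    for i, r in enumerate(reads):
        if r.qual is None:
            raise ModeError(
                f"read {r.id!r} has no quality string; "
                "quality scoring requires FASTQ input"
            )
        q = r.qual.encode("ascii")
        out[i] = sum(q) - offset * len(q)
        m = min(q) if q else offset
        if min_char is None or m < min_char:
            min_char = m
    if min_char is not None and min_char < offset:
        # re-raise through the scalar path for a precise message
        bad = chr(min_char)
        phred_values(bad, offset)
    return out


def abundance_scores(
    reads: Sequence[Read],
    counter: LabelCounter,
    encoded: Optional[EncodedReads] = None,
) -> np.ndarray:
    """Vector of kr values (lower-median label abundance) for a read set."""
    if encoded is None:
        encoded = encode_reads(reads, counter.k, counter.canonical)
    abund = counter.abundances(encoded.codes)
    out = np.zeros(len(reads), dtype=np.float64)
    offs = encoded.offsets
    for i in range(len(reads)):
        sl = abund[offs[i] : offs[i + 1]]
        if sl.size:
            k = (sl.size - 1) // 2
            out[i] = np.partition(sl, k)[k]
    return out
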