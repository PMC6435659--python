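"""Dataset-level diagnostics: score distributions and before/after reports.

The positional profile divides the file into bins of ``bin_size`` reads
(real Illumina runs are profiled with bins of one million) and reports the
mean read quality score Q̄ and mean read abundance score K̄ per bin; the
profile exposes positional quality skew, e.g. low-quality reads clustered
at the start of a run.

``compare_datasets`` reports Q̄/K̄ for an original and a reduced dataset,
the reduction percentage, and label-universe retention.  kr values for
reduced reads are always computed against the ORIGINAL dataset's counter:
the read abundance score is defined over original abundances, so a
recount of the reduced set would measure something else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InputError
from .io_fastq import DEFAULT_PHRED_OFFSET, Read
from .kmer_core import LabelCounter, encode_reads
from .scoring import abundance_scores, quality_scores

__all__ = ["PositionalProfile", "positional_profile", "compare_datasets", "ComparisonReport"]


@dataclass(slots=True)
class PositionalProfile:
    """Per-positional-bin mean scores of a read file."""

    bin_size: int
    n_reads: int
    counts: list[int]
    mean_qr: Optional[list[float]]  # None for quality-less input
    mean_kr: Optional[list[float]]  # None when no counter was supplied

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def to_tsv(self) -> str:
        lines = ["bin_index\tn_reads\tmean_qr\tmean_kr"]
        for i in range(self.n_bins):
            q = f"{self.mean_qr[i]:.4f}" if self.mean_qr is not None else "NA"
            k = f"{self.mean_kr[i]:.4f}" if self.mean_kr is not None else "NA"
            lines.append(f"{i}\t{self.counts[i]}\t{q}\t{k}")
        return "\n".join(lines) + "\n"


def _bin_means(values: np.ndarray, bin_size: int) -> list[float]:
    return [
        float(values[i : i + bin_size].mean())
        for i in range(0, len(values), bin_size)
    ]


def positional_profile(
    reads: Sequence[Read],
    counter: Optional[LabelCounter] = None,
    bin_size: int = 1_000_000,
    offset: int = DEFAULT_PHRED_OFFSET,
) -> PositionalProfile:
    """Mean qr/kr per positional bin of ``bin_size`` consecutive reads."""
    if bin_size < 1:
        raise InputError(f"bin_size must be >= 1, got {bin_size}")
    n = len(reads)
    if n == 0:
        raise InputError("cannot profile an empty dataset")
    counts = [min(bin_size, n - i) for i in range(0, n, bin_size)]
    mean_qr = None
    if all(r.qual is not None for r in reads):
        mean_qr = _bin_means(quality_scores(reads, offset).astype(float), bin_size)
    mean_kr = None
    if counter is not None:
        mean_kr = _bin_means(abundance_scores(reads, counter), bin_size)
    return PositionalProfile(
        bin_size=bin_size, n_reads=n, counts=counts, mean_qr=mean_qr, mean_kr=mean_kr
    )


@dataclass(slots=True)
class ComparisonReport:
    """Before/after normalization comparison."""

    n_original: int
    n_reduced: int
    reduction_pct: float
    mean_qr_original: Optional[float]
    mean_qr_reduced: Optional[float]
    mean_kr_original: Optional[float]
    mean_kr_reduced: Optional[float]
    label_universe_retention_pct: float
    per_label: Optional[list[tuple[str, int, int]]] = None  # (label, orig, reduced)

    def to_dict(self) -> dict:
        d = {
            "n_original": self.n_original,
            "n_reduced": self.n_reduced,
            "reduction_pct": self.reduction_pct,
            "mean_qr_original": self.mean_qr_original,
            "mean_qr_reduced": self.mean_qr_reduced,
            "mean_kr_original": self.mean_kr_original,
            "mean_kr_reduced": self.mean_kr_reduced,
            "label_universe_retention_pct": self.label_universe_retention_pct,
        }
        if self.per_label is not None:
            d["per_label"] = [list(row) for row in self.per_label]
        return d


def compare_datasets(
    original: Sequence[Read],
    reduced: Sequence[Read],
    counter: Optional[LabelCounter] = None,
    offset: int = DEFAULT_PHRED_OFFSET,
    include_labels: bool = False,
) -> ComparisonReport:
    """Compare mean scores and label retention of a reduced dataset.

    ``counter`` must be built from the ORIGINAL dataset; when omitted, kr
    statistics and label retention are skipped.  ``reduced`` must be a
    subset of ``original`` by read identity.
    """
    if len(original) == 0:
        raise InputError("original dataset is empty")
    ids = set(r.id for r in original)
    for r in reduced:
        if r.id not in ids:
            raise InputError(f"reduced read {r.id!r} absent from original dataset")

    has_qual = all(r.qual is not None for r in original)
    mean_qr_orig = (
        float(quality_scores(original, offset).mean()) if has_qual else None
    )
    mean_qr_red = (
        float(quality_scores(reduced, offset).mean())
        if has_qual and len(reduced)
        else None
    )

    mean_kr_orig = mean_kr_red = None
    retention = 100.0
    per_label = None
    if counter is not None:
        mean_kr_orig = float(abundance_scores(original, counter).mean())
        if len(reduced):
            mean_kr_red = float(abundance_scores(reduced, counter).mean())
        # universe retention: fraction of original labels present in reduced
        if len(counter):
            if len(reduced):
                enc = encode_reads(reduced, counter.k, counter.canonical)
                present = np.unique(enc.codes)
                kept = np.isin(counter.code_array, present, assume_unique=True)
            else:
                kept = np.zeros(len(counter), dtype=bool)
            retention = 100.0 * float(kept.mean())
            if include_labels:
                red_counts = np.zeros(len(counter), dtype=np.int64)
                if len(reduced):
                    idx = counter.index_of(enc.codes, strict=False)
                    hit = idx >= 0
                    np.add.at(red_counts, idx[hit], 1)
                per_label = [
                    (lab, int(c), int(rc))
                    for (lab, c), rc in zip(counter.items(), red_counts)
                ]

    n, m = len(original), len(reduced)
    return ComparisonReport(
        n_original=n,
        n_reduced=m,
        reduction_pct=100.0 * (1.0 - m / n),
        mean_qr_original=mean_qr_orig,
        mean_qr_reduced=mean_qr_red,
        mean_kr_original=mean_kr_orig,
        mean_kr_reduced=mean_kr_red,
        label_universe_retention_pct=retention,
        per_label=per_label,
    )
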