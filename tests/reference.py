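"""Independent straight-line reference implementations used as oracles.

Everything here is deliberately naive and shares no code with the package:
dict-based counting, string slicing, per-step recounts of achieved
coverage.  Tests compare the package's vectorized implementations against
these on small instances.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def ref_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def ref_labels(seq: str, k: int, canonical: bool) -> list[str]:
    width = k + 1
    seq = seq.upper()
    out = []
    for i in range(len(seq) - width + 1):
        sub = seq[i : i + width]
        if all(c in _COMP for c in sub):
            if canonical:
                sub = min(sub, ref_revcomp(sub))
            out.append(sub)
    return out


def ref_count(reads, k: int, canonical: bool) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in reads:
        for lab in ref_labels(r.seq, k, canonical):
            counts[lab] = counts.get(lab, 0) + 1
    return counts


def ref_threshold(abund: int, b: float) -> int:
    """Smallest t >= 1 with b**t >= abund (== max(1, ceil(log_b abund)))."""
    t = 1
    while b**t < abund:
        t += 1
    return t


def ref_qr(read, offset: int = 33) -> int:
    return sum(ord(c) - offset for c in read.qual)


def ref_kr(read, counts: dict[str, int], k: int, canonical: bool) -> int:
    labs = ref_labels(read.seq, k, canonical)
    if not labs:
        return 0
    vals = sorted(counts[lab] for lab in labs)
    return vals[(len(vals) - 1) // 2]  # lower median


def ref_sort_desc(scores) -> list[int]:
    """Generic stable sort, descending score."""
    return sorted(range(len(scores)), key=lambda i: -scores[i])


def ref_order(reads, mode: str, counts, k, canonical, bin_width=1) -> list[int]:
    if mode == "orna":
        return list(range(len(reads)))
    if mode == "orna-q":
        return ref_sort_desc([ref_qr(r) for r in reads])
    if mode == "orna-k":
        return ref_sort_desc(
            [ref_kr(r, counts, k, canonical) // bin_width for r in reads]
        )
    raise ValueError(mode)


def ref_greedy(reads, order, k: int, canonical: bool, b: float) -> list[int]:
    """Naive greedy: achieved coverage recounted from scratch per step."""
    counts = ref_count(reads, k, canonical)
    t = {lab: ref_threshold(a, b) for lab, a in counts.items()}
    accepted: list[int] = []
    for i in order:
        labs = ref_labels(reads[i].seq, k, canonical)
        if not labs:
            continue
        achieved: dict[str, int] = {}
        for j in accepted:
            for lab in ref_labels(reads[j].seq, k, canonical):
                achieved[lab] = achieved.get(lab, 0) + 1
        if any(achieved.get(lab, 0) < t[lab] for lab in labs):
            accepted.append(i)
    return accepted


def ref_normalize_single(reads, mode, k, canonical, b, bin_width=1) -> list[int]:
    counts = ref_count(reads, k, canonical)
    order = ref_order(reads, mode, counts, k, canonical, bin_width)
    return ref_greedy(reads, order, k, canonical, b)


def ref_greedy_paired(pairs, mode, k, canonical, b, bin_width=1) -> list[int]:
    """Naive three-stage paired greedy (recount per step)."""
    reads = [p.left for p in pairs] + [p.right for p in pairs]
    counts = ref_count(reads, k, canonical)
    t = {lab: ref_threshold(a, b) for lab, a in counts.items()}

    if mode == "orna":
        order = list(range(len(pairs)))
    else:
        if mode == "orna-q":
            scores = [ref_qr(p.left) + ref_qr(p.right) for p in pairs]
        else:
            scores = [
                ref_kr(p.left, counts, k, canonical)
                + ref_kr(p.right, counts, k, canonical)
                for p in pairs
            ]
        order = ref_sort_desc(scores)

    achieved: dict[str, int] = {}

    def qualifies(read) -> bool:
        labs = ref_labels(read.seq, k, canonical)
        return bool(labs) and any(achieved.get(lab, 0) < t[lab] for lab in labs)

    def add(read) -> None:
        for lab in ref_labels(read.seq, k, canonical):
            achieved[lab] = achieved.get(lab, 0) + 1

    accepted: list[int] = []
    marked: list[int] = []
    for i in order:
        ok_l, ok_r = qualifies(pairs[i].left), qualifies(pairs[i].right)
        if ok_l and ok_r:
            accepted.append(i)
            add(pairs[i].left)
            add(pairs[i].right)
        elif ok_l or ok_r:
            marked.append(i)
    for i in marked:
        if qualifies(pairs[i].left) or qualifies(pairs[i].right):
            accepted.append(i)
            add(pairs[i].left)
            add(pairs[i].right)
    return accepted
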