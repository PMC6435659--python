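"""Greedy selection, orderings, paired three-stage procedure, cover checks."""

import numpy as np
import pytest

from readnorm import (
    InputError,
    ModeError,
    Read,
    ReadPair,
    StateError,
    compute_thresholds,
    count_labels,
    greedy_select,
    normalize_paired,
    normalize_single,
    order_by_abundance,
    order_by_quality,
    order_original,
    order_random,
    verify_cover,
)
from readnorm.kmer_core import encode_reads
from readnorm.normalize import NormalizationResult, Ordering

from conftest import random_pairs, random_reads
from reference import (
    ref_greedy,
    ref_greedy_paired,
    ref_kr,
    ref_normalize_single,
    ref_qr,
    ref_sort_desc,
    ref_count,
)


def _four_reads(with_quals=False):
    quals = ["!!!!!", "IIIII", "88888", "IIIII"]
    return [
        Read(f"r{i}", s, quals[i] if with_quals else None)
        for i, s in enumerate(["AAAAA", "AAAAA", "AAAAA", "AAAAC"])
    ]


class TestOrderings:
    def test_quality_sort_descending(self):
        reads = [Read("a", "AAA", "&&&"), Read("b", "AAA", "##!"), Read("c", "AAA", "+++")]
        # qr: 15, 4, 30 -> descending [c, a, b]
        o = order_by_quality(reads)
        assert o.order.tolist() == [2, 0, 1]

    def test_quality_sort_stable_on_ties(self):
        reads = [Read(str(i), "AAA", "III") for i in range(3)]
        assert order_by_quality(reads).order.tolist() == [0, 1, 2]

    def test_quality_sort_matches_generic_stable_sort(self):
        rng = np.random.default_rng(11)
        reads = [
            Read(str(i), "A" * 8, "".join(chr(33 + q) for q in rng.integers(0, 42, 8)))
            for i in range(1000)
        ]
        o = order_by_quality(reads)
        assert o.order.tolist() == ref_sort_desc([ref_qr(r) for r in reads])

    def test_abundance_binsort_hand_case(self):
        reads = [Read("a", "AAAAA"), Read("b", "AAAAC"), Read("c", "AAAAA")]
        counter = count_labels(reads, 3, canonical=False)
        # kr: a=5, b=1 (lower median of [1,5]), c=5
        o = order_by_abundance(reads, counter, bin_width=1)
        assert o.order.tolist() == [0, 2, 1]
        # coarse bins collapse everything into bin 0: original order kept
        o10 = order_by_abundance(reads, counter, bin_width=10)
        assert o10.order.tolist() == [0, 1, 2]

    def test_missing_quality_is_mode_error(self):
        with pytest.raises(ModeError):
            order_by_quality([Read("a", "ACGT")])

    def test_random_order_is_seeded_permutation(self):
        o1, o2 = order_random(50, 7), order_random(50, 7)
        assert (o1.order == o2.order).all()
        assert sorted(o1.order.tolist()) == list(range(50))

    def test_non_permutation_rejected(self):
        with pytest.raises(StateError):
            Ordering(order=np.array([0, 0, 2]), strategy="original")


class TestGreedySelect:
    def test_worked_example_original_order(self):
        """abund(AAAA)=7 -> t=3; read 2 rejected after 4 copies accepted."""
        reads = _four_reads()
        counter = count_labels(reads, 3, canonical=False)
        thresholds = compute_thresholds(counter, 2.0)
        res = greedy_select(reads, order_original(4), counter, thresholds)
        assert res.accepted.tolist() == [0, 1, 3]
        assert res.reduction_pct == pytest.approx(25.0)

    def test_all_thresholds_one_gives_prefix_hitting_set(self):
        rng = np.random.default_rng(3)
        reads = random_reads(rng, 40, n_rate=0.0)
        counter = count_labels(reads, 3, canonical=False)
        thresholds = compute_thresholds(counter, 1e9)  # all t_l = 1
        assert (thresholds.threshold_array == 1).all()
        res = greedy_select(reads, order_original(len(reads)), counter, thresholds)
        kept = count_labels([reads[i] for i in res.accepted], 3, canonical=False)
        assert set(kept.as_dict()) == set(counter.as_dict())

    def test_single_read_dataset_accepted(self):
        reads = [Read("r", "ACGTACGT", "IIIIIIII")]
        res = normalize_single(reads, mode="orna", k=3, b=2, canonical=False)
        assert res.accepted.tolist() == [0]

    def test_zero_label_reads_rejected(self):
        reads = [Read("a", "NNNNNNNN"), Read("b", "ACGTACGT")]
        res = normalize_single(reads, mode="orna", k=3, b=2, canonical=False)
        assert res.accepted.tolist() == [1]

    def test_mismatched_thresholds_raise_state_error(self):
        reads = _four_reads()
        counter = count_labels(reads, 3, canonical=False)
        other = count_labels([Read("x", "GGGGG")], 3, canonical=False)
        thresholds = compute_thresholds(other, 2.0)
        with pytest.raises(StateError):
            greedy_select(reads, order_original(4), counter, thresholds)


class TestNormalizeSingle:
    def test_worked_example_quality_mode(self):
        """qr = [0,200,115,200]: processing order [1,3,2,0]; the qr=0 read
        is ordered last and rejected; output equals the naive oracle."""
        reads = _four_reads(with_quals=True)
        o = order_by_quality(reads)
        assert o.order.tolist() == [1, 3, 2, 0]
        res = normalize_single(reads, mode="orna-q", k=3, b=2, canonical=False)
        expected = ref_normalize_single(reads, "orna-q", 3, False, 2)
        assert res.accepted.tolist() == expected == [1, 3]
        assert 0 not in res.accepted

    def test_every_read_essential_keeps_all(self):
        reads = [Read("a", "AAAA"), Read("b", "CCCC"), Read("c", "GGGG")]
        res = normalize_single(reads, mode="orna", k=3, b=2, canonical=False)
        assert res.accepted.tolist() == [0, 1, 2]

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            normalize_single([])

    def test_quality_mode_needs_quals(self):
        with pytest.raises(ModeError):
            normalize_single([Read("a", "ACGT")], mode="orna-q", k=2)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        reads = random_reads(rng, 60)
        r1 = normalize_single(reads, mode="orna-k", k=4, b=1.7, canonical=True)
        r2 = normalize_single(reads, mode="orna-k", k=4, b=1.7, canonical=True)
        assert r1.accepted.tolist() == r2.accepted.tolist()
        assert r1.to_dict() == r2.to_dict()

    @pytest.mark.parametrize("mode", ["orna", "orna-q", "orna-k"])
    def test_matches_naive_reference_pipeline(self, mode):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            reads = random_reads(rng, 30)
            res = normalize_single(reads, mode=mode, k=3, b=1.7, canonical=True)
            assert res.accepted.tolist() == ref_normalize_single(
                reads, mode, 3, True, 1.7
            )

    def test_arbitrary_ordering_against_oracle(self):
        """greedy_select agrees with the oracle on shuffled orderings too."""
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            reads = random_reads(rng, 25)
            enc = encode_reads(reads, 3, True)
            counter = count_labels(reads, 3, True, encoded=enc)
            thresholds = compute_thresholds(counter, 2.0)
            ordering = order_random(len(reads), seed)
            res = greedy_select(reads, ordering, counter, thresholds, encoded=enc)
            assert res.accepted.tolist() == ref_greedy(
                reads, ordering.order.tolist(), 3, True, 2.0
            )


class TestNormalizePaired:
    def _pairs(self, rights, left_seq="AAAAA", qual=None):
        return [
            ReadPair(
                left=Read(f"p{i}/1", left_seq, qual),
                right=Read(f"p{i}/2", r, qual if qual and len(qual) == len(r) else None),
                index=i,
            )
            for i, r in enumerate(rights)
        ]

    def test_three_stage_hand_simulation(self):
        """Identical left mates saturate AAAA after two pairs; distinct
        right mates rescue pairs 2-4 in stage 3; a duplicate right mate is
        rejected."""
        rights = ["CCCCC", "GGGGG", "TTTTT", "ACACA", "AGAGA", "TTTTT"]
        pairs = self._pairs(rights)
        # abund(AAAA) = 12 -> t = ceil(log2 12) = 4
        res = normalize_paired(pairs, mode="orna", k=3, b=2, canonical=False)
        assert res.accepted.tolist() == [0, 1, 2, 3, 4]
        assert res.paired is True
        assert res.accepted.tolist() == ref_greedy_paired(
            pairs, "orna", 3, False, 2
        )

    def test_single_pair_accepted_in_stage_two(self):
        pairs = self._pairs(["CCCCC"])
        res = normalize_paired(pairs, mode="orna", k=3, b=2, canonical=False)
        assert res.accepted.tolist() == [0]

    def test_duplicate_pair_rejected_when_covered(self):
        pairs = self._pairs(["CCCCC", "CCCCC"])
        # b large: every t_l = 1; second pair has no uncovered label in
        # either mate -> rejected outright in stage 2
        res = normalize_paired(pairs, mode="orna", k=3, b=100.0, canonical=False)
        assert res.accepted.tolist() == [0]

    @pytest.mark.parametrize("mode", ["orna", "orna-q", "orna-k"])
    def test_matches_naive_reference(self, mode):
        for seed in range(6):
            rng = np.random.default_rng(40 + seed)
            pairs = random_pairs(rng, 15)
            res = normalize_paired(pairs, mode=mode, k=3, b=1.7, canonical=True)
            assert res.accepted.tolist() == ref_greedy_paired(
                pairs, mode, 3, True, 1.7
            )

    def test_output_contains_whole_pairs_only(self):
        rng = np.random.default_rng(9)
        pairs = random_pairs(rng, 30)
        res = normalize_paired(pairs, mode="orna-q", k=3, b=1.7)
        acc = res.accepted.tolist()
        assert len(set(acc)) == len(acc)
        assert all(0 <= i < len(pairs) for i in acc)
        assert res.n_accepted <= len(pairs)


class TestVerifyCover:
    def test_normalizer_output_passes(self):
        rng = np.random.default_rng(2)
        reads = random_reads(rng, 50)
        res = normalize_single(reads, mode="orna", k=3, b=2)
        report = verify_cover(reads, res)
        assert report.passed and report.n_violated == 0

    def test_deleting_an_essential_read_fails(self):
        """Falsifiability: drop an accepted read carrying a unique label."""
        import dataclasses

        reads = [Read("a", "AAAAA"), Read("b", "CCCCC"), Read("c", "AAAAA")]
        res = normalize_single(reads, mode="orna", k=3, b=2, canonical=False)
        tampered = dataclasses.replace(
            res,
            accepted=np.array(
                [i for i in res.accepted.tolist() if i != 1], dtype=np.int64
            ),
        )
        report = verify_cover(reads, tampered)
        assert not report.passed
        assert "CCCC" in report.violated_labels or report.n_violated > 0

    def test_empty_label_universe_passes_vacuously(self):
        reads = [Read("a", "AC"), Read("b", "GT")]  # too short for k=3
        res = normalize_single(reads, mode="orna", k=3, b=2)
        assert res.n_accepted == 0
        assert verify_cover(reads, res).passed

    def test_paired_result_verified_over_both_mates(self):
        rng = np.random.default_rng(12)
        pairs = random_pairs(rng, 25)
        res = normalize_paired(pairs, mode="orna-k", k=3, b=1.7)
        assert verify_cover(pairs, res).passed


class TestCoverInvariant:
    """Every original label retained >= min(t_l, abund) in all modes."""

    @pytest.mark.parametrize("mode", ["orna", "orna-q", "orna-k"])
    @pytest.mark.parametrize("b", [1.3, 2.0, 8.0])
    def test_single_end(self, mode, b):
        for seed in range(4):
            rng = np.random.default_rng(1000 * seed + int(b * 10))
            reads = random_reads(rng, 80)
            res = normalize_single(reads, mode=mode, k=3, b=b)
            assert verify_cover(reads, res).passed

    @pytest.mark.parametrize("mode", ["orna", "orna-q", "orna-k"])
    def test_paired(self, mode):
        for seed in range(3):
            rng = np.random.default_rng(77 + seed)
            pairs = random_pairs(rng, 40)
            res = normalize_paired(pairs, mode=mode, k=3, b=1.7)
            assert verify_cover(pairs, res).passed


class TestOrderingSensitivity:
    def test_weighted_modes_raise_mean_scores(self, skew_fixture):
        """With low-quality reads early in the file, sorting by score keeps
        better reads than file order at the same cover guarantee."""
        reads, params = skew_fixture
        counter = count_labels(reads, params["k"], params["canonical"])
        results = {
            m: normalize_single(reads, mode=m, **params) for m in ("orna", "orna-q", "orna-k")
        }
        qr = np.array([ref_qr(r) for r in reads])
        from readnorm.scoring import abundance_scores

        kr = abundance_scores(reads, counter)
        mean_qr = {m: qr[r.accepted].mean() for m, r in results.items()}
        mean_kr = {m: kr[r.accepted].mean() for m, r in results.items()}
        assert mean_qr["orna-q"] >= mean_qr["orna"]
        assert mean_kr["orna-k"] >= mean_kr["orna"]


class TestReductionVsB:
    def test_accepted_count_nonincreasing_in_b(self, skew_fixture):
        reads, params = skew_fixture
        for mode in ("orna", "orna-q", "orna-k"):
            counts = [
                normalize_single(
                    reads, mode=mode, k=params["k"], b=b, canonical=params["canonical"]
                ).n_accepted
                for b in (1.3, 1.7, 2, 4, 8)
            ]
            assert counts == sorted(counts, reverse=True) or all(
                c1 >= c2 for c1, c2 in zip(counts, counts[1:])
            )
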