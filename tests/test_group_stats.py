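from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from flyfitness.group_stats import (
    GroupedValues,
    PairwiseResult,
    bh_adjust,
    bonferroni_adjust,
    compact_letter_display,
    dunn_test,
    kruskal_wallis,
    logrank_test,
    pairwise_logrank,
    rank_sum_test,
)
from flyfitness.vial_data import SurvivalRecord


def grouped(**kwargs):
    values, labels = [], []
    for g, vals in kwargs.items():
        values.extend(vals)
        labels.extend([g] * len(vals))
    return GroupedValues(values=values, group_labels=labels)


class TestKruskalWallis:
    def test_hand_computed_h(self):
        # ranks 1-6, no ties: H = 12/(6*7) * 2 * 3 * 1.5^2 = 27/7
        h, p = kruskal_wallis(grouped(a=[1, 2, 3], b=[4, 5, 6]))
        assert h == pytest.approx(27 / 7, abs=1e-12)

    def test_identical_observations(self):
        h, _ = kruskal_wallis(grouped(a=[2, 2, 2], b=[2, 2]))
        assert h == 0.0

    def test_matches_rank_formula_with_ties(self, rng):
        # brute-force H from first principles, tie-corrected
        for _ in range(20):
            a = rng.integers(0, 4, 4).astype(float)
            b = rng.integers(0, 4, 3).astype(float)
            c = rng.integers(0, 4, 4).astype(float)
            allv = np.concatenate([a, b, c])
            if np.ptp(allv) == 0:
                continue
            ranks = stats.rankdata(allv)
            n = allv.size
            h = 12 / (n * (n + 1)) * sum(
                len(g) * (r.mean() - (n + 1) / 2) ** 2
                for g, r in [(a, ranks[:4]), (b, ranks[4:7]), (c, ranks[7:])]
            )
            _, counts = np.unique(allv, return_counts=True)
            h /= 1 - np.sum(counts**3 - counts) / (n**3 - n)
            got, _ = kruskal_wallis(grouped(a=a, b=b, c=c))
            assert got == pytest.approx(h, abs=1e-10)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis(grouped(a=[1, 2, 3]))


class TestDunn:
    def test_two_group_z_squared_equals_h(self, rng):
        for _ in range(10):
            a = rng.integers(0, 6, 5).astype(float)
            b = rng.integers(0, 6, 7).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            h, _ = kruskal_wallis(grouped(a=a, b=b))
            res = dunn_test(grouped(a=a, b=b), adjust="none")
            (_, _, z, _, _) = res.pairs[0]
            assert z**2 == pytest.approx(h, rel=1e-10)

    def test_three_group_fixture_frozen(self):
        # z values frozen from an independent mid-rank computation
        data = grouped(
            A=[2.1, 2.3, 2.0, 2.4], B=[1.6, 1.8, 1.7], C=[2.0, 1.9, 2.2, 2.1, 1.8]
        )
        res = dunn_test(data, adjust="none")
        by_pair = {(a, b): (z, p) for a, b, z, p, _ in res.pairs}
        assert by_pair[("A", "B")][0] == pytest.approx(2.6770787809214047, abs=1e-10)
        assert by_pair[("A", "C")][0] == pytest.approx(1.1637773409265297, abs=1e-10)
        assert by_pair[("B", "C")][0] == pytest.approx(-1.73075825754326, abs=1e-10)
        assert by_pair[("A", "B")][1] == pytest.approx(0.007426717004348681, abs=1e-12)

    def test_identical_groups_all_p_one(self):
        res = dunn_test(grouped(a=[1, 1], b=[1, 1], c=[1, 1]))
        assert all(q == pytest.approx(1.0) for *_, q in res.pairs)

    def test_adjusted_never_below_raw(self, rng):
        data = grouped(
            a=rng.normal(0, 1, 6), b=rng.normal(1, 1, 6), c=rng.normal(0.5, 1, 6)
        )
        res = dunn_test(data)
        assert all(q >= p - 1e-15 for _, _, _, p, q in res.pairs)


class TestAdjustments:
    def test_bh_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_single_p_unchanged(self):
        assert bh_adjust([0.3]) == [pytest.approx(0.3)]

    def test_bh_step_up_by_hand(self):
        # sorted p * m / rank = (0.03, 0.045, 0.04), then running min from
        # the largest: (0.03, 0.04, 0.04), mapped back to input order
        assert bh_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.04, 0.04])

    def test_bh_monotone_in_p_ordering(self, rng):
        p = rng.uniform(0, 1, 12)
        adj = np.asarray(bh_adjust(p))
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        # a flat adjusted vector is a fixed point
        assert bh_adjust([0.04, 0.04, 0.04, 0.04]) == pytest.approx([0.04] * 4)

    def test_bonferroni_mgwa_scale(self):
        # one raw p of 1e-4 across 431 pattern groups
        assert bonferroni_adjust([0.0001], m=431) == [pytest.approx(0.0431)]

    def test_bonferroni_caps_at_one(self):
        assert bonferroni_adjust([0.3, 0.001]) == [pytest.approx(0.6), pytest.approx(0.002)]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bonferroni_adjust([-0.1])


def recs(label, times, events):
    return [SurvivalRecord(f"v{i}", label, t, e) for i, (t, e) in enumerate(zip(times, events))]


class TestLogrank:
    def test_identical_curves_zero(self):
        records = recs("a", [3, 5, 8, 10], [1, 1, 0, 1]) + recs(
            "b", [3, 5, 8, 10], [1, 1, 0, 1]
        )
        chi2, p = logrank_test(records, "a", "b")
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_hypergeometric_tabulation(self):
        # group a dies at 1,2,3; group b at 4,5,6 — frozen from a from-scratch
        # observed-minus-expected tabulation over the six event times
        records = recs("a", [1, 2, 3], [1, 1, 1]) + recs("b", [4, 5, 6], [1, 1, 1])
        chi2, p = logrank_test(records, "a", "b")
        assert chi2 == pytest.approx(5.051660516605167, rel=1e-9)
        assert p == pytest.approx(0.024602349953641744, rel=1e-6)

    def test_censoring_only_group(self):
        records = recs("a", [5, 6, 7], [0, 0, 0]) + recs("b", [1, 2, 3], [1, 1, 1])
        chi2, p = logrank_test(records, "a", "b")
        assert np.isfinite(chi2) and p < 1

    def test_relabeling_invariance(self):
        ra = recs("a", [1, 4, 6], [1, 1, 0]) + recs("b", [2, 5, 9], [1, 0, 1])
        rb = recs("b", [1, 4, 6], [1, 1, 0]) + recs("a", [2, 5, 9], [1, 0, 1])
        assert logrank_test(ra, "a", "b")[0] == pytest.approx(logrank_test(rb, "a", "b")[0])

    def test_late_censoring_time_irrelevant(self):
        # a fly censored after the last event contributes the same risk
        # sets no matter how far past that event its censoring time lies
        base = recs("a", [1, 4], [1, 1]) + recs("b", [2, 5], [1, 1])
        near = base + recs("a", [6], [0]) + recs("b", [6], [0])
        far = base + recs("a", [50], [0]) + recs("b", [600], [0])
        assert logrank_test(near, "a", "b")[0] == pytest.approx(
            logrank_test(far, "a", "b")[0]
        )

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            logrank_test(recs("a", [1], [0]) + recs("b", [2], [0]), "a", "b")

    def test_rank_sum_two_group(self):
        stat, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, rel=0.01)  # exact two-sided 2/20


def make_pairwise(groups, sig_pairs):
    pairs = []
    for a, b in combinations(groups, 2):
        p = 0.001 if (a, b) in sig_pairs or (b, a) in sig_pairs else 0.8
        pairs.append((a, b, 1.0, p, p))
    return PairwiseResult(pairs=pairs, method="synthetic")


class TestCompactLetterDisplay:
    def test_two_groups_significant(self):
        letters = compact_letter_display(make_pairwise("AB", {("A", "B")})).letters
        assert letters == {"A": "a", "B": "b"}

    def test_three_groups_one_significant(self):
        letters = compact_letter_display(make_pairwise("ABC", {("A", "B")})).letters
        assert letters == {"A": "a", "B": "b", "C": "ab"}

    def test_no_significant_pairs(self):
        letters = compact_letter_display(make_pairwise("ABCD", set())).letters
        assert set(letters.values()) == {"a"}

    def test_missing_pair_errors(self):
        res = PairwiseResult(pairs=[("A", "B", 1.0, 0.5, 0.5)], method="m")
        res.pairs = res.pairs  # only 1 of 3 pairs for ABC
        res.pairs.append(("A", "C", 1.0, 0.5, 0.5))
        with pytest.raises(ValueError, match="missing"):
            compact_letter_display(
                PairwiseResult(pairs=res.pairs + [("A", "D", 1, 0.5, 0.5)], method="m")
            )

    @pytest.mark.parametrize("n_groups", [2, 3, 4, 5])
    def test_invariant_exhaustive(self, n_groups):
        # share-a-letter <=> not significantly different, for every
        # possible significance pattern
        groups = "ABCDE"[:n_groups]
        all_pairs = list(combinations(groups, 2))
        for mask in range(2 ** len(all_pairs)):
            sig = {p for i, p in enumerate(all_pairs) if mask >> i & 1}
            letters = compact_letter_display(make_pairwise(groups, sig)).letters
            for a, b in all_pairs:
                share = bool(set(letters[a]) & set(letters[b]))
                assert share != ((a, b) in sig), (
                    f"pattern {sig}: {a}={letters[a]} {b}={letters[b]}"
                )

    def test_letters_from_logrank_pipeline(self):
        records = (
            recs("a", [1, 2, 3, 4, 5], [1] * 5)
            + recs("b", [1.5, 2.5, 3.5, 4.5, 5.5], [1] * 5)
            + recs("c", [20, 21, 22, 23, 24], [1] * 5)
        )
        letters = compact_letter_display(pairwise_logrank(records)).letters
        assert set(letters) == {"a", "b", "c"}
        assert set(letters["a"]) & set(letters["b"])
        assert not set(letters["a"]) & set(letters["c"])
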