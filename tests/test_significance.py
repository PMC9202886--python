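import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from deltacc import (
    InteractionSets,
    SignificanceTable,
    ValidationError,
    add_merged_q,
    classify_sets,
    curate_local_peaks,
    merge_q,
    replicated_significant,
)

from conftest import iv

unit = st.floats(min_value=0.0, max_value=1.0)


def sig_table(q_pairs, merged=None, start=0):
    """Build a two-replicate table from (q1, q2) pairs on consecutive fragments."""
    n = len(q_pairs)
    df = pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "start": [start + i * 100 for i in range(n)],
            "end": [start + (i + 1) * 100 for i in range(n)],
            "p_rep1": [q1 / 2 for q1, _ in q_pairs],
            "q_rep1": [q1 for q1, _ in q_pairs],
            "p_rep2": [q2 / 2 for _, q2 in q_pairs],
            "q_rep2": [q2 for _, q2 in q_pairs],
        }
    )
    if merged is not None:
        df["merged_q"] = merged
    return SignificanceTable(df)


class TestMergeQ:
    def test_equal_values_are_fixed_points(self):
        assert merge_q(0.01, 0.01) == pytest.approx(0.01)

    def test_hand_computed_geometric_mean(self):
        assert merge_q(0.04, 0.09) == pytest.approx(0.06)

    def test_zero_annihilates(self):
        assert merge_q(0.0, 0.5) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            merge_q(0.5, 1.2)
        with pytest.raises(ValidationError):
            merge_q(-0.1, 0.5)

    def test_generalizes_to_three_replicates(self):
        assert merge_q([0.1, 0.2, 0.4]) == pytest.approx((0.1 * 0.2 * 0.4) ** (1 / 3))

    @given(unit, unit)
    def test_symmetric_and_bounded(self, q1, q2):
        m = merge_q(q1, q2)
        assert m == pytest.approx(merge_q(q2, q1))
        assert min(q1, q2) - 1e-12 <= m <= max(q1, q2) + 1e-12

    @given(unit, unit, unit)
    def test_monotone_in_each_argument(self, q1, q2, q3):
        lo, hi = sorted((q2, q3))
        assert merge_q(q1, lo) <= merge_q(q1, hi) + 1e-12

    def test_add_merged_q_column(self):
        t = add_merged_q(sig_table([(0.04, 0.09), (0.25, 0.01)]))
        assert t.data["merged_q"].tolist() == pytest.approx([0.06, 0.05])


class TestReplicatedSignificant:
    def test_one_failing_replicate_excludes(self):
        sets = replicated_significant({"esc": sig_table([(0.05, 0.2)])})
        assert sets["esc"] == set()

    def test_both_passing_replicates_include(self):
        sets = replicated_significant({"esc": sig_table([(0.05, 0.09)])})
        assert sets["esc"] == {iv(0, 100)}

    def test_union_semantics_across_cell_types(self):
        tracks = {
            "esc": sig_table([(0.05, 0.05), (0.5, 0.5)]),
            "neuron": sig_table([(0.5, 0.5), (0.5, 0.5)]),
        }
        sets = replicated_significant(tracks)
        assert sets["esc"] == {iv(0, 100)}
        assert sets["neuron"] == set()
        assert sets.union == {iv(0, 100)}

    def test_threshold_is_strict(self):
        sets = replicated_significant({"esc": sig_table([(0.1, 0.05)])})
        assert sets["esc"] == set()  # q == threshold does not pass q < threshold

    def test_single_replicate_cell_type_rejected(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100],
             "p_rep1": [0.01], "q_rep1": [0.01]}
        )
        with pytest.raises(ValidationError, match="replicate"):
            replicated_significant({"esc": SignificanceTable(df)})


class TestCurateLocalPeaks:
    def test_hand_scan_of_local_maxima(self):
        # -log10 merged q = (1, 3, 2, 0.5, 5, 4); threshold q<0.05 ~ 1.301
        scores = [1.0, 3.0, 2.0, 0.5, 5.0, 4.0]
        t = sig_table([(0.5, 0.5)] * 6, merged=[10.0 ** -s for s in scores])
        curated = curate_local_peaks(t, window=1, q_threshold=0.05)
        assert curated == [iv(100, 200), iv(400, 500)]

    def test_monotone_significance_curates_only_the_last(self):
        merged = [10.0 ** -s for s in (2.0, 3.0, 4.0, 5.0)]
        t = sig_table([(0.5, 0.5)] * 4, merged=merged)
        assert curate_local_peaks(t, window=2) == [iv(300, 400)]

    def test_nothing_above_threshold_curates_nothing(self):
        t = sig_table([(1.0, 1.0)] * 4, merged=[1.0] * 4)
        assert curate_local_peaks(t) == []

    def test_plateau_tie_broken_toward_leftmost(self):
        merged = [1.0, 0.001, 0.001, 1.0]
        t = sig_table([(0.5, 0.5)] * 4, merged=merged)
        assert curate_local_peaks(t, window=1) == [iv(100, 200)]

    def test_curated_fragments_never_within_window_of_each_other(self):
        rng = np.random.default_rng(13)
        merged = rng.uniform(1e-6, 1.0, size=50)
        t = sig_table([(0.5, 0.5)] * 50, merged=merged)
        curated = curate_local_peaks(t, window=2, q_threshold=0.5)
        starts = sorted(c.start // 100 for c in curated)
        assert all(b - a > 2 for a, b in zip(starts, starts[1:]))

    def test_requires_merged_q_and_valid_window(self):
        t = sig_table([(0.5, 0.5)])
        with pytest.raises(ValidationError, match="merged_q"):
            curate_local_peaks(t)
        with pytest.raises(ValidationError, match="window"):
            curate_local_peaks(add_merged_q(t), window=0)


class TestClassifySets:
    def test_hand_set_algebra(self):
        f1, f2 = iv(0, 100), iv(100, 200)
        counts = classify_sets(
            InteractionSets({"A": {f1, f2}, "B": {f2}, "C": set()})
        )
        assert counts[frozenset({"A", "B", "C"})] == 0
        assert counts[frozenset({"A", "B"})] == 1
        assert counts[frozenset({"A"})] == 1
        assert counts[frozenset({"B"})] == 0
        assert counts[frozenset({"C"})] == 0

    def test_identical_sets_are_all_shared(self):
        s = {iv(0, 100), iv(200, 300)}
        counts = classify_sets(InteractionSets({"A": set(s), "B": set(s)}))
        assert counts[frozenset({"A", "B"})] == 2
        assert counts[frozenset({"A"})] == 0

    def test_disjoint_sets_are_all_specific(self):
        counts = classify_sets(
            InteractionSets({"A": {iv(0, 100)}, "B": {iv(200, 300)}})
        )
        assert counts[frozenset({"A"})] == 1
        assert counts[frozenset({"B"})] == 1
        assert counts[frozenset({"A", "B"})] == 0

    def test_counts_sum_to_union_size(self):
        rng = np.random.default_rng(14)
        frags = [iv(i * 10, i * 10 + 10) for i in range(30)]
        sets = InteractionSets(
            {
                label: {f for f in frags if rng.random() < 0.4}
                for label in ("A", "B", "C")
            }
        )
        counts = classify_sets(sets)
        assert sum(counts.values()) == len(sets.union)

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValidationError):
            classify_sets(InteractionSets({"A": set()}))
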