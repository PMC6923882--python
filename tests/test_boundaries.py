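import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmdmarker import (
    ExpressionMatrix,
    GroupLabels,
    LabeledValues,
    boundary_table,
    candidate_splits,
    entropy,
    find_boundary,
    information_gain,
    three_class_boundaries,
)


def gain_oracle(values, labels, split):
    """Direct, unvectorised entropy bookkeeping for one split."""
    def ent(labs):
        n = len(labs)
        out = 0.0
        for c in set(labs):
            p = labs.count(c) / n
            out -= p * math.log2(p)
        return out

    pairs = list(zip(values, labels))
    left = [l for v, l in pairs if v <= split]
    right = [l for v, l in pairs if v > split]
    labs = list(labels)
    total = ent(labs)
    for child in (left, right):
        if child:
            total -= len(child) / len(labs) * ent(child)
    return total


def find_boundary_oracle(values, labels):
    """Exhaustive scan over midpoints of consecutive distinct values."""
    distinct = sorted(set(values))
    best = (None, -1.0)
    for a, b in zip(distinct, distinct[1:]):
        split = (a + b) / 2
        g = gain_oracle(values, labels, split)
        if g > best[1]:
            best = (split, g)
    return best


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [((5, 5), 1.0), ((7, 0), 0.0), ((3, 1), 0.811278), ((2, 2, 2), math.log2(3))],
    )
    def test_known_values(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-6)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            entropy((3, -1))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=1, max_size=6).filter(lambda c: sum(c) > 0))
    def test_bounded_by_log_class_count(self, counts):
        assert 0.0 <= entropy(counts) <= math.log2(len(counts)) + 1e-12


class TestCandidateSplits:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 2, 3], [1.5, 2.5]), ([1, 1, 2], [1.5]), ([5], []), ([4, 4, 4], [])],
    )
    def test_midpoints_of_distinct_values(self, values, expected):
        np.testing.assert_allclose(candidate_splits(values), expected)

    def test_no_split_collides_with_a_data_value(self):
        rng = np.random.default_rng(0)
        values = rng.integers(0, 10, 30).astype(float)
        assert not set(candidate_splits(values)) & set(values)


class TestInformationGain:
    def test_perfect_split_gain_equals_parent_entropy(self):
        data = LabeledValues([1, 2, 10, 11], ("n", "n", "t", "t"))
        assert information_gain(data, 6.0) == pytest.approx(1.0, abs=1e-12)

    def test_worked_example(self):
        data = LabeledValues([1, 2, 3, 6, 4, 5, 7, 8], ("n",) * 4 + ("t",) * 4)
        assert information_gain(data, 3.5) == pytest.approx(0.548795, abs=1e-6)

    def test_uninformative_split_gain_zero(self):
        # both children keep the 1:1 class mix
        data = LabeledValues([1, 2, 3, 4], ("n", "t", "n", "t"))
        assert information_gain(data, 2.5) == pytest.approx(0.0, abs=1e-12)

    def test_split_outside_range_rejected(self):
        data = LabeledValues([1, 2], ("n", "t"))
        with pytest.raises(ValueError, match="outside"):
            information_gain(data, 5.0)

    def test_gain_bounded_by_parent_entropy(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = rng.integers(4, 20)
            values = rng.uniform(0, 10, n)
            labels = tuple(rng.choice(["a", "b", "c"], n))
            if len(set(labels)) < 2:
                continue
            data = LabeledValues(values, labels)
            parent = entropy(list(data.class_counts().values()))
            for split in candidate_splits(values):
                g = information_gain(data, split)
                assert -1e-12 <= g <= parent + 1e-12


class TestFindBoundary:
    def test_separable_case_picks_gap_midpoint(self):
        data = LabeledValues([1, 2, 3, 4, 5, 6], ("n",) * 3 + ("t",) * 3)
        threshold, gain = find_boundary(data)
        assert threshold == pytest.approx(3.5)
        assert gain == pytest.approx(1.0)

    def test_overlapping_worked_example(self):
        data = LabeledValues([1, 2, 3, 6, 4, 5, 7, 8], ("n",) * 4 + ("t",) * 4)
        threshold, gain = find_boundary(data)
        assert threshold == pytest.approx(3.5)
        assert gain == pytest.approx(0.548795, abs=1e-6)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = rng.integers(4, 31)
            values = np.round(rng.uniform(0, 10, n), 2)
            labels = tuple(rng.choice(["n", "t"], n))
            if len(set(labels)) < 2 or len(set(values)) < 2:
                continue
            data = LabeledValues(values, labels)
            got = find_boundary(data)
            want = find_boundary_oracle(values.tolist(), labels)
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_threshold_is_never_a_data_value(self):
        rng = np.random.default_rng(1)
        values = rng.integers(0, 8, 20).astype(float)
        labels = tuple(rng.choice(["n", "t"], 20))
        data = LabeledValues(values, labels)
        threshold, _ = find_boundary(data)
        assert threshold not in set(values)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(12)
        values = rng.uniform(0, 5, 25)
        labels = tuple(rng.choice(["n", "t"], 25))
        t0, g0 = find_boundary(LabeledValues(values, labels))
        t1, g1 = find_boundary(LabeledValues(3.0 * values + 7.0, labels))
        assert t1 == pytest.approx(3.0 * t0 + 7.0, rel=1e-12)
        assert g1 == pytest.approx(g0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            find_boundary(LabeledValues([2.0, 2.0, 2.0], ("n", "t", "n")))
        with pytest.raises(ValueError, match="two classes"):
            find_boundary(LabeledValues([1.0, 2.0], ("n", "n")))


def _matrix_from_groups(normal, nat, tumor):
    values = np.concatenate([normal, nat, tumor])[None, :]
    sample_ids = (
        [f"N{i}" for i in range(len(normal))]
        + [f"A{i}" for i in range(len(nat))]
        + [f"T{i}" for i in range(len(tumor))]
    )
    labels = GroupLabels(
        {
            **{f"N{i}": "normal" for i in range(len(normal))},
            **{f"A{i}": "nat" for i in range(len(nat))},
            **{f"T{i}": "tumor" for i in range(len(tumor))},
        }
    )
    return ExpressionMatrix(("g",), tuple(sample_ids), values), labels


class TestThreeClassBoundaries:
    def test_separated_groups_yield_clean_intervals(self):
        matrix, labels = _matrix_from_groups(
            normal=np.array([9.0, 10.0, 11.0]),
            nat=np.array([5.0, 5.5, 6.0]),
            tumor=np.array([1.0, 1.5, 2.0]),
        )
        result = three_class_boundaries(matrix, labels, "g")
        assert result.group_order == ("tumor", "nat", "normal")
        assert result.monotone
        t1, t2 = result.thresholds
        assert 2.0 < t1 < 5.0 and 6.0 < t2 < 9.0
        assert result.gains == (pytest.approx(1.0), pytest.approx(1.0))
        assert result.intervals["tumor"] == (-np.inf, t1)
        assert result.intervals["nat"] == (t1, t2)
        assert result.intervals["normal"] == (t2, np.inf)

    def test_group_order_follows_medians_not_tissue_names(self):
        # NAT highest — the inverted orientation some markers show
        matrix, labels = _matrix_from_groups(
            normal=np.array([4.0, 4.5, 5.0]),
            nat=np.array([9.0, 9.5, 10.0]),
            tumor=np.array([0.5, 1.0, 1.5]),
        )
        result = three_class_boundaries(matrix, labels, "g")
        assert result.group_order == ("tumor", "normal", "nat")

    def test_threshold_recovery_on_noisy_gene(self):
        """True cutpoints 4 and 8, sd 0.5: recovered within ±0.75 in >=95%."""
        rng = np.random.default_rng(31)
        hits = 0
        for _ in range(100):
            matrix, labels = _matrix_from_groups(
                normal=rng.normal(10, 0.5, 100),
                nat=rng.normal(6, 0.5, 100),
                tumor=rng.normal(2, 0.5, 100),
            )
            r = three_class_boundaries(matrix, labels, "g")
            if abs(r.thresholds[0] - 4.0) <= 0.75 and abs(r.thresholds[1] - 8.0) <= 0.75:
                hits += 1
        assert hits >= 95

    def test_boundary_table_intervals_partition_the_line(self):
        matrix, labels = _matrix_from_groups(
            normal=np.array([9.0, 10.0, 11.0]),
            nat=np.array([5.0, 5.5, 6.0]),
            tumor=np.array([1.0, 1.5, 2.0]),
        )
        table = boundary_table(matrix, labels, ["g"])
        assert list(table.columns) == [
            "gene_id", "group", "interval_lower", "interval_upper",
            "threshold_gain", "monotone_flag",
        ]
        rows = table.sort_values("interval_lower")
        lowers, uppers = rows["interval_lower"].to_numpy(), rows["interval_upper"].to_numpy()
        assert lowers[0] == -np.inf and uppers[-1] == np.inf
        np.testing.assert_allclose(uppers[:-1], lowers[1:])
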