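"""Confusion counting, metric formulas, splits and cohort statistics."""

import numpy as np
import pytest
from scipy import stats

from acti2img import (
    ConfusionCounts,
    Group,
    SimulationConfig,
    confusion,
    f1_from_precision_recall,
    group_statistics,
    metrics,
    simulate_cohort,
    split_dataset,
)
from acti2img.io import ActigraphyRecording, CohortManifest
from acti2img.segment import Segment


def _segments(n_per_participant, participants):
    out = []
    for pid, group in participants:
        for i in range(n_per_participant):
            out.append(
                Segment(pid, group, i * 60, 60, np.zeros(60, dtype=int))
            )
    return out


class TestConfusion:
    def test_enumerated_counts(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_predictions(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == 0 and c.fn == 0

    def test_all_wrong_predictions(self):
        c = confusion([1, 0], [0, 1])
        assert c.tp == 0 and c.tn == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_hand_computed_percentages(self):
        rep = metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert rep.accuracy == pytest.approx(70.0)
        assert rep.precision == pytest.approx(75.0)
        assert rep.recall == pytest.approx(60.0)
        assert rep.f1 == pytest.approx(66.67, abs=0.005)

    def test_f1_is_harmonic_mean_of_reported_precision_recall_pairs(self):
        assert f1_from_precision_recall(92.1, 93.13) == pytest.approx(
            92.61, abs=0.005
        )
        assert f1_from_precision_recall(96.77, 93.5) == pytest.approx(
            95.11, abs=0.005
        )

    def test_undefined_precision_flagged(self):
        rep = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=2))
        assert rep.precision is None
        assert rep.f1 == 0.0
        assert any("precision" in f for f in rep.flags)

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 30, size=4)
            rep = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert min(rep.precision, rep.recall) - 1e-9 <= rep.f1
            assert rep.f1 <= max(rep.precision, rep.recall) + 1e-9

    def test_accuracy_exact_on_integer_counts(self):
        rep = metrics(ConfusionCounts(tp=7, fp=0, tn=13, fn=0))
        assert rep.accuracy == 100.0 * 20 / 20

    def test_all_zero_confusion_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(0, 0, 0, 0)


class TestSplitDataset:
    def test_segment_level_sizes(self):
        segs = _segments(
            25, [("a", Group.CONDITION), ("b", Group.CONDITION),
                 ("c", Group.CONTROL), ("d", Group.CONTROL)]
        )
        train, test = split_dataset(segs, "segment_level", 0.2, seed=0)
        assert len(train) == 80 and len(test) == 20

    def test_segment_level_stratified(self):
        segs = _segments(
            50, [("a", Group.CONDITION), ("c", Group.CONTROL)]
        )
        train, test = split_dataset(segs, "segment_level", 0.2, seed=1)
        assert sum(s.label for s in test) == 10

    def test_participant_level_no_leakage(self):
        segs = _segments(
            10,
            [(f"p{i}", Group.CONDITION) for i in range(5)]
            + [(f"q{i}", Group.CONTROL) for i in range(5)],
        )
        train, test = split_dataset(segs, "participant_level", 0.2, seed=3)
        train_ids = {s.participant_id for s in train}
        test_ids = {s.participant_id for s in test}
        assert train_ids.isdisjoint(test_ids)
        assert {s.label for s in test} == {0, 1}

    @pytest.mark.parametrize("mode", ["segment_level", "participant_level"])
    def test_same_seed_identical_split(self, mode):
        segs = _segments(
            10,
            [(f"p{i}", Group.CONDITION) for i in range(4)]
            + [(f"q{i}", Group.CONTROL) for i in range(4)],
        )
        a = split_dataset(segs, mode, 0.25, seed=7)
        b = split_dataset(segs, mode, 0.25, seed=7)
        assert [id(s) for s in a[0]] == [id(s) for s in b[0]]
        assert [id(s) for s in a[1]] == [id(s) for s in b[1]]

    def test_missing_class_on_one_side_rejected(self):
        segs = _segments(
            5, [("a", Group.CONDITION), ("b", Group.CONTROL)]
        )
        # one participant per class cannot be split participant-level
        with pytest.raises(ValueError, match="missing a class"):
            split_dataset(segs, "participant_level", 0.5, seed=0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_segments(5, [("a", Group.CONDITION)]), "segment_level", 1.5, 0)


class TestGroupStatistics:
    def test_symmetric_data_zero_skew(self):
        assert stats.skew([1, 2, 3, 3, 2, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_normal_draws_near_zero_excess_kurtosis(self, rng):
        draws = rng.standard_normal(10_000)
        assert stats.kurtosis(draws, fisher=True) == pytest.approx(0.0, abs=0.2)

    def test_table_shape_and_direction_on_synthetic_cohort(self):
        cohort = simulate_cohort(
            SimulationConfig(n_condition=10, n_control=10, days_per_participant=1)
        )
        table = group_statistics(cohort)
        assert set(table["group"]) == {"condition", "control"}
        skew = table.set_index("group")["skewness"]
        assert skew["condition"] > skew["control"]
        assert (table["p_value_between_groups"] < 0.05).all()

    def test_null_calibration_of_between_group_pvalue(self):
        """Same-distribution groups: p-values uniform over repeated seeds."""
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(200):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            pvals.append(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_group_rejected(self):
        ts = (
            np.datetime64("2020-01-01T00:00:00")
            + np.arange(10).astype("timedelta64[m]")
        ).astype("datetime64[s]")
        recs = [
            ActigraphyRecording(f"p{i}", Group.CONTROL, ts, np.ones(10, int))
            for i in range(3)
        ]
        with pytest.raises(ValueError, match="at least 2 participants"):
            group_statistics(CohortManifest(recs))
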