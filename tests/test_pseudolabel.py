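"""Engine contracts: strict confidence filtering, sweep bookkeeping against
brute-force counting, tie-breaking, pool conservation and full-run
determinism with the reference backbone."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herdid import (
    ClassifierSpec,
    ConfidenceVector,
    ThresholdGrid,
    TrainingSchedule,
    filter_confident,
    run_pseudo_labeling,
    run_round,
    run_threshold_sweep,
    select_best_threshold,
)
from herdid.errors import ArgumentError
from herdid.pseudolabel import (
    DEFAULT_THRESHOLD_GRID,
    EngineState,
    SweepRow,
    pseudo_label_precision,
)


def _cv(confidence: float, k: int = 4, label: int = 0) -> ConfidenceVector:
    p = np.full(k, (1 - confidence) / (k - 1))
    p[label] = confidence
    return ConfidenceVector(p=p, predicted_label=label, confidence=confidence)


def _preds(confidences, k=4):
    return [(f"s{i}", _cv(c, k=k, label=i % k)) for i, c in enumerate(confidences)]


class TestThresholdGrid:
    def test_default_is_the_13_value_grid(self):
        grid = ThresholdGrid()
        assert grid.values == DEFAULT_THRESHOLD_GRID
        assert len(grid.values) == 13
        assert 0.995 in grid.values

    def test_must_be_strictly_increasing_in_unit_interval(self):
        with pytest.raises(ArgumentError):
            ThresholdGrid((0.5, 0.5))
        with pytest.raises(ArgumentError):
            ThresholdGrid((0.5, 1.0))


class TestFilterConfident:
    def test_threshold_zero_admits_everything(self):
        preds = _preds([0.3, 0.9, 0.26])
        assert len(filter_confident(preds, 0.0)) == 3

    def test_threshold_one_admits_nothing(self):
        preds = _preds([0.999, 0.9999999])
        assert filter_confident(preds, 1.0) == []

    def test_strictly_above_boundary(self):
        preds = _preds([0.9990001, 0.999, 0.5])
        kept = filter_confident(preds, 0.999)
        assert [r.snapshot_id for r in kept] == ["s0"]

    def test_labels_are_the_predicted_classes_in_input_order(self):
        preds = _preds([0.8, 0.9, 0.85], k=4)
        kept = filter_confident(preds, 0.7, round_assigned=2)
        assert [r.snapshot_id for r in kept] == ["s0", "s1", "s2"]
        assert [r.assigned_label for r in kept] == [0, 1, 2]
        assert all(r.round_assigned == 2 for r in kept)

    def test_threshold_outside_unit_interval_rejected(self):
        with pytest.raises(ArgumentError):
            filter_confident(_preds([0.5]), -0.1)
        with pytest.raises(ArgumentError):
            filter_confident(_preds([0.5]), 1.1)

    @given(
        confs=st.lists(st.floats(0.26, 0.999999), min_size=0, max_size=30),
        t1=st.floats(0, 1),
        t2=st.floats(0, 1),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_nested_in_threshold(self, confs, t1, t2):
        """filter(t2) is a subset of filter(t1) whenever t1 < t2."""
        lo, hi = min(t1, t2), max(t1, t2)
        preds = _preds(confs)
        kept_hi = {r.snapshot_id for r in filter_confident(preds, hi)}
        kept_lo = {r.snapshot_id for r in filter_confident(preds, lo)}
        assert kept_hi <= kept_lo
        # and both match the brute-force count
        assert len(kept_lo) == sum(1 for c in confs if c > lo)


class TestSelectBestThreshold:
    def _row(self, t, acc):
        return SweepRow(threshold=t, train_size=0, n_new=0, validation_accuracy=acc)

    def test_single_row_is_chosen(self):
        assert select_best_threshold([self._row(0.9, 0.5)]) == 0.9

    def test_argmax_of_validation_accuracy(self):
        rows = [self._row(0.5, 0.80), self._row(0.999, 0.90), self._row(0.9999, 0.85)]
        assert select_best_threshold(rows) == 0.999

    def test_tie_broken_toward_largest_threshold(self):
        rows = [self._row(0.99, 0.90), self._row(0.999, 0.90)]
        assert select_best_threshold(rows) == 0.999

    def test_empty_table_rejected(self):
        with pytest.raises(ArgumentError):
            select_best_threshold([])


class TestThresholdSweep:
    def test_empty_labeled_pool_rejected(self, tiny_data, reference_spec):
        with pytest.raises(ArgumentError):
            run_threshold_sweep(
                [], [], [], ThresholdGrid((0.5,)), tiny_data,
                reference_spec, TrainingSchedule(),
            )

    def test_grid_zero_row_counts_everything(self, tiny_data, reference_spec):
        preds = [
            (sid, _cv(0.8, k=tiny_data.n_classes, label=0))
            for sid in tiny_data.unlabeled_ids[:7]
        ]
        rows, _ = run_threshold_sweep(
            tiny_data.labeled_pool, [], preds, ThresholdGrid((0.0,)),
            tiny_data, reference_spec, TrainingSchedule(),
        )
        assert len(rows) == 1
        assert rows[0].train_size == len(tiny_data.labeled_pool) + 7

    def test_row_sizes_match_brute_force_counts_and_decrease(self, tiny_data, reference_spec):
        rng = np.random.default_rng(5)
        confs = rng.uniform(0.3, 0.99999, size=len(tiny_data.unlabeled_ids))
        preds = [
            (sid, _cv(float(c), k=tiny_data.n_classes, label=int(i % tiny_data.n_classes)))
            for i, (sid, c) in enumerate(zip(tiny_data.unlabeled_ids, confs))
        ]
        grid = ThresholdGrid()
        rows, _ = run_threshold_sweep(
            tiny_data.labeled_pool, [], preds, grid, tiny_data,
            reference_spec, TrainingSchedule(),
        )
        sizes = [r.train_size for r in rows]
        base = len(tiny_data.labeled_pool)
        for row, t in zip(rows, grid.values):
            assert row.train_size == base + sum(1 for c in confs if c > t)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestRunRound:
    def _baseline_state(self, data, spec):
        result = run_pseudo_labeling(data, n_rounds=0, spec=spec, master_seed=3)
        return result.state

    def test_pools_partition_after_round(self, tiny_data, reference_spec):
        state = self._baseline_state(tiny_data, reference_spec)
        new_state, result = run_round(
            state, ThresholdGrid(), tiny_data, reference_spec, TrainingSchedule(),
            master_seed=3,
        )
        labeled = {sid for sid, _ in new_state.labeled_pool}
        pseudo = {r.snapshot_id for r in new_state.pseudo_pool}
        remaining = set(new_state.unlabeled_ids)
        assert not labeled & pseudo
        assert not pseudo & remaining
        assert pseudo | remaining == set(tiny_data.unlabeled_ids)
        assert len(pseudo) + len(remaining) == len(tiny_data.unlabeled_ids)
        assert result.n_promoted == len(pseudo)

    def test_promoted_records_exceed_chosen_threshold(self, tiny_data, reference_spec):
        state = self._baseline_state(tiny_data, reference_spec)
        new_state, result = run_round(
            state, ThresholdGrid(), tiny_data, reference_spec, TrainingSchedule(),
            master_seed=3,
        )
        for rec in new_state.pseudo_pool:
            assert rec.confidence > result.chosen_threshold

    def test_empty_unlabeled_pool_promotes_nothing(self, tiny_data, reference_spec):
        state = self._baseline_state(tiny_data, reference_spec)
        state = EngineState(
            labeled_pool=state.labeled_pool, pseudo_pool=[], unlabeled_ids=[],
            model=state.model, history=list(state.history),
        )
        new_state, result = run_round(
            state, ThresholdGrid(), tiny_data, reference_spec, TrainingSchedule(),
            master_seed=3,
        )
        assert new_state.pseudo_pool == []
        assert result.stopped_early


class TestRunPseudoLabeling:
    def test_zero_rounds_gives_baseline_only(self, tiny_data, reference_spec):
        result = run_pseudo_labeling(tiny_data, n_rounds=0, spec=reference_spec, master_seed=1)
        assert len(result.history) == 1
        assert result.history[0].round_index == 0
        assert result.history[0].chosen_threshold is None
        assert result.history[0].n_pseudo == 0

    def test_pseudo_counts_never_decrease(self, tiny_data, reference_spec):
        result = run_pseudo_labeling(tiny_data, n_rounds=3, spec=reference_spec, master_seed=1)
        counts = [rr.n_pseudo for rr in result.history]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_pool_conservation_across_rounds(self, tiny_data, reference_spec):
        result = run_pseudo_labeling(tiny_data, n_rounds=3, spec=reference_spec, master_seed=1)
        total = len(tiny_data.labeled_pool) + len(tiny_data.unlabeled_ids)
        state = result.state
        assert (
            len(state.labeled_pool) + len(state.pseudo_pool) + len(state.unlabeled_ids)
            == total
        )

    def test_full_history_bit_identical_across_runs(self, tiny_data, reference_spec):
        a = run_pseudo_labeling(tiny_data, n_rounds=2, spec=reference_spec, master_seed=7)
        b = run_pseudo_labeling(tiny_data, n_rounds=2, spec=reference_spec, master_seed=7)
        assert len(a.history) == len(b.history)
        for ra, rb in zip(a.history, b.history):
            assert ra.chosen_threshold == rb.chosen_threshold
            assert ra.n_pseudo == rb.n_pseudo
            assert ra.validation_accuracy == rb.validation_accuracy
            assert ra.test_accuracy == rb.test_accuracy
            assert [(s.threshold, s.train_size, s.validation_accuracy) for s in ra.sweep] == [
                (s.threshold, s.train_size, s.validation_accuracy) for s in rb.sweep
            ]

    def test_frozen_records_never_relabeled(self, tiny_data, reference_spec):
        result = run_pseudo_labeling(tiny_data, n_rounds=3, spec=reference_spec, master_seed=1)
        seen: dict[str, int] = {}
        for rec in result.state.pseudo_pool:
            assert rec.snapshot_id not in seen
            seen[rec.snapshot_id] = rec.assigned_label


class TestPseudoLabelQuality:
    def test_precision_scoreable_and_higher_at_larger_threshold(self, tiny_data, reference_spec):
        """Confidence filtering concentrates correct labels: precision of
        promotions at a high threshold beats precision at threshold 0."""
        from herdid.classify import predict_batch

        result = run_pseudo_labeling(tiny_data, n_rounds=0, spec=reference_spec, master_seed=1)
        preds = list(
            zip(
                tiny_data.unlabeled_ids,
                predict_batch(result.final_model, tiny_data.images(tiny_data.unlabeled_ids)),
            )
        )
        all_records = filter_confident(preds, 0.0)
        assert len(all_records) == len(tiny_data.unlabeled_ids)  # ledger covers 100%
        p_all = pseudo_label_precision(all_records, tiny_data.true_labels)
        confident = filter_confident(preds, 0.9)
        assert confident  # the fixture produces some high-confidence predictions
        p_high = pseudo_label_precision(confident, tiny_data.true_labels)
        assert p_high > p_all
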