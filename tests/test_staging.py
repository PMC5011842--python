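import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stagemine.corpus_io import Corpus, LogNote
from stagemine.staging import (
    StageTrajectory,
    build_trajectories,
    collapse_probabilities,
    detect_stage_interval,
    estimate_transition_matrix,
    evaluate_predictions,
    flag_stage_attainment,
)


def _trajectory(p_values, stage_dim=2):
    dates = [dt.date(2008, 1, 1) + dt.timedelta(days=7 * i) for i in range(len(p_values))]
    probs = np.column_stack([p_values] + [(1 - np.asarray(p_values)) / (stage_dim - 1)] * (stage_dim - 1))
    return StageTrajectory("c17", dates, probs, [1] * len(p_values))


# ---------------------------------------------------------------------------
# classification


def test_collapse_pools_tail_stages_by_summation():
    row = np.array([[0.1, 0.1, 0.1, 0.2, 0.2, 0.1, 0.1, 0.1]])
    pooled = collapse_probabilities(row, collapse_at=4)
    assert pooled.shape == (1, 4)
    assert pooled[0].tolist() == pytest.approx([0.1, 0.1, 0.1, 0.7])
    assert pooled.sum() == pytest.approx(1.0)


def test_argmax_and_tie_break_via_trajectories():
    notes = [LogNote("a", dt.date(2008, 1, 1), "x"), LogNote("a", dt.date(2008, 1, 2), "y")]
    corpus = Corpus(notes, n_stages=4)
    probs = np.array([[0.1, 0.2, 0.3, 0.4], [0.25, 0.25, 0.25, 0.25]])
    cats = [int(np.argmax(p)) + 1 for p in probs]
    trajs = build_trajectories(corpus, probs, cats)
    assert trajs["a"].categories == [4, 1]  # uniform row ties to category 1


# ---------------------------------------------------------------------------
# evaluation


def test_accuracy_from_reference_confusion_matrix():
    # four-category confusion over 120 samples with diagonal (29, 63, 5, 3):
    # 100 correct of 120 -> 83.3 % regardless of where the 20 errors fall
    confusion = np.array(
        [[29, 2, 3, 2], [2, 63, 5, 0], [1, 1, 5, 1], [1, 1, 1, 3]]
    )
    assert confusion.sum() == 120
    truth, pred = [], []
    for t in range(4):
        for p in range(4):
            truth += [t + 1] * confusion[t, p]
            pred += [p + 1] * confusion[t, p]
    report = evaluate_predictions(pred, truth, n_categories=4)
    assert report.n == 120
    assert np.array_equal(report.confusion, confusion)
    assert report.accuracy == pytest.approx(100 / 120)
    assert round(100 * report.accuracy, 1) == 83.3


def test_accuracy_simple_fraction_and_identity():
    pred = [1] * 55 + [2] * 10
    truth = [1] * 55 + [1] * 10
    assert evaluate_predictions(pred, truth).accuracy == pytest.approx(55 / 65)
    perfect = evaluate_predictions([1, 2, 3], [1, 2, 3])
    assert perfect.accuracy == 1.0
    assert np.trace(perfect.confusion) == 3


def test_evaluation_matches_sklearn_metrics():
    from sklearn.metrics import accuracy_score, confusion_matrix

    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(2, 40))
        pred = rng.integers(1, 5, size=n).tolist()
        truth = rng.integers(1, 5, size=n).tolist()
        report = evaluate_predictions(pred, truth, n_categories=4)
        assert report.accuracy == pytest.approx(accuracy_score(truth, pred))
        assert np.array_equal(
            report.confusion, confusion_matrix(truth, pred, labels=[1, 2, 3, 4])
        )


def test_evaluation_rejects_empty_or_mismatched():
    with pytest.raises(ValueError):
        evaluate_predictions([], [])
    with pytest.raises(ValueError):
        evaluate_predictions([1], [1, 2])


# ---------------------------------------------------------------------------
# interval detection


def test_sustained_run_brackets_interval():
    traj = _trajectory([0.1, 0.1, 0.9, 0.9, 0.9, 0.1])
    [(start, end)] = detect_stage_interval(traj, stage=1, threshold=0.5, min_run=2)
    assert start == traj.dates[2]
    assert end == traj.dates[4]


def test_no_interval_below_threshold_and_run_too_short():
    assert detect_stage_interval(_trajectory([0.2, 0.3, 0.1]), 1) == []
    assert detect_stage_interval(_trajectory([0.1, 0.9, 0.1]), 1, min_run=2) == []


def test_reentry_gives_multiple_intervals():
    traj = _trajectory([0.9, 0.9, 0.1, 0.9, 0.9, 0.9])
    intervals = detect_stage_interval(traj, 1)
    assert len(intervals) == 2


def _oracle_runs(above, min_run):
    """Run detection via itertools.groupby, independently of the scanner."""
    runs = []
    i = 0
    for val, grp in itertools.groupby(above):
        n = len(list(grp))
        if val and n >= min_run:
            runs.append((i, i + n - 1))
        i += n
    return runs


@given(
    st.lists(st.booleans(), min_size=1, max_size=12),
    st.integers(min_value=1, max_value=4),
)
@settings(max_examples=200, deadline=None)
def test_interval_scanner_matches_groupby_oracle(bits, min_run):
    p = [0.9 if b else 0.1 for b in bits]
    traj = _trajectory(p)
    got = detect_stage_interval(traj, 1, threshold=0.5, min_run=min_run)
    expected = [
        (traj.dates[a], traj.dates[b]) for a, b in _oracle_runs(bits, min_run)
    ]
    assert got == expected


# ---------------------------------------------------------------------------
# stage attainment flags


def test_false_flag_rate_arithmetic():
    sites = {f"s{i}": [1, 2, 3] for i in range(31)}
    for i in range(7):
        sites[f"s{i}"] = [1, 2, 4]
    flags, rate = flag_stage_attainment(sites, stage=4)
    assert sum(flags.values()) == 7
    assert round(rate, 1) == 22.6


def test_flag_rates_at_extremes():
    none_flagged = {f"s{i}": [1, 2] for i in range(5)}
    assert flag_stage_attainment(none_flagged, stage=4)[1] == 0.0
    all_flagged = {f"s{i}": [4] for i in range(5)}
    assert flag_stage_attainment(all_flagged, stage=4)[1] == 100.0


def test_flagging_is_monotone_in_added_notes():
    sites = {"a": [1, 2, 4, 2], "b": [1, 1]}
    flags, _ = flag_stage_attainment(sites, stage=4)
    sites["a"] = sites["a"] + [1, 1, 1]
    flags_after, _ = flag_stage_attainment(sites, stage=4)
    assert flags_after["a"] >= flags["a"]


def test_flag_subset_and_errors():
    sites = {"a": [4], "b": [1], "c": [2]}
    _, rate = flag_stage_attainment(sites, stage=4, subset=["b", "c"])
    assert rate == 0.0
    with pytest.raises(ValueError):
        flag_stage_attainment(sites, stage=4, subset=[])
    with pytest.raises(ValueError, match="not in corpus"):
        flag_stage_attainment(sites, stage=4, subset=["zzz"])


# ---------------------------------------------------------------------------
# transitions


def test_transition_counts_and_probabilities():
    model = estimate_transition_matrix([[1, 1, 1, 2]])
    assert model.counts[0].tolist() == [2, 1]
    assert model.P[0] == pytest.approx([2 / 3, 1 / 3])
    assert model.n_transitions == 3


def test_constant_sequence_identity_row():
    model = estimate_transition_matrix([[2, 2, 2]], n_categories=3)
    assert model.P[1].tolist() == [0.0, 1.0, 0.0]
    assert model.zero_rows == [0, 2]


def test_observed_rows_sum_to_one_exactly():
    rng = np.random.default_rng(5)
    seqs = [rng.integers(1, 5, size=rng.integers(2, 30)).tolist() for _ in range(10)]
    model = estimate_transition_matrix(seqs, n_categories=4)
    for i in range(4):
        if i not in model.zero_rows:
            assert model.P[i].sum() == pytest.approx(1.0, abs=1e-9)
    assert model.counts.sum() == model.n_transitions


def test_transitions_require_a_pair():
    with pytest.raises(ValueError, match="shorter than 2"):
        estimate_transition_matrix([[1], [2]])


def test_laplace_smoothing_fills_zero_rows():
    model = estimate_transition_matrix([[1, 1]], n_categories=2, laplace=1.0)
    assert model.P[1] == pytest.approx([0.5, 0.5])
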