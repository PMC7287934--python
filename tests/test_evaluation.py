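"""Top-N accuracy, contingency classification and derived statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retroseq.beam import Candidate, RankedPrediction
from retroseq.evaluation import (
    ContingencyTable,
    accuracy,
    best_f1_threshold,
    compute_metrics,
    contingency,
    delta_accuracy,
    per_class_accuracy,
    precision_recall_f1,
    top_n_accuracy,
)

# Printed contingency counts of the transformer-transfer top-1 predictions
# on the 5004-reaction patent test set.
PRINTED_TABLE = ContingencyTable(tp=2021, fp=776, fn=1191, tn=1016, threshold=0.5)


def rp(cands, source=("C",)):
    return RankedPrediction(
        source=source,
        candidates=[Candidate(smiles=s, confidence=c, complete=comp) for s, c, comp in cands],
    )


@pytest.fixture
def three_example_fixture():
    preds = [
        rp([("CCO", 0.9, True), ("CCN", 0.5, True)]),  # truth at rank 1
        rp([("CCN", 0.8, True), ("CCS", 0.6, True), ("CCO", 0.4, True)]),  # rank 3
        rp([("CCN", 0.7, True)]),  # absent
    ]
    truths = ["CCO", "CCO", "CCO"]
    return preds, truths


def test_top_n_manual_enumeration(three_example_fixture):
    preds, truths = three_example_fixture
    assert top_n_accuracy(preds, truths, 1) == pytest.approx(1 / 3)
    assert top_n_accuracy(preds, truths, 3) == pytest.approx(2 / 3)
    assert top_n_accuracy(preds, truths, 20) == pytest.approx(2 / 3)


def test_top_n_edge_cases():
    empty = [rp([]), rp([])]
    for n in (1, 5, 20):
        assert top_n_accuracy(empty, ["CCO", "CCN"], n) == 0.0
    with pytest.raises(ValueError):
        top_n_accuracy([rp([])], ["CCO", "CCN"], 1)
    # incomplete candidates can never match
    preds = [rp([("CCO", 0.9, False)])]
    assert top_n_accuracy(preds, ["CCO"], 1) == 0.0


def test_top_n_nondecreasing_random_fixtures():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n_ex = int(rng.integers(1, 30))
        preds, truths = [], []
        for i in range(n_ex):
            truth = f"C{'C' * int(rng.integers(0, 5))}O"
            k = int(rng.integers(0, 8))
            scores = np.sort(rng.random(k))[::-1]
            cands = [
                (truth if rng.random() < 0.3 else f"CCN{'C' * j}", float(scores[j]), True)
                for j in range(k)
            ]
            preds.append(rp(cands))
            truths.append(truth)
        values = [top_n_accuracy(preds, truths, n) for n in range(1, 25)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))


def test_contingency_four_way_fixture():
    preds = [
        rp([("CCO", 0.9, True)]),  # match, above -> TP
        rp([("CCO", 0.3, True)]),  # match, below -> FN
        rp([("CCN", 0.9, True)]),  # non-match, above -> FP
        rp([("CCN", 0.3, True)]),  # non-match, below -> TN
    ]
    truths = ["CCO"] * 4
    t = contingency(preds, truths, threshold=0.5)
    assert (t.tp, t.fp, t.fn, t.tn) == (1, 1, 1, 1)
    assert t.n == 4


def test_contingency_boundaries():
    preds = [rp([("CCO", 0.9, True)]), rp([("CCN", 0.2, True)])]
    truths = ["CCO", "CCO"]
    t0 = contingency(preds, truths, threshold=0.0)
    assert (t0.fn, t0.tn) == (0, 0)  # all scores > 0
    t1 = contingency(preds, truths, threshold=1.0)
    assert (t1.tp, t1.fp) == (0, 0)
    # strict 'above': an example exactly at the threshold is 'below'
    t = contingency(preds, truths, threshold=0.9)
    assert t.fn == 1 and t.tn == 1
    with pytest.raises(ValueError):
        contingency(preds, truths, threshold=1.5)


def test_precision_recall_f1_printed_counts():
    p, r, f1, degenerate = precision_recall_f1(PRINTED_TABLE)
    assert not degenerate
    assert round(p, 3) == 0.723
    assert round(r, 3) == 0.629
    assert round(100 * f1, 1) == 67.3
    assert round(100 * accuracy(PRINTED_TABLE), 1) == 60.7


def test_precision_recall_f1_degenerate():
    assert precision_recall_f1(ContingencyTable(5, 0, 0, 0)) == (1.0, 1.0, 1.0, False)
    p, r, f1, degenerate = precision_recall_f1(ContingencyTable(0, 0, 0, 5))
    assert (p, r, f1) == (0.0, 0.0, 0.0) and degenerate


def test_delta_accuracy_printed_counts():
    assert round(100 * delta_accuracy(PRINTED_TABLE), 1) == 9.0


def test_delta_accuracy_saturated_and_swap():
    assert delta_accuracy(ContingencyTable(7, 0, 0, 0)) == 0.0
    rng = np.random.default_rng(1)
    for _ in range(200):
        tp, fp, fn, tn = (int(x) for x in rng.integers(0, 50, 4))
        if tp + fp + fn + tn == 0:
            continue
        d1 = delta_accuracy(ContingencyTable(tp, fp, fn, tn))
        d2 = delta_accuracy(ContingencyTable(tn, fn, fp, tp))  # TP<->TN, FP<->FN
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert abs(d1) <= 1.0


def test_delta_accuracy_permutation_null():
    """Scores shuffled against outcomes give mean delta-accuracy near 0."""
    rng = np.random.default_rng(42)
    n = 200
    matches = rng.random(n) < 0.4
    scores = rng.random(n)
    deltas = []
    for _ in range(1000):
        perm = rng.permutation(n)
        s = scores[perm]
        tp = int(np.sum(matches & (s > 0.5)))
        fn = int(np.sum(matches & (s <= 0.5)))
        fp = int(np.sum(~matches & (s > 0.5)))
        tn = int(np.sum(~matches & (s <= 0.5)))
        deltas.append(delta_accuracy(ContingencyTable(tp, fp, fn, tn)))
    deltas = np.asarray(deltas)
    assert abs(deltas.mean()) < 3 * deltas.std(ddof=1) / np.sqrt(len(deltas))


@given(
    st.integers(0, 1000), st.integers(0, 1000), st.integers(0, 1000), st.integers(0, 1000)
)
@settings(max_examples=1000, deadline=None, derandomize=True)
def test_table_invariants_random(tp, fp, fn, tn):
    table = ContingencyTable(tp, fp, fn, tn)
    assert table.n == tp + fp + fn + tn
    p, r, f1, degenerate = precision_recall_f1(table)
    if not degenerate:
        assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12
    if table.n:
        assert abs(delta_accuracy(table)) <= 1.0


def test_accuracy_equals_top1_at_zero_threshold(three_example_fixture):
    preds, truths = three_example_fixture
    t = contingency(preds, truths, threshold=0.0)
    assert accuracy(t) == pytest.approx(top_n_accuracy(preds, truths, 1))


def test_per_class_accuracy():
    preds = [rp([("CCO", 0.9, True)]), rp([("X", 0.9, True)]), rp([("CCO", 0.9, True)])]
    truths = ["CCO", "CCO", "CCO"]
    labels = [1, 2, 1]
    out = per_class_accuracy(preds, truths, labels, n_values=(1, 10))
    assert out[1] == {1: 1.0, 10: 1.0}
    assert out[2] == {1: 0.0, 10: 0.0}
    assert 3 not in out  # absent class reported as absent, not zero
    # weighted average identity
    overall = top_n_accuracy(preds, truths, 1)
    weighted = (2 * out[1][1] + 1 * out[2][1]) / 3
    assert overall == pytest.approx(weighted)
    with pytest.raises(ValueError):
        per_class_accuracy(preds, truths, [1, 2], n_values=(1,))


def test_best_f1_threshold_and_compute_metrics(three_example_fixture):
    preds, truths = three_example_fixture
    t = best_f1_threshold(preds, truths)
    report = compute_metrics(preds, truths, class_labels=[1, 1, 2], threshold=None)
    assert report.table.threshold == t
    assert list(report.top_n) == [1, 2, 3, 5, 10, 20]
    vals = list(report.top_n.values())
    assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
    d = report.as_dict()
    import json

    assert json.loads(json.dumps(d)) == d
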