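"""The ordered staging rules, the low-count branch, and the estimator API."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from cytostage.staging import (
    DIESTRUS,
    ESTRUS,
    IMPOSSIBILITY_TAG,
    METESTRUS,
    PROESTRUS,
    UNCLASSIFIED,
    CellCounts,
    StageRuleClassifier,
    StageRuleConfig,
    classify_stage,
    impossibility_check,
    proportions,
    stage_table,
)

counts_strategy = st.builds(
    CellCounts,
    st.integers(0, 500),
    st.integers(0, 500),
    st.integers(0, 500),
)


@pytest.mark.parametrize(
    "counts, stage, branch, tagged",
    [
        ((80, 10, 10), DIESTRUS, "high_count", False),
        ((25, 30, 45), PROESTRUS, "high_count", False),  # 45% nucleated >= 35%
        ((0, 100, 0), ESTRUS, "high_count", False),
        ((34, 33, 33), METESTRUS, "high_count", False),  # no rule fires
        ((1, 1, 0), DIESTRUS, "low_count", True),
        ((0, 0, 0), UNCLASSIFIED, "low_count", True),
        ((50, 15, 35), DIESTRUS, "high_count", False),  # leukocytes exactly 50%: inclusive, wins first
        ((30, 35, 35), PROESTRUS, "high_count", False),  # nucleated exactly at the inclusive 35% boundary
        ((5, 2, 2), DIESTRUS, "low_count", True),
        ((5, 3, 2), DIESTRUS, "high_count", False),  # total exactly at low_count_total
    ],
)
def test_classify_stage_examples(counts, stage, branch, tagged):
    call = classify_stage(CellCounts(*counts))
    assert call.stage == stage
    assert call.branch == branch
    assert call.tagged is tagged
    assert call.tag_text == (IMPOSSIBILITY_TAG if tagged else "")


def test_leukocyte_priority_over_proestrus_rule():
    # 50% leukocytes with 40% nucleated: diestrus, not proestrus
    assert classify_stage(CellCounts(50, 10, 40)).stage == DIESTRUS


def test_proportions():
    assert proportions(CellCounts(2, 1, 3)) == pytest.approx((2 / 6, 1 / 6, 3 / 6))
    assert proportions(CellCounts(0, 0, 0)) == (0.0, 0.0, 0.0)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(counts_strategy)
def test_call_is_total_deterministic_and_proportions_sum(counts):
    call_a = classify_stage(counts)
    call_b = classify_stage(counts)
    assert call_a == call_b
    if counts.total > 0:
        assert sum(call_a.proportions) == pytest.approx(1.0)
    assert (call_a.stage == UNCLASSIFIED) == (counts.total == 0)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(counts_strategy, st.integers(1, 5))
def test_scale_invariance_in_high_count_branch(counts, k):
    """Rules depend only on proportions: scaling counts by k changes
    nothing while both totals stay in the high-count branch."""
    rules = StageRuleConfig()
    if counts.total < rules.low_count_total:
        return
    scaled = CellCounts(k * counts.n_leukocyte, k * counts.n_cornified, k * counts.n_nucleated)
    assert classify_stage(scaled, rules).stage == classify_stage(counts, rules).stage


@settings(max_examples=200, derandomize=True, deadline=None)
@given(counts_strategy, st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
def test_adding_cells_never_sets_the_tag(counts, dl, dc, dn):
    rules = StageRuleConfig()
    if counts.total < rules.low_count_total:
        return
    bigger = CellCounts(counts.n_leukocyte + dl, counts.n_cornified + dc, counts.n_nucleated + dn)
    assert classify_stage(bigger, rules).tagged is False


@pytest.mark.parametrize(
    "counts, expected",
    [((1, 1, 1), True), ((50, 30, 20), False), ((4, 3, 3), False)],
)
def test_impossibility_check_strictly_below_semantics(counts, expected):
    assert impossibility_check(CellCounts(*counts)) is expected


def test_rule_config_validation_and_file_round_trip(tmp_path):
    with pytest.raises(ValueError):
        StageRuleConfig(proestrus_nucleated_min=0.0)
    with pytest.raises(ValueError):
        StageRuleConfig(majority_min=1.5)

    cfg = StageRuleConfig(proestrus_nucleated_min=0.4, low_count_total=5)
    path = tmp_path / "rules.cfg"
    cfg.to_file(path)
    assert StageRuleConfig.from_file(path) == cfg

    path.write_text("proestrus_nucleated_min: 0.35\n# comment\nmystery_key: 1\n")
    with pytest.raises(ValueError, match="mystery_key"):
        StageRuleConfig.from_file(path)


def test_custom_low_count_threshold_moves_the_branch():
    rules = StageRuleConfig(low_count_total=20)
    assert classify_stage(CellCounts(10, 3, 2), rules).tagged is True
    assert classify_stage(CellCounts(15, 3, 2), rules).tagged is False


def test_stage_table_layout_and_tags():
    table = stage_table(
        [
            ("a.png", CellCounts(80, 10, 10)),
            ("b.png", CellCounts(1, 1, 0)),
            ("c.png", CellCounts(5, 90, 5)),
        ]
    )
    assert list(table["image"]) == ["a.png", "b.png", "c.png"]
    assert list(table["stage"]) == [DIESTRUS, DIESTRUS, ESTRUS]
    assert list(table["tag"]) == ["", IMPOSSIBILITY_TAG, ""]
    pct_sums = table[["pct_leukocyte", "pct_cornified", "pct_nucleated"]].sum(axis=1)
    assert (abs(pct_sums - 100.0) <= 0.1).all()

    empty = stage_table([])
    assert len(empty) == 0
    assert list(empty.columns)[:4] == ["image", "n_leukocyte", "n_cornified", "n_nucleated"]


class TestStageRuleClassifier:
    def test_predict_matches_functional_api(self):
        X = np.array([[80, 10, 10], [25, 30, 45], [0, 100, 0], [34, 33, 33], [1, 1, 0]])
        clf = StageRuleClassifier().fit(X)
        expected = [classify_stage(CellCounts(*row)).stage for row in X]
        assert list(clf.predict(X)) == expected
        calls = clf.predict_calls(X)
        assert [c.tagged for c in calls] == [False, False, False, False, True]

    def test_sklearn_contract(self):
        clf = StageRuleClassifier(proestrus_nucleated_min=0.4)
        cloned = clone(clf)
        assert cloned.get_params()["proestrus_nucleated_min"] == 0.4
        cloned.set_params(low_count_total=5).fit(np.zeros((2, 3)))
        assert UNCLASSIFIED in cloned.classes_
        with pytest.raises(ValueError):
            StageRuleClassifier().fit(np.zeros((2, 4)))

    def test_threshold_parameters_change_calls(self):
        X = np.array([[20, 40, 40]])
        default = StageRuleClassifier().fit(X)
        strict = StageRuleClassifier(proestrus_nucleated_min=0.45).fit(X)
        assert default.predict(X)[0] == PROESTRUS
        assert strict.predict(X)[0] == METESTRUS
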