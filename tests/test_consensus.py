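"""Consensus gold standard: exhaustive truth table, symmetry, adjudication."""

import itertools

import pandas as pd
import pytest

from lungsound.consensus import (
    INDETERMINATE,
    GoldStandardDecision,
    SpecialistTriple,
    Status,
    adjudicate,
    build_gold_standard,
    specialist_round,
)

LABELS = ("crackle", "wheeze", "normal", "indeterminate")
ALL_TRIPLES = list(itertools.product(LABELS, repeat=3))


def oracle_status(labels):
    """Independent brute-force restatement of the consensus rules."""
    definite = [l for l in labels if l != INDETERMINATE]
    n_indet = 3 - len(definite)
    if n_indet == 0 and len(set(definite)) == 1:
        return "accepted"
    if n_indet >= 2:
        return "rejected"
    if any(definite.count(l) == 2 for l in set(definite)):
        return "needs_adjudication"
    return "rejected"  # no two raters agree on a definite label


class TestSpecialistRound:
    def test_unanimous_crackle_accepted(self):
        d = specialist_round(SpecialistTriple("r", ("crackle",) * 3))
        assert (d.status, d.label) == (Status.ACCEPTED, "crackle")
        assert d.provenance.value == "unanimous"

    def test_three_way_split_rejected(self):
        d = specialist_round(SpecialistTriple("r", ("crackle", "wheeze", "normal")))
        assert d.status is Status.REJECTED
        assert d.label is None

    def test_two_vs_one_needs_adjudication(self):
        d = specialist_round(SpecialistTriple("r", ("wheeze", "wheeze", "normal")))
        assert d.status is Status.NEEDS_ADJUDICATION

    def test_majority_with_indeterminate_goes_to_experts_by_default(self):
        d = specialist_round(SpecialistTriple("r", ("wheeze", "wheeze", INDETERMINATE)))
        assert d.status is Status.NEEDS_ADJUDICATION

    def test_policy_switch_accepts_majority_with_indeterminate(self):
        d = specialist_round(
            SpecialistTriple("r", ("wheeze", "wheeze", INDETERMINATE)),
            accept_majority_with_indeterminate=True)
        assert (d.status, d.label) == (Status.ACCEPTED, "wheeze")

    def test_exhaustive_truth_table_matches_oracle(self):
        """All 4^3 = 64 triples match an independent enumeration, with
        partition sizes accepted 3 / rejected 34 / adjudication 27."""
        statuses = {}
        for labels in ALL_TRIPLES:
            d = specialist_round(SpecialistTriple("r", labels))
            assert d.status.value == oracle_status(labels), labels
            statuses[labels] = d.status.value
        counts = pd.Series(statuses).value_counts().to_dict()
        assert counts == {"rejected": 34, "needs_adjudication": 27, "accepted": 3}

    def test_symmetric_under_rater_permutation(self):
        for labels in ALL_TRIPLES:
            base = specialist_round(SpecialistTriple("r", labels))
            for perm in itertools.permutations(labels):
                d = specialist_round(SpecialistTriple("r", perm))
                assert (d.status, d.label) == (base.status, base.label)

    def test_no_accepted_label_is_indeterminate(self):
        for labels in ALL_TRIPLES:
            d = specialist_round(SpecialistTriple("r", labels))
            if d.status in (Status.ACCEPTED, Status.ADJUDICATED):
                assert d.label != INDETERMINATE


class TestAdjudicate:
    def pending(self):
        return specialist_round(SpecialistTriple("r", ("wheeze", "wheeze", "normal")))

    def test_expert_confirms(self):
        d = adjudicate(self.pending(), "wheeze")
        assert (d.status, d.label) == (Status.ADJUDICATED, "wheeze")
        assert d.provenance.value == "expert"

    def test_expert_indeterminate_rejects(self):
        assert adjudicate(self.pending(), INDETERMINATE).status is Status.REJECTED

    def test_expert_reject_signal(self):
        assert adjudicate(self.pending(), "reject").status is Status.REJECTED

    def test_state_error_on_settled_decision(self):
        settled = specialist_round(SpecialistTriple("r", ("normal",) * 3))
        with pytest.raises(ValueError, match="status"):
            adjudicate(settled, "normal")

    def test_invalid_decision_construction(self):
        with pytest.raises(ValueError):
            GoldStandardDecision(Status.ACCEPTED, INDETERMINATE)
        with pytest.raises(ValueError):
            GoldStandardDecision(Status.REJECTED, "crackle")


def ratings_frame(rows):
    return pd.DataFrame(
        [{"recording_id": rid, "rater_id": f"s{i}", "label": lab}
         for rid, labels in rows for i, lab in enumerate(labels)],
        columns=["recording_id", "rater_id", "label"],
    )


class TestBuildGoldStandard:
    def test_batch_decisions_and_audit(self):
        ratings = ratings_frame([
            ("a", ("crackle", "crackle", "crackle")),
            ("b", ("crackle", "wheeze", "normal")),
            ("c", ("wheeze", "wheeze", "normal")),
        ])
        experts = pd.DataFrame({"recording_id": ["c"], "expert_label": ["wheeze"]})
        gs = build_gold_standard(ratings, experts)
        by_id = gs.set_index("recording_id")
        assert by_id.loc["a", "status"] == "accepted"
        assert by_id.loc["a", "rule"] == "unanimous"
        assert by_id.loc["b", "status"] == "rejected"
        assert by_id.loc["c", "gs_label"] == "wheeze"
        assert by_id.loc["c", "provenance"] == "expert"

    def test_missing_expert_label_lists_recordings(self):
        ratings = ratings_frame([("x", ("wheeze", "wheeze", "normal"))])
        with pytest.raises(ValueError, match="x"):
            build_gold_standard(ratings, None)

    def test_empty_input_empty_output(self):
        gs = build_gold_standard(ratings_frame([]), None)
        assert len(gs) == 0

    def test_rater_order_irrelevant(self):
        a = build_gold_standard(
            ratings_frame([("r", ("crackle", "normal", "crackle"))]),
            pd.DataFrame({"recording_id": ["r"], "expert_label": ["crackle"]}))
        b = build_gold_standard(
            ratings_frame([("r", ("crackle", "crackle", "normal"))]),
            pd.DataFrame({"recording_id": ["r"], "expert_label": ["crackle"]}))
        pd.testing.assert_frame_equal(a, b)

    def test_wrong_rating_count_rejected(self):
        ratings = ratings_frame([("r", ("crackle", "crackle"))])
        with pytest.raises(ValueError, match="exactly 3"):
            build_gold_standard(ratings, None)
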