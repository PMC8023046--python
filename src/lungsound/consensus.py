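"""Gold-standard consensus over independent specialist triples.

Each recording is labelled independently by three specialists, each
choosing crackle, wheeze, normal, or indeterminate (the rater could not
distinguish the sound). The consensus rules:

* all three agree on a non-indeterminate label -> accepted directly;
* two or more raters indeterminate -> rejected;
* no two raters agree on a non-indeterminate label -> rejected;
* exactly two agree on a non-indeterminate label (the third differs or
  is indeterminate) -> referred to the expert group for adjudication,
  which either confirms a label or rejects the recording.

Rater identity plays no role: decisions are symmetric under permutation
of the three labels. Whether a (X, X, indeterminate) triple goes to the
experts or is accepted outright is a policy switch
(``two_plus_indeterminate``), defaulting to expert referral — only fully
consistent triples qualify directly.
"""

from __future__ import annotations

import dataclasses
import enum
from collections import Counter

import pandas as pd

LABELS = ("crackle", "wheeze", "normal", "indeterminate")
INDETERMINATE = "indeterminate"


class Status(str, enum.Enum):
    ACCEPTED = "accepted"
    REJECTED = "rejected"
    NEEDS_ADJUDICATION = "needs_adjudication"
    ADJUDICATED = "adjudicated"


class Provenance(str, enum.Enum):
    UNANIMOUS = "unanimous"
    EXPERT = "expert"


@dataclasses.dataclass(frozen=True)
class SpecialistTriple:
    recording_id: str
    labels: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.labels) != 3:
            raise ValueError("exactly three specialist labels are required")
        for lab in self.labels:
            if lab not in LABELS:
                raise ValueError(f"unknown label {lab!r}")


@dataclasses.dataclass(frozen=True)
class GoldStandardDecision:
    status: Status
    label: str | None = None
    provenance: Provenance | None = None
    rule: str = ""

    def __post_init__(self) -> None:
        if self.status in (Status.ACCEPTED, Status.ADJUDICATED):
            if self.label is None or self.label == INDETERMINATE:
                raise ValueError("accepted decisions need a definite label")
        if self.status is Status.REJECTED and self.label is not None:
            raise ValueError("rejected decisions carry no label")


def specialist_round(
    triple: SpecialistTriple, accept_majority_with_indeterminate: bool = False
) -> GoldStandardDecision:
    """Apply the specialist-group rules to one triple.

    Total over the full 4^3 label space and symmetric in the three
    labels. With ``accept_majority_with_indeterminate`` the policy switch
    accepts (X, X, indeterminate) outright instead of referring it.
    """
    counts = Counter(triple.labels)
    n_indet = counts[INDETERMINATE]
    definite = Counter({k: v for k, v in counts.items() if k != INDETERMINATE})

    if n_indet == 0 and len(definite) == 1:
        label = next(iter(definite))
        return GoldStandardDecision(Status.ACCEPTED, label, Provenance.UNANIMOUS,
                                    rule="unanimous")
    if n_indet >= 2:
        return GoldStandardDecision(Status.REJECTED, rule="indeterminate_majority")
    majority = [lab for lab, c in definite.items() if c == 2]
    if majority:
        if n_indet == 1 and accept_majority_with_indeterminate:
            return GoldStandardDecision(Status.ACCEPTED, majority[0],
                                        Provenance.UNANIMOUS,
                                        rule="majority_with_indeterminate")
        return GoldStandardDecision(Status.NEEDS_ADJUDICATION,
                                    rule="split_opinion", label=None)
    return GoldStandardDecision(Status.REJECTED, rule="all_inconsistent")


def adjudicate(
    decision: GoldStandardDecision, expert_label: str | None
) -> GoldStandardDecision:
    """Resolve a pending decision with the expert group's label.

    A definite expert label confirms the recording; ``indeterminate``,
    ``None`` or ``"reject"`` rejects it. Calling this on a non-pending
    decision is a state error.
    """
    if decision.status is not Status.NEEDS_ADJUDICATION:
        raise ValueError(
            f"adjudicate called on a decision with status {decision.status.value!r}"
        )
    if expert_label in (None, INDETERMINATE, "reject"):
        return GoldStandardDecision(Status.REJECTED, rule="expert_reject")
    if expert_label not in LABELS:
        raise ValueError(f"unknown expert label {expert_label!r}")
    return GoldStandardDecision(Status.ADJUDICATED, expert_label,
                                Provenance.EXPERT, rule="expert_confirm")


def triples_from_frame(ratings: pd.DataFrame) -> list[SpecialistTriple]:
    """Group a (recording_id, rater_id, label) table into triples."""
    triples = []
    for rec_id, group in ratings.groupby("recording_id", sort=True):
        labs = tuple(group["label"])
        if len(labs) != 3:
            raise ValueError(
                f"recording {rec_id!r} has {len(labs)} ratings; exactly 3 required"
            )
        triples.append(SpecialistTriple(str(rec_id), labs))
    return triples


def build_gold_standard(
    ratings: pd.DataFrame,
    expert_labels: pd.DataFrame | None = None,
    accept_majority_with_indeterminate: bool = False,
) -> pd.DataFrame:
    """Batch consensus: one decision per recording plus an audit trail.

    ``ratings`` columns: recording_id, rater_id, label (3 rows per
    recording). ``expert_labels`` columns: recording_id, expert_label;
    required for every recording whose triple splits 2-vs-1. Returns a
    frame with recording_id, gs_label, status, provenance, rule.
    """
    experts = {}
    if expert_labels is not None and len(expert_labels):
        experts = dict(zip(expert_labels["recording_id"].astype(str),
                           expert_labels["expert_label"]))
    rows = []
    missing = []
    for triple in triples_from_frame(ratings):
        decision = specialist_round(triple, accept_majority_with_indeterminate)
        if decision.status is Status.NEEDS_ADJUDICATION:
            if triple.recording_id not in experts:
                missing.append(triple.recording_id)
                continue
            decision = adjudicate(decision, experts[triple.recording_id])
        rows.append(
            {"recording_id": triple.recording_id,
             "gs_label": decision.label if decision.label else "",
             "status": decision.status.value,
             "provenance": decision.provenance.value if decision.provenance else "",
             "rule": decision.rule}
        )
    if missing:
        raise ValueError(
            "missing expert labels for recordings needing adjudication: "
            + ", ".join(missing)
        )
    return pd.DataFrame(
        rows, columns=["recording_id", "gs_label", "status", "provenance", "rule"]
    )
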