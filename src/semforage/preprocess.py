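"""List- and participant-level exclusion rules with a full audit trail.

A fluency list is invalid if any response time is missing or if it contains
fewer than five valid animal responses (an earnestness floor, counting
non-intrusion, non-perseveration responses).  A participant is removed
entirely if they produced three or more intrusions across their lists, or if
fewer than three valid lists remain.  The retained dataset therefore
contains only participants with exactly three valid lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .coding import CodedDataset, CodedList

__all__ = ["ExclusionReport", "apply_exclusions", "MIN_ANIMALS", "INTRUSION_QUOTA"]

MIN_ANIMALS = 5          # minimum valid animal responses per list
INTRUSION_QUOTA = 3      # intrusions across all lists at which a participant is removed
REQUIRED_LISTS = 3


@dataclass
class ExclusionReport:
    """Per-list and per-participant decisions; nothing is dropped silently.

    Each excluded list carries exactly one primary reason:
    ``missing_rt`` / ``too_few_animals`` (list-level defects, checked in that
    order) or ``intrusion_quota`` / ``incomplete_participant`` (the list was
    fine but its participant was removed).
    """

    list_decisions: list[dict] = field(default_factory=list)
    participant_decisions: list[dict] = field(default_factory=list)
    n_lists_in: int = 0
    n_lists_retained: int = 0
    n_participants_in: int = 0
    n_participants_retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.list_decisions)


def _list_defect(cl: CodedList) -> str | None:
    if cl.has_missing_rt:
        return "missing_rt"
    if cl.n_valid < MIN_ANIMALS:
        return "too_few_animals"
    return None


def apply_exclusions(dataset: CodedDataset) -> tuple[CodedDataset, ExclusionReport]:
    """Apply the exclusion rules; returns (retained dataset, report).

    Idempotent: running it on its own output changes nothing.
    """
    report = ExclusionReport(
        n_lists_in=len(dataset.lists),
        n_participants_in=len(dataset.participant_ids),
    )
    retained_lists: list[CodedList] = []
    for pid, lists in dataset.by_participant().items():
        defects = {id(cl): _list_defect(cl) for cl in lists}
        valid = [cl for cl in lists if defects[id(cl)] is None]
        total_intrusions = sum(cl.n_intrusions for cl in lists)
        if total_intrusions >= INTRUSION_QUOTA:
            participant_reason = "intrusion_quota"
        elif len(valid) < REQUIRED_LISTS:
            participant_reason = "incomplete_participant"
        else:
            participant_reason = None
        report.participant_decisions.append(
            {
                "participant": pid,
                "retained": participant_reason is None,
                "reason": participant_reason,
                "n_valid_lists": len(valid),
                "n_intrusions": total_intrusions,
            }
        )
        for cl in lists:
            defect = defects[id(cl)]
            if defect is not None:
                reason = defect
                kept = False
            elif participant_reason is not None:
                reason = participant_reason
                kept = False
            else:
                reason = None
                kept = True
            report.list_decisions.append(
                {
                    "participant": pid,
                    "trial": cl.trial_index,
                    "retained": kept,
                    "reason": reason,
                    "n_valid_responses": cl.n_valid,
                    "n_intrusions": cl.n_intrusions,
                }
            )
            if kept:
                retained_lists.append(cl)
        if participant_reason is None:
            report.n_participants_retained += 1
    report.n_lists_retained = len(retained_lists)
    return CodedDataset(retained_lists), report
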