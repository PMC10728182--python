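"""Category coding, the fluid switch rule, and cluster segmentation.

A *cluster* (semantic patch) is a maximal run of adjacent valid responses in
which every adjacent pair shares at least one taxonomic category.  A
transition between adjacent responses that share *no* category is a *switch*
(the fluid rule: switch iff the category sets are disjoint; no similarity
thresholds).  Intrusions (items absent from the lexicon) and perseverations
(within-list repeats) are excluded from the comparison chain — a non-animal
cannot define a semantic patch — and, under the default timing policy, their
response time is folded into the following response so elapsed time is
conserved.

Cluster timing follows the patch-foraging reading of the task:

* ``switch_time_ms`` — the inter-item latency spanning the cluster boundary
  (last item of the previous cluster to the first item of this one);
  undefined for the first cluster of a list.
* ``leave_time_ms`` — time from the cluster's first item to its last item
  (0 for singleton clusters).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal, Sequence

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .fluency_io import FluencyList, Lexicon

__all__ = [
    "normalize_item",
    "CodedResponse",
    "CodedList",
    "CodedDataset",
    "Cluster",
    "code_list",
    "code_dataset",
    "segment_clusters",
    "coded_frame",
]

_WS = re.compile(r"\s+")

TimingPolicy = Literal["fold", "drop"]


def normalize_item(raw: str) -> str:
    """Lowercase, strip, and collapse internal whitespace. No spell correction."""
    return _WS.sub(" ", raw.strip()).lower()


@dataclass
class CodedResponse:
    """A response with its category assignment and coding flags.

    ``is_switch`` is None for the first valid response of a list and for
    invalid responses (intrusions/perseverations have no place in the chain).
    """

    participant_id: str
    trial_index: int
    position: int
    item_raw: str
    item_norm: str
    rt_ms: float
    categories: frozenset[str]
    is_intrusion: bool
    is_perseveration: bool
    is_switch: bool | None

    @property
    def is_valid(self) -> bool:
        return not (self.is_intrusion or self.is_perseveration)


@dataclass
class CodedList:
    participant_id: str
    trial_index: int
    responses: list[CodedResponse]

    @property
    def n_valid(self) -> int:
        return sum(r.is_valid for r in self.responses)

    @property
    def n_intrusions(self) -> int:
        return sum(r.is_intrusion for r in self.responses)

    @property
    def has_missing_rt(self) -> bool:
        return any(r.rt_ms != r.rt_ms for r in self.responses)  # NaN check


@dataclass
class CodedDataset:
    """All coded lists of a study, ordered by (participant, trial)."""

    lists: list[CodedList]

    def by_participant(self) -> dict[str, list[CodedList]]:
        out: dict[str, list[CodedList]] = {}
        for cl in self.lists:
            out.setdefault(cl.participant_id, []).append(cl)
        return out

    @property
    def participant_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for cl in self.lists:
            seen.setdefault(cl.participant_id)
        return list(seen)

    def __len__(self) -> int:
        return len(self.lists)


@dataclass
class Cluster:
    """A semantic patch with its timing quantities.

    ``item_offsets_ms[k]`` is the time of the (k+1)-th item measured from the
    cluster's first item; the first offset is always 0 and the last equals
    ``leave_time_ms``.
    """

    participant_id: str
    trial_index: int
    start_position: int
    end_position: int
    item_offsets_ms: list[float] = field(default_factory=list)
    switch_time_ms: float | None = None

    @property
    def n_items(self) -> int:
        return len(self.item_offsets_ms)

    @property
    def leave_time_ms(self) -> float:
        return self.item_offsets_ms[-1]


def code_list(flist: "FluencyList", lexicon: "Lexicon") -> CodedList:
    """Assign categories and flags to every response of one list.

    The switch flag of response *i* compares its categories with those of the
    previous *valid* response: True iff the intersection is empty.
    """
    coded: list[CodedResponse] = []
    seen: set[str] = set()
    prev_valid_cats: frozenset[str] | None = None
    for resp in flist.responses:
        cats = lexicon.categories_of(resp.item_norm)
        is_intrusion = len(cats) == 0
        is_persev = resp.item_norm in seen
        seen.add(resp.item_norm)
        valid = not (is_intrusion or is_persev)
        if not valid:
            is_switch: bool | None = None
        elif prev_valid_cats is None:
            is_switch = None  # first valid response of the list
        else:
            is_switch = len(cats & prev_valid_cats) == 0
        if valid:
            prev_valid_cats = cats
        coded.append(
            CodedResponse(
                participant_id=resp.participant_id,
                trial_index=resp.trial_index,
                position=resp.position,
                item_raw=resp.item_raw,
                item_norm=resp.item_norm,
                rt_ms=resp.rt_ms,
                categories=cats,
                is_intrusion=is_intrusion,
                is_perseveration=is_persev,
                is_switch=is_switch,
            )
        )
    return CodedList(flist.participant_id, flist.trial_index, coded)


def code_dataset(
    lists_by_participant: dict[str, list["FluencyList"]], lexicon: "Lexicon"
) -> CodedDataset:
    coded = [
        code_list(fl, lexicon)
        for pid in lists_by_participant
        for fl in lists_by_participant[pid]
    ]
    return CodedDataset(coded)


def cleaned_responses(
    coded: Sequence[CodedResponse] | CodedList, timing_policy: TimingPolicy = "fold"
) -> list[tuple[CodedResponse, float]]:
    """Valid responses with their effective response times.

    Under ``fold`` (default) the rt of each removed intrusion/perseveration
    is added to the next valid response's rt, conserving elapsed time; under
    ``drop`` invalid rts vanish from the record.
    """
    if isinstance(coded, CodedList):
        coded = coded.responses
    out: list[tuple[CodedResponse, float]] = []
    carry = 0.0
    for r in coded:
        if r.is_valid:
            rt = r.rt_ms + carry if timing_policy == "fold" else r.rt_ms
            out.append((r, rt))
            carry = 0.0
        else:
            carry += r.rt_ms
    return out


def segment_clusters(
    coded: Sequence[CodedResponse] | CodedList,
    timing_policy: TimingPolicy = "fold",
) -> list[Cluster]:
    """Cut a coded list into maximal same-patch runs with their timings.

    Each True switch flag opens a new cluster; the boundary-spanning latency
    becomes the new cluster's ``switch_time_ms`` (None for the first cluster
    of the list, whose entry latency is the trial-start latency, not a
    switch).  Within a cluster, item offsets are cumulative sums of the
    effective inter-item rts.
    """
    cleaned = cleaned_responses(coded, timing_policy)
    clusters: list[Cluster] = []
    cur: Cluster | None = None
    for i, (resp, rt) in enumerate(cleaned):
        opens_new = i == 0 or resp.is_switch
        if opens_new:
            cur = Cluster(
                participant_id=resp.participant_id,
                trial_index=resp.trial_index,
                start_position=resp.position,
                end_position=resp.position,
                item_offsets_ms=[0.0],
                switch_time_ms=None if i == 0 else rt,
            )
            clusters.append(cur)
        else:
            assert cur is not None
            cur.item_offsets_ms.append(cur.item_offsets_ms[-1] + rt)
            cur.end_position = resp.position
    return clusters


def coded_frame(dataset: CodedDataset, timing_policy: TimingPolicy = "fold") -> "pd.DataFrame":
    """Audit export: one row per response with flags and cluster ids."""
    import pandas as pd

    rows = []
    cluster_counter = 0
    for cl in dataset.lists:
        clusters = segment_clusters(cl, timing_policy)
        pos_to_cluster: dict[int, int] = {}
        for k, c in enumerate(clusters):
            for p in range(c.start_position, c.end_position + 1):
                pos_to_cluster[p] = cluster_counter + k
        for r in cl.responses:
            rows.append(
                {
                    "participant": r.participant_id,
                    "trial": r.trial_index,
                    "position": r.position,
                    "item": r.item_norm,
                    "rt_ms": r.rt_ms,
                    "categories": ";".join(sorted(r.categories)),
                    "is_intrusion": r.is_intrusion,
                    "is_perseveration": r.is_perseveration,
                    "is_switch": r.is_switch,
                    "cluster_id": pos_to_cluster.get(r.position) if r.is_valid else None,
                }
            )
        cluster_counter += len(clusters)
    return pd.DataFrame(rows)
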