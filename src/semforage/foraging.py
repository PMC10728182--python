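"""Retrieval curves and marginal-value-theorem quantities.

The analysis treats memory search as patch foraging.  For a set of clusters
(patches) it computes:

* ``S`` — the mean between-cluster switch time (first-cluster entries are
  not switches and are excluded);
* ``L̂`` — the mean empirical leave time (time from first to last item of a
  cluster; singletons contribute 0);
* ``g(t)`` — the average retrieval curve, the mean cumulative number of
  items produced by time *t* since cluster entry, a non-decreasing step
  function;
* ``t*`` — the MVT-optimal leave time, ``argmax_t g(t) / (S + t)``, i.e.
  the residence time that maximizes the long-run rate of producing items
  when every patch visit costs ``S`` of travel.

Because ``g`` is piecewise constant and the denominator strictly
increasing, the maximizer lies on the jump set, so the search evaluates
exactly the jump times (ties broken by the earliest maximizer).  The
maximized rate ``g(t*)/(S+t*)`` is the slope of the line from ``(-S, 0)``
through ``(t*, g(t*))`` — the classic tangent construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .coding import Cluster, CodedDataset, TimingPolicy, segment_clusters

__all__ = [
    "RetrievalCurve",
    "MVTResult",
    "ClusterArrays",
    "cluster_step_function",
    "average_retrieval_curve",
    "mean_switch_time",
    "mean_leave_time",
    "optimal_leave_time",
    "mvt_from_arrays",
    "mvt_analysis",
]

HoldPolicy = Literal["hold", "truncate"]
Scope = Literal["group", "participant", "trial"]


@dataclass
class RetrievalCurve:
    """Mean cumulative retrievals vs. time-in-cluster, as a step function.

    ``values[i]`` is g(t) for ``jump_times_ms[i] <= t < jump_times_ms[i+1]``.
    Under the default hold policy every cluster contributes at every t (its
    count held at the final value beyond its own leave time), so values are
    non-decreasing and ``g(0) >= 1``.
    """

    jump_times_ms: np.ndarray
    values: np.ndarray
    n_clusters: int
    t_max_ms: float

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.jump_times_ms, t, side="right") - 1
        return self.values[np.clip(idx, 0, len(self.values) - 1)]


@dataclass
class MVTResult:
    scope: str
    label: str
    switch_time_mean_ms: float
    empirical_leave_mean_ms: float
    optimal_leave_ms: float
    abs_deviance_ms: float
    max_rate_per_ms: float
    n_clusters: int
    n_switch_times: int

    @property
    def relative_deviance(self) -> float:
        """|t* - L̂| / L̂ — the scale-free adherence measure."""
        return self.abs_deviance_ms / self.empirical_leave_mean_ms

    @property
    def signed_deviance_ms(self) -> float:
        """L̂ - t*: positive when patches are overstayed relative to optimal."""
        return self.empirical_leave_mean_ms - self.optimal_leave_ms


@dataclass
class ClusterArrays:
    """Columnar view of a cluster collection for fast, repeated MVT evaluation.

    ``pos_offsets_ms`` pools the strictly-positive item offsets of all
    clusters (items after each cluster's entry item); ``offset_cluster_idx``
    maps each one back to its cluster row.
    """

    leave_times_ms: np.ndarray
    switch_times_ms: np.ndarray          # defined switch times only
    pos_offsets_ms: np.ndarray
    offset_cluster_idx: np.ndarray
    n_items: np.ndarray

    @classmethod
    def from_clusters(cls, clusters: Sequence[Cluster]) -> "ClusterArrays":
        leave = np.array([c.leave_time_ms for c in clusters], dtype=float)
        switch = np.array(
            [c.switch_time_ms for c in clusters if c.switch_time_ms is not None],
            dtype=float,
        )
        pos, idx = [], []
        for k, c in enumerate(clusters):
            pos.extend(c.item_offsets_ms[1:])
            idx.extend([k] * (c.n_items - 1))
        return cls(
            leave_times_ms=leave,
            switch_times_ms=switch,
            pos_offsets_ms=np.asarray(pos, dtype=float),
            offset_cluster_idx=np.asarray(idx, dtype=int),
            n_items=np.array([c.n_items for c in clusters], dtype=int),
        )

    @property
    def n_clusters(self) -> int:
        return len(self.leave_times_ms)


def cluster_step_function(cluster: Cluster) -> tuple[np.ndarray, np.ndarray]:
    """Single-cluster retrieval curve: count k at the offset of the k-th item."""
    times = np.asarray(cluster.item_offsets_ms, dtype=float)
    counts = np.arange(1, cluster.n_items + 1, dtype=float)
    return times, counts


def _as_arrays(clusters) -> ClusterArrays:
    if isinstance(clusters, ClusterArrays):
        return clusters
    return ClusterArrays.from_clusters(list(clusters))


def average_retrieval_curve(
    clusters: Iterable[Cluster] | ClusterArrays,
    hold_policy: HoldPolicy = "hold",
    t_max: float | None = None,
) -> RetrievalCurve:
    """Average the single-cluster step functions into g(t).

    Under ``hold`` (default) each cluster's step function is held at its
    final count beyond its own leave time, so every cluster contributes at
    every t and the curve is non-decreasing.  Under ``truncate`` a cluster
    stops contributing after its own leave time and g(t) averages only the
    still-active clusters (a survivorship-weighted curve; may decrease).
    """
    arr = _as_arrays(clusters)
    n = arr.n_clusters
    if n == 0:
        raise ValueError("cannot average an empty cluster collection")
    cap = float(np.max(arr.leave_times_ms)) if t_max is None else float(t_max)
    off = np.sort(arr.pos_offsets_ms[arr.pos_offsets_ms <= cap])
    jumps = np.unique(np.concatenate(([0.0], off)))
    if hold_policy == "hold":
        g = 1.0 + np.searchsorted(off, jumps, side="right") / n
    elif hold_policy == "truncate":
        order = np.argsort(arr.leave_times_ms, kind="stable")
        leave_sorted = arr.leave_times_ms[order]
        extra_sorted = (arr.n_items[order] - 1).astype(float)
        cum_extra = np.concatenate(([0.0], np.cumsum(extra_sorted)))
        n_left = np.searchsorted(leave_sorted, jumps, side="left")  # leave < t
        active = n - n_left
        b = np.searchsorted(off, jumps, side="right").astype(float)
        g = (active + b - cum_extra[n_left]) / active
    else:
        raise ValueError(f"unknown hold_policy {hold_policy!r}")
    return RetrievalCurve(jump_times_ms=jumps, values=g, n_clusters=n, t_max_ms=cap)


def mean_switch_time(clusters: Iterable[Cluster] | ClusterArrays) -> float:
    """Mean over defined switch times; first clusters of a list contribute none."""
    arr = _as_arrays(clusters)
    if len(arr.switch_times_ms) == 0:
        raise ValueError("no defined switch times: cannot run the MVT analysis")
    return float(np.mean(arr.switch_times_ms))


def mean_leave_time(clusters: Iterable[Cluster] | ClusterArrays) -> float:
    """Mean empirical leave time over all clusters (singletons contribute 0)."""
    arr = _as_arrays(clusters)
    if arr.n_clusters == 0:
        raise ValueError("no clusters")
    return float(np.mean(arr.leave_times_ms))


def optimal_leave_time(curve: RetrievalCurve, S: float) -> tuple[float, float]:
    """MVT-optimal residence time on a retrieval curve with travel cost S.

    Returns ``(t*, max_rate)``.  Evaluates the rate g(t)/(S+t) exactly on the
    curve's jump set (where any maximizer of a piecewise-constant numerator
    over an increasing denominator must lie); ties go to the earliest time.
    """
    if S <= 0:
        raise ValueError("switch time S must be positive")
    rates = curve.values / (S + curve.jump_times_ms)
    i = int(np.argmax(rates))
    return float(curve.jump_times_ms[i]), float(rates[i])


def mvt_from_arrays(
    arr: ClusterArrays,
    hold_policy: HoldPolicy = "hold",
    t_max: float | None = None,
    scope: str = "group",
    label: str = "group",
) -> MVTResult:
    """Full MVT computation from columnar cluster data."""
    S = mean_switch_time(arr)
    L_hat = mean_leave_time(arr)
    curve = average_retrieval_curve(arr, hold_policy=hold_policy, t_max=t_max)
    t_star, max_rate = optimal_leave_time(curve, S)
    return MVTResult(
        scope=scope,
        label=label,
        switch_time_mean_ms=S,
        empirical_leave_mean_ms=L_hat,
        optimal_leave_ms=t_star,
        abs_deviance_ms=abs(t_star - L_hat),
        max_rate_per_ms=max_rate,
        n_clusters=arr.n_clusters,
        n_switch_times=len(arr.switch_times_ms),
    )


def dataset_clusters(
    dataset: CodedDataset, timing_policy: TimingPolicy = "fold"
) -> list[Cluster]:
    out: list[Cluster] = []
    for cl in dataset.lists:
        out.extend(segment_clusters(cl, timing_policy))
    return out


def mvt_analysis(
    dataset: CodedDataset,
    scope: Scope = "group",
    timing_policy: TimingPolicy = "fold",
    hold_policy: HoldPolicy = "hold",
    t_max: float | None = None,
) -> list[MVTResult]:
    """Run the MVT analysis at group, participant, or trial scope.

    * ``group`` — one result pooling every cluster in the dataset;
    * ``participant`` — one result per participant (their own clusters,
      all three lists); participants with no defined switch time cannot be
      analyzed and are omitted;
    * ``trial`` — one result per trial index, pooling all participants.
    """
    clusters = dataset_clusters(dataset, timing_policy)
    if scope == "group":
        return [mvt_from_arrays(ClusterArrays.from_clusters(clusters),
                                hold_policy, t_max, "group", "group")]
    if scope == "participant":
        groups: dict[str, list[Cluster]] = {}
        for c in clusters:
            groups.setdefault(c.participant_id, []).append(c)
        results = []
        for pid, cs in groups.items():
            arr = ClusterArrays.from_clusters(cs)
            if len(arr.switch_times_ms) == 0:
                continue  # no defined switch time: flagged out of downstream stats
            results.append(mvt_from_arrays(arr, hold_policy, t_max, "participant", pid))
        return results
    if scope == "trial":
        groups_t: dict[int, list[Cluster]] = {}
        for c in clusters:
            groups_t.setdefault(c.trial_index, []).append(c)
        return [
            mvt_from_arrays(ClusterArrays.from_clusters(groups_t[t]),
                            hold_policy, t_max, "trial", str(t))
            for t in sorted(groups_t)
        ]
    raise ValueError(f"unknown scope {scope!r}")
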