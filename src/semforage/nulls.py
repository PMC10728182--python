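"""Permutation chance baselines for deviance from MVT-optimality.

The null hypothesis is that the observed closeness of empirical and optimal
leave times is an artifact of the response-time distribution rather than of
*when* switches happen.  Simulated datasets are built by permuting the
inter-item response times while keeping the sequence of items — and hence
the pattern of cluster switches — fixed.  Each permuted dataset yields a new
empirical leave time, retrieval curve, optimal leave time, and absolute
deviance; the empirical deviance is compared against that distribution.

By default the permutable pool is the inter-item rts at positions >= 2
(trial-start latencies are neither switch nor within-cluster transitions and
stay fixed; a config flag includes them).  Group scope shuffles the pool
across the whole dataset; participant scope shuffles within each
participant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .coding import CodedDataset, CodedList, TimingPolicy, cleaned_responses
from .foraging import ClusterArrays, HoldPolicy, mvt_from_arrays, MVTResult
from .stats import exact_binomial

__all__ = [
    "PermutationNull",
    "CompiledTiming",
    "compile_timing",
    "permute_rts",
    "null_distribution",
    "individual_optimality_test",
]


@dataclass
class PermutationNull:
    scope: str
    n_perms: int
    seed: int
    deviances_ms: np.ndarray
    empirical_deviance_ms: float
    empirical: MVTResult

    @property
    def mean_ms(self) -> float:
        return float(np.mean(self.deviances_ms))

    @property
    def min_ms(self) -> float:
        return float(np.min(self.deviances_ms))

    @property
    def exceedance(self) -> float:
        """Fraction of permuted deviances <= the empirical deviance."""
        return float(np.mean(self.deviances_ms <= self.empirical_deviance_ms))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"perm": np.arange(self.n_perms),
                             "abs_deviance_ms": self.deviances_ms})


@dataclass
class CompiledTiming:
    """Columnar timing view of a coded dataset for fast re-evaluation.

    Holds one row per *valid* response (invalid rts already folded per the
    timing policy), in (participant, trial, position) order, plus the fixed
    cluster structure.  Re-deriving cluster timings for a permuted rt vector
    is pure vectorized arithmetic — the switch-flag pattern never changes.
    """

    rt: np.ndarray                  # effective rt per valid response
    participant_idx: np.ndarray     # dense participant index per response
    first_in_list: np.ndarray       # bool
    first_in_cluster: np.ndarray    # bool
    cluster_counts: np.ndarray      # items per cluster, cluster order
    cluster_first_of_list: np.ndarray
    cluster_participant_idx: np.ndarray
    participant_ids: list[str]
    permutable: np.ndarray          # bool mask over responses

    def cluster_arrays(self, rt: np.ndarray | None = None) -> ClusterArrays:
        rt = self.rt if rt is None else rt
        rt_in = np.where(self.first_in_cluster, 0.0, rt)
        cs = np.cumsum(rt_in)
        starts = np.flatnonzero(self.first_in_cluster)
        base = np.repeat(cs[starts], self.cluster_counts)
        offsets = cs - base
        ends = starts + self.cluster_counts - 1
        leave = offsets[ends]
        switch = rt[starts][~self.cluster_first_of_list]
        mask = ~self.first_in_cluster
        return ClusterArrays(
            leave_times_ms=leave,
            switch_times_ms=switch,
            pos_offsets_ms=offsets[mask],
            offset_cluster_idx=np.repeat(
                np.arange(len(starts)), self.cluster_counts - 1
            ),
            n_items=self.cluster_counts.copy(),
        )

    def select_participant(self, idx: int) -> "CompiledTiming":
        rmask = self.participant_idx == idx
        cmask = self.cluster_participant_idx == idx
        return CompiledTiming(
            rt=self.rt[rmask],
            participant_idx=np.zeros(int(rmask.sum()), dtype=int),
            first_in_list=self.first_in_list[rmask],
            first_in_cluster=self.first_in_cluster[rmask],
            cluster_counts=self.cluster_counts[cmask],
            cluster_first_of_list=self.cluster_first_of_list[cmask],
            cluster_participant_idx=np.zeros(int(cmask.sum()), dtype=int),
            participant_ids=[self.participant_ids[idx]],
            permutable=self.permutable[rmask],
        )


def compile_timing(
    dataset: CodedDataset,
    timing_policy: TimingPolicy = "fold",
    include_first_latencies: bool = False,
) -> CompiledTiming:
    pids = dataset.participant_ids
    pid_index = {p: i for i, p in enumerate(pids)}
    rt, p_idx, first_list, first_cluster = [], [], [], []
    c_counts, c_first, c_pidx = [], [], []
    ordered = sorted(dataset.lists, key=lambda cl: (cl.participant_id, cl.trial_index))
    for cl in ordered:
        cleaned = cleaned_responses(cl, timing_policy)
        if not cleaned:
            continue
        count = 0
        for i, (resp, eff_rt) in enumerate(cleaned):
            opens = i == 0 or resp.is_switch
            if opens:
                if count:
                    c_counts.append(count)
                count = 0
                c_first.append(i == 0)
                c_pidx.append(pid_index[cl.participant_id])
            count += 1
            rt.append(eff_rt)
            p_idx.append(pid_index[cl.participant_id])
            first_list.append(i == 0)
            first_cluster.append(opens)
        c_counts.append(count)
    first_list_arr = np.asarray(first_list, dtype=bool)
    permutable = (
        np.ones_like(first_list_arr) if include_first_latencies else ~first_list_arr
    )
    return CompiledTiming(
        rt=np.asarray(rt, dtype=float),
        participant_idx=np.asarray(p_idx, dtype=int),
        first_in_list=first_list_arr,
        first_in_cluster=np.asarray(first_cluster, dtype=bool),
        cluster_counts=np.asarray(c_counts, dtype=int),
        cluster_first_of_list=np.asarray(c_first, dtype=bool),
        cluster_participant_idx=np.asarray(c_pidx, dtype=int),
        participant_ids=list(pids),
        permutable=permutable,
    )


def _permuted_rt(timing: CompiledTiming, scope: str, rng: np.random.Generator) -> np.ndarray:
    rt = timing.rt.copy()
    if scope == "group":
        pools = [timing.permutable]
    elif scope == "participant":
        pools = [
            timing.permutable & (timing.participant_idx == i)
            for i in range(len(timing.participant_ids))
        ]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    for mask in pools:
        idx = np.flatnonzero(mask)
        if len(idx) < 2:
            raise ValueError("scope has fewer than 2 permutable response times")
        rt[idx] = rng.permutation(rt[idx])
    return rt


def permute_rts(
    dataset: CodedDataset,
    scope: str = "group",
    rng: np.random.Generator | None = None,
    timing_policy: TimingPolicy = "fold",
    include_first_latencies: bool = False,
) -> CodedDataset:
    """Return a copy of the dataset with permuted inter-item response times.

    Item sequences and switch flags are untouched; only the rt values of the
    permutable responses move.  Operates on effective (fold-cleaned) lists,
    so the output contains only valid responses.
    """
    rng = np.random.default_rng() if rng is None else rng
    timing = compile_timing(dataset, timing_policy, include_first_latencies)
    new_rt = _permuted_rt(timing, scope, rng)
    new_lists: list[CodedList] = []
    pos = 0
    ordered = sorted(dataset.lists, key=lambda cl: (cl.participant_id, cl.trial_index))
    for cl in ordered:
        cleaned = cleaned_responses(cl, timing_policy)
        new_responses = []
        for resp, _ in cleaned:
            new_responses.append(replace(resp, rt_ms=float(new_rt[pos])))
            pos += 1
        new_lists.append(CodedList(cl.participant_id, cl.trial_index, new_responses))
    return CodedDataset(new_lists)


def null_distribution(
    dataset: CodedDataset | CompiledTiming,
    scope: str = "group",
    n_perms: int = 1000,
    seed: int = 0,
    timing_policy: TimingPolicy = "fold",
    hold_policy: HoldPolicy = "hold",
    t_max: float | None = None,
    include_first_latencies: bool = False,
) -> PermutationNull:
    """Distribution of |t* - L̂| over rt-permuted datasets at the given scope.

    Seeded and bit-reproducible; each permutation re-runs the full MVT
    computation (leave times, retrieval curve, optimal leave time) under the
    same configuration as the empirical analysis.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    timing = (
        dataset
        if isinstance(dataset, CompiledTiming)
        else compile_timing(dataset, timing_policy, include_first_latencies)
    )
    empirical = mvt_from_arrays(timing.cluster_arrays(), hold_policy, t_max)
    rng = np.random.default_rng(seed)
    devs = np.empty(n_perms)
    for k in range(n_perms):
        rt = _permuted_rt(timing, scope, rng)
        res = mvt_from_arrays(timing.cluster_arrays(rt), hold_policy, t_max)
        devs[k] = res.abs_deviance_ms
    return PermutationNull(
        scope=scope,
        n_perms=n_perms,
        seed=seed,
        deviances_ms=devs,
        empirical_deviance_ms=empirical.abs_deviance_ms,
        empirical=empirical,
    )


def individual_optimality_test(
    dataset: CodedDataset,
    n_perms: int = 1000,
    seed: int = 0,
    timing_policy: TimingPolicy = "fold",
    hold_policy: HoldPolicy = "hold",
) -> tuple[pd.DataFrame, dict]:
    """Per-participant permutation test plus the binomial summary.

    For each participant, their own rts are permuted ``n_perms`` times and
    their empirical deviance is compared with the mean permuted deviance.
    The summary counts participants whose empirical deviance is below their
    null mean and reports the exact one-sided binomial tail probability
    P(X >= k | n, 1/2).
    """
    timing = compile_timing(dataset, timing_policy)
    child_seeds = np.random.SeedSequence(seed).spawn(len(timing.participant_ids))
    rows = []
    for i, pid in enumerate(timing.participant_ids):
        sub = timing.select_participant(i)
        if (~sub.cluster_first_of_list).sum() == 0:
            continue  # no defined switch times; cannot be analyzed
        sub_seed = int(child_seeds[i].generate_state(1)[0] % (2**31))
        null = null_distribution(
            sub, scope="group", n_perms=n_perms, seed=sub_seed,
            hold_policy=hold_policy,
        )
        rows.append(
            {
                "participant": pid,
                "empirical_deviance_ms": null.empirical_deviance_ms,
                "null_mean_ms": null.mean_ms,
                "null_min_ms": null.min_ms,
                "below_null_mean": null.empirical_deviance_ms < null.mean_ms,
            }
        )
    table = pd.DataFrame(rows)
    k = int(table["below_null_mean"].sum())
    n = len(table)
    summary = {
        "n_participants": n,
        "n_below_null_mean": k,
        "proportion": k / n if n else float("nan"),
        "mean_empirical_deviance_ms": float(table["empirical_deviance_ms"].mean()),
        "mean_null_deviance_ms": float(table["null_mean_ms"].mean()),
        "binomial_p": exact_binomial(k, n, 0.5, alternative="greater"),
    }
    return table, summary
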