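"""Synthetic fluency-data generator with known foraging ground truth.

The generator emulates the structure the analysis assumes: a timed
free-listing task in which an agent visits semantic patches, experiences
diminishing returns within a patch (each successive item is slower by a
geometric factor ``gamma``), pays a travel cost to reach a new patch
(switch latencies longer than within-cluster latencies), and leaves each
patch according to a configurable policy.  The marginal-value-theorem
optimum for this environment is computable in closed form over leave
counts, so every pipeline stage can be validated against ground truth.

Defaults describe the study conditions this package analyses: three
3-minute trials per participant, mean switch latency 6 s, first
within-cluster transition 3 s with gamma = 1.35 (giving an optimal leave
count of 3 items and an optimal residence time of ~7.05 s, in the range of
the human data), right-skewed (lognormal) latency noise.

Age models implement the two theories the analysis is designed to
discriminate:

* ``global_slowing`` — all latencies scale by a common age factor; the MVT
  prediction is scale invariant, so adherence to optimality is untouched.
* ``switch_delay`` — an executive-style deficit in *disengaging* from a
  patch: the agent's leave threshold is discounted with age, so patches are
  overstayed increasingly (observed leave times exceed the optimum more and
  more), while switch latencies themselves stay put.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .fluency_io import Lexicon

__all__ = [
    "LexiconSpec",
    "GeneratorConfig",
    "generate_lexicon",
    "solve_optimal_threshold",
    "simulate_dataset",
    "SimulatedStudy",
]

AgeModel = Literal["none", "global_slowing", "switch_delay"]
NoiseFamily = Literal["lognormal", "gamma", "exponential"]


@dataclass(frozen=True)
class LexiconSpec:
    n_categories: int = 30
    items_per_category: int = 12
    overlap_p: float = 0.0  # probability an item is shared with the next category


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the simulator (times in milliseconds)."""

    n_participants: int = 527
    trials_per_participant: int = 3
    trial_duration_ms: float = 180_000.0
    lexicon: LexiconSpec = field(default_factory=LexiconSpec)
    mu_within_ms: float = 3000.0     # mean of the first within-patch transition
    gamma: float = 1.35              # geometric slowdown per successive item
    mu_switch_ms: float = 6000.0     # mean patch-to-patch travel latency
    policy: tuple = ("mvt_optimal",)  # or ("fixed_k", k) / ("threshold_scale", c)
    age_model: AgeModel = "none"
    age_slope: float = 0.5           # effect size at the oldest age (see age models)
    age_range: tuple[int, int] = (25, 69)
    noise: NoiseFamily = "lognormal"
    cv: float = 0.3                  # coefficient of variation of latency noise
    seed: int = 0

    def __post_init__(self):
        if min(self.mu_within_ms, self.mu_switch_ms, self.trial_duration_ms) <= 0:
            raise ValueError("latency means and trial duration must be positive")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1 (diminishing returns)")


@dataclass
class SimulatedStudy:
    """A simulated cohort: canonical table, lexicon, and ground truth."""

    responses: pd.DataFrame       # participant, trial, position, item, rt_ms
    lexicon: Lexicon
    ground_truth: dict

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.responses.to_csv(out_dir / "fluency.csv", index=False,
                              float_format="%.3f")
        rows = [
            {"category": cat, "member": item}
            for item, cats in sorted(self.lexicon.entries.items())
            for cat in sorted(cats)
        ]
        pd.DataFrame(rows).to_csv(out_dir / "lexicon.csv", index=False)
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=2)


def generate_lexicon(
    spec: LexiconSpec, rng: np.random.Generator | None = None
) -> Lexicon:
    """Synthetic item names grouped into categories, disjoint by default.

    With ``overlap_p`` > 0, each item is additionally assigned to the next
    category (cyclically) with that probability, exercising the
    multi-category path of the switch rule.
    """
    if spec.n_categories < 2 or spec.items_per_category < 2:
        raise ValueError("need >=2 categories with >=2 items each")
    if not 0.0 <= spec.overlap_p <= 1.0:
        raise ValueError("overlap_p must lie in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    entries: dict[str, frozenset[str]] = {}
    for c in range(spec.n_categories):
        cat = f"cat{c:02d}"
        for i in range(spec.items_per_category):
            item = f"animal_{c:02d}_{i:02d}"
            cats = {cat}
            if spec.overlap_p > 0 and rng.random() < spec.overlap_p:
                cats.add(f"cat{(c + 1) % spec.n_categories:02d}")
            entries[item] = frozenset(cats)
    return Lexicon(entries)


def _within_time(k: int, mu_w: float, gamma: float) -> float:
    """Expected residence time after k items: sum of the first k-1 transitions."""
    if k <= 1:
        return 0.0
    if gamma == 1.0:
        return mu_w * (k - 1)
    return mu_w * (gamma ** (k - 1) - 1.0) / (gamma - 1.0)


def _leave_count_for_rate(rate: float, mu_w: float, gamma: float, k_max: int = 1000) -> int:
    """Smallest patch size at which the marginal item rate drops below ``rate``.

    The agent holding k items faces a next transition with mean
    mu_w * gamma**(k-1); it stays while 1 / (mu_w * gamma**(k-1)) >= rate.
    """
    k = 1
    while k < k_max and 1.0 / (mu_w * gamma ** (k - 1)) >= rate:
        k += 1
    return k


def solve_optimal_threshold(
    config: GeneratorConfig,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> dict:
    """Self-consistent MVT solution for the generator's environment.

    Fixed-point iteration on the long-run rate R: given a candidate R, the
    agent leaves after the item count k(R) at which the marginal rate falls
    below R; the implied cycle rate is k / (mu_switch + within_time(k)).
    Returns ``{"rate_per_ms": R*, "leave_count": k*, "leave_time_ms": ...}``.
    """
    mu_w, g, mu_s = config.mu_within_ms, config.gamma, config.mu_switch_ms
    rate = 1.0 / (mu_s + mu_w)  # rate of a 2-item cycle as a starting point
    for _ in range(max_iter):
        k = _leave_count_for_rate(rate, mu_w, g)
        new_rate = k / (mu_s + _within_time(k, mu_w, g))
        if abs(new_rate - rate) <= tol * rate:
            rate = new_rate
            break
        rate = new_rate
    else:
        raise ArithmeticError("MVT fixed-point iteration did not converge")
    k = _leave_count_for_rate(rate, mu_w, g)
    # guard against limit cycles between adjacent counts: take the best of the two
    best_k = max(
        (k_try for k_try in {max(k - 1, 1), k, k + 1}),
        key=lambda kk: kk / (mu_s + _within_time(kk, mu_w, g)),
    )
    best_rate = best_k / (mu_s + _within_time(best_k, mu_w, g))
    return {
        "rate_per_ms": best_rate,
        "leave_count": int(best_k),
        "leave_time_ms": _within_time(best_k, mu_w, g),
    }


def _draw_latency(rng: np.random.Generator, mean: float, family: str, cv: float) -> float:
    if family == "lognormal":
        sigma2 = np.log1p(cv * cv)
        return float(rng.lognormal(np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)))
    if family == "gamma":
        shape = 1.0 / (cv * cv)
        return float(rng.gamma(shape, mean / shape))
    if family == "exponential":
        return float(rng.exponential(mean))
    raise ValueError(f"unknown noise family {family!r}")


def _age_norm(age: float, age_range: tuple[int, int]) -> float:
    lo, hi = age_range
    return (age - lo) / (hi - lo)


def simulate_dataset(config: GeneratorConfig) -> SimulatedStudy:
    """Simulate a cohort of patch-foraging fluency participants.

    Per trial the agent alternates patch visits: draw a travel latency
    (also the first-item latency at trial start), then successive
    within-patch transitions with means mu_within * gamma**(j-1), items
    sampled without replacement from one category per patch.  The agent
    leaves after its policy's item count; the trial ends when the next
    response would cross the time limit.
    """
    rng = np.random.default_rng(config.seed)
    lexicon = generate_lexicon(config.lexicon, rng)
    mvt = solve_optimal_threshold(config)
    categories: dict[str, list[str]] = {}
    for item, cats in sorted(lexicon.entries.items()):
        for cat in sorted(cats):
            categories.setdefault(cat, []).append(item)
    cat_names = sorted(categories)

    ages = rng.integers(config.age_range[0], config.age_range[1] + 1,
                        size=config.n_participants)
    rows: list[dict] = []
    per_participant: list[dict] = []
    for p in range(config.n_participants):
        pid = f"p{p + 1:04d}"
        a = _age_norm(float(ages[p]), config.age_range)
        scale_all = scale_switch = 1.0
        threshold_factor = 1.0
        if config.age_model == "global_slowing":
            scale_all = 1.0 + config.age_slope * a
        elif config.age_model == "switch_delay":
            # delayed disengagement: lower leave threshold -> overstays patches
            threshold_factor = 1.0 / (1.0 + config.age_slope * a)

        if config.policy[0] == "mvt_optimal":
            k_leave = _leave_count_for_rate(
                threshold_factor * mvt["rate_per_ms"], config.mu_within_ms, config.gamma
            )
        elif config.policy[0] == "fixed_k":
            k_leave = int(config.policy[1])
        elif config.policy[0] == "threshold_scale":
            k_leave = _leave_count_for_rate(
                float(config.policy[1]) * threshold_factor * mvt["rate_per_ms"],
                config.mu_within_ms, config.gamma,
            )
        else:
            raise ValueError(f"unknown policy {config.policy!r}")

        per_participant.append(
            {"participant": pid, "age": int(ages[p]), "scale_all": scale_all,
             "leave_count": int(k_leave)}
        )
        for trial in range(1, config.trials_per_participant + 1):
            t = 0.0
            position = 0
            used: set[str] = set()
            cat_order = list(rng.permutation(cat_names))
            cat_cursor = 0
            exhausted = False
            while not exhausted:
                # travel to (or initially, find) a patch
                while cat_cursor < len(cat_order):
                    cat = cat_order[cat_cursor]
                    pool = [i for i in categories[cat] if i not in used]
                    if len(pool) >= 1:
                        break
                    cat_cursor += 1
                else:
                    break  # lexicon exhausted: truncate the list
                cat_cursor += 1
                latency = scale_all * scale_switch * _draw_latency(
                    rng, config.mu_switch_ms, config.noise, config.cv
                )
                if t + latency > config.trial_duration_ms:
                    break
                t += latency
                order = rng.permutation(len(pool))
                n_in_patch = min(k_leave, len(pool))
                for j in range(n_in_patch):
                    if j > 0:
                        mean = config.mu_within_ms * config.gamma ** (j - 1)
                        latency = scale_all * _draw_latency(
                            rng, mean, config.noise, config.cv
                        )
                        if t + latency > config.trial_duration_ms:
                            exhausted = True
                            break
                        t += latency
                    item = pool[order[j]]
                    used.add(item)
                    position += 1
                    rows.append(
                        {"participant": pid, "trial": trial, "position": position,
                         "item": item, "rt_ms": latency}
                    )

    frame = pd.DataFrame(rows)
    truth = {
        "config": _config_dict(config),
        "optimal_rate_per_ms": mvt["rate_per_ms"],
        "optimal_leave_count": mvt["leave_count"],
        "optimal_leave_time_ms": mvt["leave_time_ms"],
        "participants": per_participant,
    }
    return SimulatedStudy(responses=frame, lexicon=lexicon, ground_truth=truth)


def _config_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["policy"] = list(config.policy)
    d["age_range"] = list(config.age_range)
    return d
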