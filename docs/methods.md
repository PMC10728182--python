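# Methods

This note documents the model implemented by `semforage`, the defaults and
why they were chosen, the numerical decisions, what the synthetic
generator does and does not emulate, and the package's known limitations.

## The foraging model of fluency

Semantic fluency is modelled as patch foraging.  A *cluster* (patch) is a
maximal run of adjacent valid responses in which every adjacent pair
shares at least one category from the dictionary — the *fluid* switch
rule: a switch occurs exactly when the category sets of two adjacent
responses are disjoint.  No similarity thresholds, embeddings, or human
annotation are used; items carrying several categories (e.g. *dog* ∈
{Pets, Canine}) simply make switches rarer, because the rule uses set
intersection.

Three quantities summarize a cluster set:

- the mean **switch time** S (the inter-item latency spanning each cluster
  boundary; entering the first cluster of a list is not a switch and
  contributes nothing);
- the mean **empirical leave time** L̂ (time from a cluster's first to its
  last item; singleton clusters are genuine clusters with leave time 0 and
  are retained — they are the patches abandoned after a single find);
- the **average retrieval curve** g(t), the mean over clusters of each
  cluster's cumulative-count step function at time t since cluster entry.

The marginal value theorem says a forager maximizes its long-run rate by
leaving each patch when the local rate of return falls to the global
average rate.  Operationally the optimal residence time is

    t* = argmax_{t in [0, t_max]}  g(t) / (S + t),

and the maximized rate g(t\*)/(S+t\*) equals the slope of the line from
(−S, 0) tangent to the curve — the classic graphical construction, which
the `report` command draws.  **Deviance from optimality** is |t\* − L̂|;
its scale-free form |t\* − L̂|/L̂ is the package's *adherence* measure
(below).

Assumptions inherited from the model: the switch cost and the
within-cluster return structure are treated as fixed over the task and
summarized by averages; patches are abundant (no depletion of the patch
*supply*); and response times index search effort.

## Numerical choices

- **Jump-set optimization.**  g is piecewise constant and t ↦ S+t is
  strictly increasing, so any maximizer of the rate lies on the jump set
  of g.  The optimizer evaluates exactly those points; ties go to the
  earliest time.  A test compares 1,000 random step curves against a 1 ms
  brute-force grid and requires exact agreement.
- **t_max.**  The curve's support ends by default at the largest observed
  leave time in scope; a smaller cap can be configured to suppress tail
  noise, but the default keeps the full support because capping pins t\*
  to the cap whenever the rate is still rising there.
- **Averaging beyond a cluster's end (`hold` vs `truncate`).**  Under the
  default `hold` policy a cluster contributes its final count at every
  t beyond its own leave time, so all clusters are weighted equally at
  every time point and g is non-decreasing with g(0) = 1.  The
  alternative `truncate` policy averages only clusters still active at t;
  it conditions on survival (long-lived clusters are the big ones), can
  decrease, and is provided as a sensitivity option.
- **Intrusion/perseveration timing (`fold` vs `drop`).**  Items missing
  from the dictionary (intrusions) and within-list repeats
  (perseverations) are excluded from the switch chain — a non-animal
  should not define a semantic patch.  Their response time is, by
  default, folded into the next valid response so elapsed time is
  conserved (the `drop` alternative discards it).  Which convention the
  original analyses of such data used is generally unreported; both are
  implemented and the conservation property is tested.
- **Degenerate inputs.**  Empty cluster collections, zero-variance
  correlation inputs, non-positive switch times, rank-deficient designs,
  and permutation pools smaller than two all raise errors naming the
  problem; a participant with no defined switch time (every cluster the
  first of its list) cannot be analyzed and is flagged out of the
  per-participant tables.

## Exclusion rules

A list is invalid if any response time is missing or it contains fewer
than five valid animals (an earnestness floor, counted over
non-intrusion, non-perseveration responses — perseverations do not count
toward the five).  A participant is removed when their lists contain
three or more intrusions in total, or when fewer than three valid lists
remain.  Every decision is recorded with exactly one primary reason
(`missing_rt`, `too_few_animals`, `intrusion_quota`,
`incomplete_participant`); exclusion is idempotent and conserves counts.

## Permutation nulls

The null hypothesis is that closeness of L̂ to t\* reflects the marginal
distribution of response times rather than the placement of switches.
Inter-item rts are permuted while the item sequence and switch flags stay
fixed; L̂, g, t\*, and the deviance are recomputed per permutation.
Choices:

- Trial-start latencies are excluded from the permutable pool by default
  (they are neither switch nor within-cluster transitions); a flag
  includes them.
- Group scope shuffles across the whole dataset; participant scope
  shuffles within each participant (used by the per-participant test,
  whose summary is the exact one-sided binomial tail P(X ≥ k | n, ½) on
  the count of participants beating their own null mean).
- Randomness: one integer seed; per-participant substreams are spawned
  deterministically, so results are bit-reproducible.

## Statistics

Pearson correlations are reported with r, t = r·√(df/(1−r²)), df = n−2,
and two-sided p.  The correlation Bayes factor uses the default
(stretched symmetric beta) prior on ρ with width κ (κ = 1 → uniform on
(−1,1)), integrating the exact sampling density of r by adaptive
quadrature; BF10 < 1 favors the null.  The prior family/width used in any
particular published analysis is rarely stated, so κ is exposed and the
BF should be read as a default-prior quantity.  OLS regression (classical
SEs) supports a product interaction and a natural-log transform of
time-valued predictors.  Adherence to optimality is operationalized as
**relative** deviance |t\*−L̂|/L̂: absolute deviance in ms scales with a
participant's overall tempo, so under uniform slowing pure sampling noise
would acquire a mechanical positive age correlation, which the
scale-free measure removes.

## The synthetic generator

Each simulated participant alternates patch visits within a 3-minute
trial (three trials per participant): a switch latency (lognormal, mean
μ_s), then within-patch transitions with means μ_w·γ^(j−1) for the j-th
transition — geometric slowdown is the generator's form of diminishing
returns.  Items are drawn without replacement from one category of a
synthetic 30 × 12 lexicon per patch, so patch boundaries are genuine
category switches.  The trial ends when the next response would cross the
time limit.

Defaults (chosen once, before the test suite was written): μ_w = 3000 ms,
γ = 1.35, μ_s = 6000 ms, lognormal noise with coefficient of variation
0.3.  Under these the MVT solution is to take 3 items per patch
(residence 7050 ms, global rate ≈ 2.3×10⁻⁴ items/ms), giving cohorts
with mean switch times ≈ 6 s and mean leave times ≈ 6.8–7 s, in the range
reported for human animal-fluency cohorts; mean list length comes out
≈ 40 responses per 3-minute trial, somewhat above typical human lists —
matching the timing quantities was prioritized over list length.

`solve_optimal_threshold` computes the MVT solution by fixed-point
iteration on the global rate R (leave after the item count at which the
marginal item rate 1/(μ_w·γ^(k−1)) falls below R), guarded against limit
cycles by checking adjacent counts; a brute-force policy search over
k = 1…20 is the test oracle.  Indexing note: μ_w is the mean of the
*first* within-patch transition, so in the γ → ∞ limit the optimal agent
takes two items (the first transition is still cheap) and R\* =
2/(μ_s + μ_w).

Leave policies: `mvt_optimal` (the count above), `fixed_k` (late/early
leavers for sign checks), `threshold_scale` (leave when the marginal rate
falls below c·R\*).  Age models:

- `global_slowing` — all latency means scale by 1 + slope·(age−25)/44
  (default slope 0.5: a 69-year-old is 50% slower).  MVT predictions are
  scale invariant, so adherence should not vary with age.
- `switch_delay` — an executive-style deficit in *disengaging* from a
  patch: the leave threshold is discounted by 1/(1 + slope·age_norm), so
  older agents overstay (observed leave times exceed their optimum
  increasingly), while switch latencies themselves are untouched.  This
  operationalizes "failure to disengage" directly; note that inflating
  switch latencies instead would *raise* the optimum and make empirical
  minus optimal leave time fall with age — the opposite diagnostic sign.

What the generator does **not** emulate: real rt dispersion and
heavy tails (cv 0.3 is moderate; human inter-response times are more
variable), the high singleton-cluster rates of human data (~half of
human clusters are singletons; simulated patches have a fixed optimal
count), item frequency/typicality structure, retest effects across the
three trials, and any semantic-network topology.  Passing recovery tests
therefore shows the pipeline is correct for patchy, diminishing-returns
data — not that human data satisfies the generator's assumptions.

## Known limitations

- **Estimator vs. policy family.**  t\* is the optimal *time-threshold*
  policy for the averaged curve.  For agents who leave after a fixed item
  *count*, the averaged curve keeps rising until the upper tail of the
  last item's arrival-time distribution, so t\* sits above the mean leave
  time by an amount driven by latency dispersion (≈ 10–14% of L̂ at the
  default cv, shrinking as dispersion → 0; a test verifies the shrinkage).
  Trial-end censoring additionally pulls L̂ down slightly.  Group
  relative deviance for simulated MVT-optimal count-policy agents
  therefore plateaus near 0.1 rather than at 0; near-zero deviance in
  human data is an empirical alignment, not an estimator identity.
- **Fixed task window.**  Under global slowing, slower (older) agents
  produce fewer clusters in the fixed 3 minutes, so their per-participant
  deviance estimates are noisier; cohort-level age correlations of the
  adherence measure are only approximately zero (|r| ≈ 0.03–0.12 across
  generator seeds at n = 300).
- The environment is stationary within task: no patch-supply depletion,
  no drift in switch costs, and cluster demarcation is purely taxonomic
  (no embedding-based or hand-coded alternatives).
- The per-participant test inherits Monte-Carlo error from its
  permutation count; the binomial summary treats participants as
  exchangeable and independent.
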