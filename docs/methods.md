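# Methods

## Model

The simulator implements a stochastic evolutionary model of collective
problem solving.  A population of `N` players is partitioned into
`n = N/S` groups of equal size `S`.  Each player carries an immutable
collaboration probability `p_i`, drawn uniformly on `[0, 1]` at birth,
and an accumulated fitness `π_i`; each group carries an integer capacity
`Σ_j`.  The two state variables model two scales of knowledge: `π_i` is
what a player has learned individually, `Σ_j` what the group has built
collectively.

Per iteration, within every group independently: each player is a
*collectivist* with probability `p_i`, else an *individualist*; each
individualist draws a fresh integer gain `G ~ U{G_min, …, G_max}`;
collectivists solve with probability `R`, individualists with
probability `R^G` (a `G`-times harder task is modelled as `G`
independent sub-tasks of simplicity `R`, so a larger desired gain means
a smaller chance of winning it).  Roles and gains are redrawn every
iteration; `p_i` itself never changes during a player's lifetime —
adaptation happens only through selection.

### Scoring

If `s ≥ 1` collectivists in a group solved, the group capacity is
updated first, `Σ → Σ + 1`, and then **each solving collectivist
contributes the updated capacity `Σ` to every member of the group**, so
every member (collectivist or individualist, successful or not) receives
`s · Σ` that iteration.  A solving individualist additionally keeps its
drawn `G` privately.  If no collectivist solved, no shared gain is paid
(the group's knowledge did not advance), but private gains still are.

Two properties of this rule matter:

* **Superlinear accumulation.**  Because the per-solve payment is the
  capacity itself, shared payoffs compound: under certainty
  (`S = 1, p = 1, R = 1`) fitness after `T` iterations is exactly
  `T(T+1)/2`.  This models the incremental nature of knowledge — each
  advance is worth more the more has already been built.
* **Scale of the contribution.**  The natural alternative normalisation
  — each solver contributing `Σ/S` instead of `Σ` — makes the expected
  per-member receipt `p̄·R·Σ`, independent of group size, so evolved
  fitness simply tracks `p̄` and decreases monotonically with `S`,
  leaving no interior optimum.  With the adopted rule the receipt is
  `p̄·S·R·Σ`: it grows with the number of solvers but is eroded by the
  free-riding that large groups tolerate (`p̄` falls with `S`), and the
  product peaks at the balanced size `S = N/2`.  The interior optimum is
  the model's central prediction, and it is specific to this choice; the
  mean-field thresholds below inherit the same normalisation.

### Rounds, selection, games

A round is `iterations_per_round` iterations.  Between rounds (i.e. at
the start of every round after the first) selection runs as one atomic
step: compute the global mean fitness `π̄` over all `N` players; form
the pool of players with fitness **strictly below** `π̄`; remove
`k = min(⌊replacement_fraction · N⌋, pool size)` of them, sampled
uniformly without replacement; replace each in its group slot by a fresh
player with new uniform `p` and zero fitness; then reset **all** fitness
values and **all** capacities to zero.  Group sizes never change, and a
player at or above the mean is never removed.

The strict inequality makes the all-equal-fitness state (nothing ever
solved) a true neutral-drift regime: the pool is empty, nobody is
replaced, and the population's `p` distribution stays uniform — which is
exactly the observed behaviour at `R ≈ 10⁻⁴`, where the evolved mean
`p̄` stays within a few percent of 0.5 for every `S`.

A game is `rounds_per_game` rounds; its outputs are the final `p`
distribution, the final round's mean fitness, and the final round's
capacities (`Σ_max` — capacity resets each round, so this is the
capacity the evolved population builds within one round).

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `N` | population size | 100 | must be a multiple of `S` |
| `S` | group size | grid `{1,2,5,10,25,50,100}` | `n = N/S` groups |
| `R` | task simplicity | grid `{1e-4, 1e-3, 1e-2, 0.1, …, 1}` | fixed per simulation; `(0, 1]` |
| `G_min, G_max` | individualist gain range | 1, 10 | uniform integers, inclusive |
| `iterations_per_round` | task attempts per round | 1000 | `Σ` is bounded by this |
| `rounds_per_game` | selection steps per game | 2000 | |
| `games` | games averaged per cell | 20 | independent seeds |
| `replacement_fraction` | share of `N` replaced per round | 0.2 | capped by the below-mean pool |
| `seed` | root seed | — | all randomness derives from it |

Budget presets: `paper` (1000 × 2000 × 20) is the full protocol; `desk`
(200 × 200 × 5) is the scaled-down budget the tests, the examples and
the results script use.  At the desk budget every reported qualitative
and optimal-size result is stable across base seeds; one desk game takes
~0.15 s, the full optimal-size experiment ~20 s on one CPU.

## Randomness and reproducibility

All streams derive from the root seed through `numpy` `SeedSequence`
paths: game initialisation, each round's iteration block and each
round's selection step get independent children keyed by purpose and
round index, and grid cells derive per-game seeds keyed by
`(base_seed, S index, R index, game index)` — so extending a grid never
perturbs existing cells, and any game can be reproduced in isolation.

For speed, `run_round` draws its randomness in whole-round blocks of
shape `(T, n, S)` (role draws, gain draws, solve draws, in that order)
and scores the round with array cumulative sums; this is exact, not an
approximation, because within a round the role/solve process does not
depend on fitness or capacity.  With `T = 1` the block order coincides
with the single-iteration path bit-for-bit; at larger `T` the
equivalence of the two paths is certified statistically by the oracle
suite.

## Validation

Per-iteration expectations for a frozen group configuration have exact
closed forms: the capacity increments with probability
`1 − Π_i(1 − p_i R)`; every member's expected shared gain is
`(Σ+1) · R · Σ_i p_i`; player `i`'s expected private gain is
`(1 − p_i) · E[G R^G]`.  The oracle suite replays independent single
iterations through the real engine and z-tests the Monte-Carlo means
against these forms (threshold `|z| ≤ 3`, configurable), alongside the
role counts and the gain-draw distribution.  A deliberately corrupted
sharing rule (doubled contribution) is detected by the shared-gain
check in a few thousand samples.

## Mean-field analysis

Treating `Σ` as quasi-static and the collectivist density `α` as fixed,
a member of a group with `α·S` collectivists expects shared receipts
`α·S·R·Σ` per iteration; a defector in the same group expects
`α·(S−1)·R·Σ` from the others plus the private
`E(R) = E[G R^G] = mean_g(g R^g)`.  Within one group a defector's
receipts therefore always dominate a collectivist's, which is why a
single full-size group (`n = 1`) evolves towards individualism.
Cooperation pays only through between-group competition: an
all-cooperator group beats a defector-carrying group once its capacity
lead `δ = Σ_l − Σ_j` exceeds `E(R)/(S·R)` (large `S`, early-game
baseline `Σ_j ≈ 0`); for `S = 1` the threshold is the smallest integer
capacity with `R·Σ > E(R)` — at `R = 1`, the sixth solved task.  Both
thresholds grow monotonically with `R`, and both scale with the sharing
normalisation discussed above, so their absolute values are meaningful
only relative to this engine's scoring rule.

## What the simulator does and does not emulate

The model is the data-generating process — there is no external data.
It deliberately idealises: collaboration tendencies are innate and fixed
within a lifetime (no learning from outcomes); groups are isolated and
equally sized (no migration, no network structure); tasks are
memoryless Bernoulli trials with a single difficulty; gains are uniform
integers; selection is global and fitness-proportional only through a
hard below-mean threshold.  Passing tests therefore certify the internal
consistency of the engine and the reproducibility of the model's
emergent regimes — they say nothing about real crowdsourcing
populations, where tendencies adapt, group membership is fluid and task
difficulty is endogenous.

## Numerical choices and degenerate inputs

* `R = 0` is excluded from simulation parameters (the analytic
  `E[G R^G]` is still defined and zero there); the capacity-gap
  threshold is undefined at `R = 0` and raises.
* Optimal-size ties break toward the smaller `S`; trend profiles with
  fewer than three points are reported as `undefined`; a constant
  profile has trend sign 0.
* `iterations_per_round = 0` yields a valid empty round (zero fitness
  and capacities).
* Capacity is stored as `int64`, fitness as `float64` at full precision;
  desk-budget fitness values (~10⁵–10⁶) are far below any precision
  loss.
* Replacement draws fresh `p` at full floating precision; no
  quantisation anywhere.

## Known limitations

* **Capacity saturation.**  `Σ_max` is bounded by `iterations_per_round`
  and, for easy tasks (`R ≥ 0.8`) and groups with `S ≥ 25`, the
  probability that an iteration passes without a single collective solve
  is below ~10⁻⁵, so the final capacity sits exactly at the ceiling for
  all such sizes.  In that regime capacity cannot discriminate between
  large group sizes — only mean fitness can, and the optimal-size
  experiment therefore ranks sizes by fitness (checking that the winner
  also attains the maximal, possibly tied, capacity).
* The mean-field treatment is quasi-static in `Σ` and ignores
  fluctuations in `α`; it predicts thresholds and signs, not
  trajectories.  No self-consistent dynamics for `Σ(t)` is provided.
* The stochastic-`R` variant (redrawing task difficulty per task) is not
  implemented; `R` is a fixed per-simulation constant from a grid.
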