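# crowdsolve

An evolutionary agent-based simulator of collective problem solving in
fixed-size groups — how a crowd splits into collaborators and
free-riders, and what group size lets its members learn the most.

It is written for researchers in computational social science and
evolutionary game theory who want a reproducible, validated
implementation of this class of model: a stochastic engine, parameter
sweeps over group size and task difficulty, closed-form mean-field
analytics, and Monte-Carlo oracles that certify the engine.

## The model

A population of `N` players is divided into `n = N/S` groups of size
`S`.  Player `i` carries a fixed collaboration probability `p_i ~
U[0,1]`.  Each group faces tasks of simplicity `R ∈ (0, 1]` (`1 − R` is
the difficulty).  One **iteration**:

1. each player independently joins its group's *collectivists* with
   probability `p_i`, otherwise it plays alone as an *individualist*;
2. each individualist draws a desired gain `G_i ~ U{1, …, 10}`;
3. each collectivist solves the task with probability `R`; each
   individualist faces a `G_i`-times harder task and solves with
   probability `R^{G_i}`.

Each group keeps an integer **capacity** `Σ_j`, the number of iterations
in which at least one of its collectivists solved — accumulated
collective knowledge.  Scoring an iteration with `s ≥ 1` solving
collectivists: `Σ_j → Σ_j + 1`, then every member of the group (any
role, solved or not) gains `s · Σ_j` **fitness** — each solver
contributes the updated capacity to everyone, so collective payoffs grow
superlinearly as knowledge compounds.  A solving individualist keeps its
`G_i` privately; if no collectivist solved, shared gains are zero but
private gains still pay.

A **round** is 1000 iterations.  Between rounds, up to 20% of the
players — drawn from those with fitness strictly below the population
mean — are replaced by fresh players with new uniform `p`, and all
fitness and capacities reset.  A **game** is 2000 such rounds; its end
state is the evolved distribution of collaboration probabilities for one
`(S, R)` cell.  The study protocol averages 20 games per cell over the
grid `S ∈ {1, 2, 5, 10, 25, 50, 100}` × `R ∈ {0.0001, 0.001, 0.01, 0.1,
0.2, …, 1}`.

Key emergent results the simulator reproduces: near-impossible tasks
leave `p̄ ≈ 0.5` (neutral drift); small groups evolve strong
collaboration while the single full-size group breeds free-riders; and
the evolved fitness is maximised at the balanced size `S = N/2`.

## Worked example

`python examples/optimal_group_size.py` sweeps the divisor grid of
`N = 100` at `R = 0.9` with scaled-down budgets (200 iterations × 200
rounds × 5 games):

```
  S     mean_p  mean_fitness  capacity_max
  1      0.889     13843.738       159.882
  2      0.842     28992.052       183.056
  5      0.721     64492.206       197.340
 10      0.653    118118.032       199.800
 25      0.570    257926.094       200.000
 50      0.551    497420.816       200.000
100      0.167    300600.090       200.000

optimal group size by mean fitness: S = 50 (N = 100)
```

`mean_p` is the evolved mean collaboration probability: it falls with
group size, collapsing to 0.167 for the single 100-player group where
free-riding is safe.  `mean_fitness` (the average knowledge gained per
player in the final round) peaks at `S = 50` — half the population —
which also attains the maximal capacity; the full-size group, despite
having the most potential solvers, ends up with 40% less fitness.  Other
examples in `examples/` cover single games, trend summaries over `R`,
the analytic cooperation thresholds and the engine validation oracles.

The same functionality is available from a thin CLI:

```bash
crowdsolve simulate --N 100 --S 50 --R 0.9 --preset desk --seed 7 --out game.json
crowdsolve grid --preset desk --seed 1 --out surface.csv
crowdsolve meanfield --R-grid 0.1:1:0.1
crowdsolve validate
```

Every data file is written with a JSON manifest (resolved parameters,
derived seeds, version) that suffices to reproduce it bit-for-bit.

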