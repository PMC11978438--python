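# Methods

## Model

`culturesim` simulates a population of `N` budget-limited agents on a static
undirected social network accumulating cultural traits. The model couples
three mechanisms — innovation, payoff-biased social learning, and globally
aggregated recommendation ("algorithmic mediation") — and tracks how their
balance shapes population-level performance, diversity and complexity.

**Cultural space.** Traits live on `X` parallel branches with unbounded
complexity levels; level `l` requires some trait at level `l−1` on *any*
branch (the dependency is branch-agnostic, so mixed-branch repertoires are
legal). Each `(branch, level)` pair has one world-level integer payoff,
drawn lazily on first contact and memoized forever: all agents see the same
world, an unviable pair stays unviable, and trait identity is well defined
for the diversity count and the recommender's archive. The payoff chain is
`z = round_half_up(2 e²)`, `e ~ Exp(λ)`.

**Per-step cycle** (every agent once per step, fresh random order,
sequential state updates): death–birth with probability `q`; learning —
recommender with probability `r`, else social; innovation only if learning
did not succeed. Costs: `Cs` and `Cr` are charged only on successful
copying; `Ci` is charged on every innovation attempt made with sufficient
budget. An agent whose budget is below every applicable cost idles until
replaced. Social learning copies the teacher's actual next-level trait
(branch and payoff); only innovation adds to the archive, which persists
across deaths.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `N` | 100 | population size (nodes) |
| `B` | 1000 | effort budget per life (effort units) |
| `Ci, Cs, Cr` | 10, 5, 1 | innovation / social / recommendation cost; ordering `Cr < Cs < Ci` enforced |
| `X` | 100 | cultural branches |
| `r` | 0 | probability a learning event is mediated |
| `q` | `1/N` | per-step replacement probability (≈1 death per step) |
| `λ` | `2 ln 2` | exponential payoff rate |
| horizon | `20 N` | steps per realization |
| window | 200 | final steps averaged for stationary summaries |
| realizations | 200 | independent repeats (library default; see below) |

The exponential rate is the one free calibration of the payoff chain: it is
set so that `P(z = 0) = 1 − e^{−λ/2} = 1/2` exactly (half of all potential
traits worthless) while keeping payoffs near 50 rare
(`P(z ≥ 50) = e^{−λ√24.75} ≈ 1.0×10⁻³`). It is exposed as `payoff_rate`.

Network families: Erdős–Rényi with `p = k/(N−1)`; complete; Watts–Strogatz
with even base degree `k` and rewiring probability 0.1 (configurable);
Barabási–Albert with `m = round(k/2)`; user-supplied edge lists. Isolated
nodes are kept: an isolated agent simply always innovates, which is exactly
the `k → 0` limit the sparse sweeps probe.

## Design choices where the design was open

- **Update schedule.** Agents act in a fresh random permutation each step
  with sequential updates: a later agent sees earlier intra-step changes.
  This avoids synchronous-copy artefacts and matches the "on average one
  replacement per step" accounting. One consequence worth noting: in the
  very first step of an all-naive population, agents acting later may
  already copy from intra-step innovators; only the first actor (or agents
  without neighbours) is forced to innovate.
- **Newborns act.** A newborn proceeds with the learning/innovation phases
  of its birth step (death–birth is event one of the same cycle).
- **Tie-breaking.** Teacher selection and recommendation break payoff ties
  uniformly at random, under seed control.
- **Stationary summaries.** `T̄max` is summarized like the other measures as
  the window mean of `T(t)` (nearly flat in the stationary regime). Window
  means are computed per realization first, then averaged; the
  between-realization spread gives the reported standard errors.
- **Seeding.** One master seed per run spawns substreams (topology vs.
  payoffs/dynamics); sweep seeds derive from (master, grid index,
  realization index), so results are independent of execution order.

## Engines and numerics

Two implementations of identical rules ship:

- `dynamics.py`, a per-agent object engine whose operations mirror the
  conceptual cycle one-to-one and support exact audits (budget ledger,
  repertoire contiguity, archive monotonicity);
- `_kernel.py`, a numba-compiled array kernel used by default in
  `run_simulation`/`sweep`; it maintains the payoff table, the archive and
  per-level argmax structures in flat arrays with capacity doubling.

The two engines use different random streams, so they are compared
statistically (stationary summaries within Monte-Carlo error), while each
engine is bit-reproducible under a fixed seed. Budgets change only by the
three integer-valued costs, so the budget ledger
`B − budget = Cs·n_social + Cr·n_rec + Ci·n_attempts` holds exactly in
floating point. Rounding of payoffs is half-up (the boundary has
probability zero; the convention is fixed for reproducibility).

## What the generator emulates — and what it does not

Simulated data reproduce the structural features the model is about:
functional dependency of traits, rare high-payoff innovations, budget
limits, network-localized copying versus global recommendation. They do not
emulate real platforms: no co-evolving or biased recommender, no
algorithmic innovation, no recombination, no payoff-dependent costs, no
empirical calibration. Passing tests therefore demonstrate the model's
internal phenomena (logarithmic `Z̄max(N)` growth, diversity loss with
density, interior optima in `k` and `r`), not claims about any particular
real system.

## Problem sizes used by tests and the acceptance script

The library default of 200 realizations matches the reference study
conditions; tests and the acceptance script use smaller, stated sizes with
correspondingly labelled tolerances: 20 realizations per grid point for the
monotonicity/correlation properties (12 for the per-`k` mediation scan), 50
for locating the optimal mediation ratio, 500 single-agent runs for the
closed-form innovation limit, and 10⁶ draws for the payoff-distribution
check. The optimal ratio is reported as the vertex of a parabola fitted to
the five `r`-grid points around the empirical maximum — a lower-variance
estimator of the peak of a smooth noisy curve than the raw 0.1-grid argmax
(a fine-grid scan at 100 realizations puts the model's optimum at ≈ 0.73
for `k = 1`).

## Known limitations

- The intra-step schedule is sequential only; a synchronous variant is not
  implemented.
- The recommender is static, unbiased and omniscient by construction.
- Payoff distributions other than the exponential→square→double→round chain
  are not shipped (the chain is a single pluggable point of
  `cultural_space`).
- Sweeps run serially; the per-point seeding contract makes them trivially
  parallelizable externally, but no built-in multiprocessing is provided.
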