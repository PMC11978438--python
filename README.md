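# culturesim

An agent-based simulator of **cumulative cultural evolution** for populations
that learn both from their social network and from a global recommender
("algorithmic mediation"). It is aimed at researchers in cultural evolution
and computational social science who want to study how network density and
algorithmically mediated information exchange jointly shape a population's
ability to accumulate complex, high-utility culture.

## The model

A population of `N` agents occupies the nodes of a static undirected network
(Erdős–Rényi with mean degree `k = p(N−1)`, complete, Watts–Strogatz,
Barabási–Albert, or user-supplied). Culture is an open-ended space of traits
indexed by a branch `x ∈ {1..X}` (parallel development paths) and an
unbounded complexity level `l ≥ 1`; acquiring a level-`l` trait requires
owning some trait at level `l−1`. Each `(x, l)` pair carries a fixed integer
payoff drawn once on first contact as `z = round(2·e²)` with
`e ~ Exp(λ)`, `λ = 2 ln 2` — so half of all potential traits are worthless
(`z = 0`, unviable) and payoffs near `z = 50` are rare (~10⁻³).

Each agent has a finite effort budget `B`. Per time step every agent, in
random order, runs a three-event cycle:

1. **Death–birth** — with probability `q = 1/N` the agent is replaced by a
   naive newborn (empty repertoire, fresh budget) at the same node.
2. **Learning** — with probability `r` the *recommender*, which knows every
   trait innovated so far, offers the highest-payoff trait at the agent's
   next level (cost `Cr` on success); otherwise the agent learns *socially*,
   copying the next-level trait of the neighbour with the highest cumulative
   payoff `Z_j` (cost `Cs` on success). Failures cost nothing.
3. **Innovation** — only if learning failed: pay `Ci`, probe a uniformly
   random branch at the next level, and keep the trait iff it is viable.

Default costs are `Cr = 1 < Cs = 5 < Ci = 10` and `B = 1000`. The measures
tracked are performance `Z̄(t)` (mean cumulative payoff), complexity `L̄(t)`
(mean repertoire level) and diversity `T(t)` (distinct traits ever
innovated); the finite budget drives the system into a quasi-stationary
state, summarized by window means `Z̄max`, `L̄max`, `T̄max` averaged over
independent realizations.

The simulator reproduces the characteristic phenomena of this model class:
logarithmic growth of `Z̄max` with `N` on complete graphs, a monotone decline
of diversity with connectivity, an interior optimum of `Z̄max` in `k`, and —
with mediation — mutual benefit of the two learning channels: `Z̄max` peaks
at intermediate `r` (near `r ≈ 0.7` for `k = 1`), while pure social learning
(`r = 0`) and pure mediation (`r = 1`) both underperform.

## Worked example

Sweep the mediation ratio on a very sparse random network
(`examples/sweep_k_r.yaml` holds `N=100`, `k=1`, `r ∈ {0, 0.35, 0.7, 1}`):

```bash
culturesim sweep --config examples/sweep_k_r.yaml --realizations 20 --out sweep.csv
```

The summary table (selected columns; 20 realizations per point, seed 42):

```
   r   Z_max  L_max   T_max  se_Z
0.00  218.36  50.80 6323.33  3.96
0.35 1464.99  66.57 7741.29 31.06
0.70 2091.98  84.25 8499.79 42.17
1.00  385.78  96.26  573.91  7.70
```

Reading it: with only social learning (`r = 0`) the sparse network barely
spreads what is innovated — performance `Z̄max ≈ 218` stays low although
diversity is high. Pure mediation (`r = 1`) reaches the deepest repertoires
(`L̄max ≈ 96`) but collapses diversity to ~574 distinct traits and with it
performance. Mixing the channels at `r = 0.7` is an order of magnitude
better (`Z̄max ≈ 2092`) than either extreme: the recommender spreads the best
findings globally while the sparse network keeps innovation pressure high.

The same can be done from Python:

```python
from culturesim import SimConfig, grid_from_base, sweep

base = SimConfig(network_family="erdos_renyi", mean_degree=1.0)
table = sweep(grid_from_base(base, r=[0.0, 0.35, 0.7, 1.0]),
              realizations=20, seed=42)
```

`culturesim run` writes the per-step time series of a single realization,
and `culturesim show-config` echoes the fully resolved defaults.

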