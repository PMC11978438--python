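"""Per-time-step agent dynamics.

Each agent's cycle in a time step has three events, in order:

(i)   *death-birth*: with probability ``q = 1/N`` the agent is replaced by a
      naive newborn (empty repertoire, full budget B) at the same network
      position; the newborn proceeds with the rest of the cycle.
(ii)  *learning*: with probability ``r`` the agent asks the recommender
      (algorithmic mediation) for the best archived trait at its next level,
      paying ``Cr`` on success; otherwise it learns socially, copying the
      next-level trait of its best neighbour and paying ``Cs`` on success.
      Failed learning (no suitable teacher/trait, or insufficient budget)
      costs nothing.
(iii) *innovation*: only if learning did not succeed.  If the budget covers
      ``Ci`` the cost is charged regardless of outcome: a uniformly random
      branch is probed at the agent's next level and the trait is acquired
      iff it is viable (payoff > 0).  Successful innovations enter the
      global archive, which is what the recommender reads and what the
      trait-diversity measure counts.

Within a time step agents act once each, in a fresh random order, with
sequential state updates.  This module is the readable reference engine;
:mod:`culturesim._kernel` implements the same rules as a compiled array
kernel for large sweeps.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .cultural_space import DEFAULT_RATE, PayoffTable, Trait, is_viable
from .networks import SocialNetwork

__all__ = [
    "Agent", "Archive", "SimConfig", "Outcome", "StepRecord",
    "death_birth", "select_neighbour", "social_learn", "recommend",
    "algorithmic_learn", "innovate", "agent_step", "time_step",
    "STRATEGIES",
]

STRATEGIES = ("payoff_biased", "level_biased", "random_neighbour")


class Outcome(enum.Enum):
    """Result of a learning or innovation attempt (failures are outcomes,
    not errors)."""

    SUCCESS = "success"
    FAIL_LEVEL = "fail_level"        # teacher's repertoire too shallow
    FAIL_NO_TEACHER = "fail_no_teacher"  # isolated node: nobody to copy from
    FAIL_BUDGET = "fail_budget"
    FAIL_EMPTY = "fail_empty"        # archive has nothing at the next level
    FAIL_UNVIABLE = "fail_unviable"  # innovation probed a zero-payoff trait
    NOT_ATTEMPTED = "not_attempted"


class Agent:
    """A network node with an effort budget and a contiguous repertoire.

    The repertoire holds exactly one trait per level 1..max_level (traits
    must be acquired in ascending level order), all of them viable.  The
    action counters support exact budget-ledger audits:
    ``B - budget == Cs*n_social + Cr*n_recommend + Ci*n_innovation_attempts``
    for every agent since its birth.
    """

    __slots__ = ("node_id", "budget", "repertoire", "cumulative_payoff",
                 "n_social", "n_recommend", "n_innovation_attempts")

    def __init__(self, node_id: int, budget: float) -> None:
        self.node_id = node_id
        self.budget = budget
        self.repertoire: list[Trait] = []
        self.cumulative_payoff = 0
        self.n_social = 0
        self.n_recommend = 0
        self.n_innovation_attempts = 0

    @property
    def max_level(self) -> int:
        return len(self.repertoire)

    def trait_at(self, level: int) -> Trait:
        return self.repertoire[level - 1]

    def acquire(self, trait: Trait) -> None:
        if trait.level != self.max_level + 1:
            raise ValueError(
                f"agent at level {self.max_level} cannot acquire a "
                f"level-{trait.level} trait")
        if not is_viable(trait.payoff):
            raise ValueError("only viable traits can be acquired")
        self.repertoire.append(trait)
        self.cumulative_payoff += trait.payoff

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Agent(node={self.node_id}, l={self.max_level}, "
                f"Z={self.cumulative_payoff}, B={self.budget})")


class Archive:
    """Monotone global store of every viable trait innovated so far.

    This is both the recommender's knowledge base and the trait-diversity
    counter: ``total_count`` is the number of distinct (branch, level) pairs
    ever innovated.  Knowledge survives its innovator's death; traits are
    never removed.
    """

    def __init__(self) -> None:
        self.traits_by_level: dict[int, dict[int, Trait]] = {}
        self.total_count = 0
        # per level: (best payoff, list of best traits) for O(1) recommend
        self._best: dict[int, tuple[int, list[Trait]]] = {}

    def add(self, trait: Trait) -> bool:
        """Archive a trait; returns True iff its (branch, level) is new."""
        if not is_viable(trait.payoff):
            raise ValueError("only viable traits can be archived")
        level_map = self.traits_by_level.setdefault(trait.level, {})
        if trait.branch in level_map:
            return False
        level_map[trait.branch] = trait
        self.total_count += 1
        best = self._best.get(trait.level)
        if best is None or trait.payoff > best[0]:
            self._best[trait.level] = (trait.payoff, [trait])
        elif trait.payoff == best[0]:
            best[1].append(trait)
        return True

    def best_at(self, level: int) -> list[Trait]:
        """All maximum-payoff traits at ``level`` (empty if none)."""
        best = self._best.get(level)
        return list(best[1]) if best else []


@dataclass
class SimConfig:
    """Full configuration of one simulation run.

    Defaults follow the reference parameter set: N=100 agents on a random
    network, budget B=1000, costs Ci=10 > Cs=5 > Cr=1, X=100 branches,
    horizon 20N steps with the last 200 used for stationary summaries.
    """

    N: int = 100
    B: float = 1000.0
    Ci: float = 10.0
    Cs: float = 5.0
    Cr: float = 1.0
    X: int = 100
    r: float = 0.0
    q: Optional[float] = None            # None -> 1/N
    strategy: str = "payoff_biased"
    network_family: str = "erdos_renyi"
    mean_degree: float = 1.0
    rewiring_prob: float = 0.1
    edge_list_path: Optional[str] = None
    horizon: Optional[int] = None        # None -> 20 N
    stationary_window: int = 200
    realizations: int = 200
    payoff_rate: float = DEFAULT_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        # remember which fields were left to auto-derive, so that
        # with_updates() re-derives them for a changed N
        self._auto = {"q": self.q is None, "horizon": self.horizon is None}
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.B <= 0:
            raise ValueError("B must be positive")
        if not (0.0 < self.Cr < self.Cs < self.Ci):
            raise ValueError("costs must satisfy 0 < Cr < Cs < Ci")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must be in [0, 1]")
        if self.q is None:
            self.q = 1.0 / self.N
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must be in [0, 1]")
        if self.X < 1:
            raise ValueError("X must be >= 1")
        if self.horizon is None:
            self.horizon = 20 * self.N
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; "
                             f"choose from {STRATEGIES}")

    def with_updates(self, **kwargs) -> "SimConfig":
        """A copy with fields replaced; auto-derived q and horizon are
        re-derived from the (possibly new) N unless given explicitly."""
        from dataclasses import fields as _fields

        init = {f.name: getattr(self, f.name) for f in _fields(self)}
        for name, auto in self._auto.items():
            if auto:
                init[name] = None
        init.update(kwargs)
        return SimConfig(**init)


@dataclass
class StepRecord:
    """What happened to one agent during one time step (for audits)."""

    replaced: bool = False
    learning_mode: str = "none"          # "social" | "algorithmic" | "none"
    learning_outcome: Outcome = Outcome.NOT_ATTEMPTED
    innovation_outcome: Outcome = Outcome.NOT_ATTEMPTED


# ----------------------------------------------------------------------
# the three events of the cycle
# ----------------------------------------------------------------------

def death_birth(agent: Agent, q: float, budget: float,
                rng: np.random.Generator) -> tuple[Agent, bool]:
    """Replace ``agent`` by a naive newborn with probability ``q``.

    The newborn keeps the network position; returns ``(agent, replaced)``.
    """
    if q > 0.0 and rng.random() < q:
        return Agent(agent.node_id, budget), True
    return agent, False


def select_neighbour(strategy: str, focal: Agent,
                     neighbour_agents: Sequence[Agent],
                     rng: np.random.Generator) -> Optional[Agent]:
    """Pick a teacher among the focal agent's neighbours.

    ``payoff_biased`` takes the highest cumulative payoff, ``level_biased``
    the highest repertoire level, ``random_neighbour`` a uniform draw; ties
    are broken uniformly at random.  Returns None for an isolated agent.
    """
    if not neighbour_agents:
        return None
    if strategy == "random_neighbour":
        return neighbour_agents[rng.integers(len(neighbour_agents))]
    if strategy == "payoff_biased":
        scores = [a.cumulative_payoff for a in neighbour_agents]
    elif strategy == "level_biased":
        scores = [a.max_level for a in neighbour_agents]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    best = max(scores)
    ties = [a for a, s in zip(neighbour_agents, scores) if s == best]
    return ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]


def social_learn(focal: Agent, teacher: Agent, Cs: float) -> Outcome:
    """Copy the teacher's trait at the focal agent's next level.

    Succeeds iff the teacher is at a strictly higher level and the focal
    budget covers ``Cs``; only success is charged.
    """
    target_level = focal.max_level + 1
    if teacher.max_level < target_level:
        return Outcome.FAIL_LEVEL
    if focal.budget < Cs:
        return Outcome.FAIL_BUDGET
    focal.acquire(teacher.trait_at(target_level))
    focal.budget -= Cs
    focal.n_social += 1
    return Outcome.SUCCESS


def recommend(archive: Archive, level: int,
              rng: Optional[np.random.Generator] = None) -> Optional[Trait]:
    """The recommender: highest-payoff archived trait at exactly ``level``.

    Personalization means only traits at the learner's next level are
    eligible.  Ties are broken uniformly at random; None if the archive
    holds nothing at that level.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    best = archive.best_at(level)
    if not best:
        return None
    if len(best) == 1 or rng is None:
        return best[0]
    return best[rng.integers(len(best))]


def algorithmic_learn(focal: Agent, archive: Archive, Cr: float,
                      rng: Optional[np.random.Generator] = None) -> Outcome:
    """Acquire the recommended next-level trait, paying ``Cr`` on success."""
    trait = recommend(archive, focal.max_level + 1, rng)
    if trait is None:
        return Outcome.FAIL_EMPTY
    if focal.budget < Cr:
        return Outcome.FAIL_BUDGET
    focal.acquire(trait)
    focal.budget -= Cr
    focal.n_recommend += 1
    return Outcome.SUCCESS


def innovate(focal: Agent, table: PayoffTable, archive: Archive, Ci: float,
             X: int, rng: np.random.Generator) -> Outcome:
    """Attempt to innovate a next-level trait on a random branch.

    With sufficient budget the cost ``Ci`` is charged regardless of outcome;
    the trait is acquired (and archived) only if it is viable.
    """
    if focal.budget < Ci:
        return Outcome.FAIL_BUDGET
    focal.budget -= Ci
    focal.n_innovation_attempts += 1
    branch = int(rng.integers(1, X + 1))
    trait = table.trait(branch, focal.max_level + 1)
    if not is_viable(trait.payoff):
        return Outcome.FAIL_UNVIABLE
    focal.acquire(trait)
    archive.add(trait)
    return Outcome.SUCCESS


# ----------------------------------------------------------------------
# schedule
# ----------------------------------------------------------------------

def agent_step(focal: Agent, net: SocialNetwork, agents: list[Agent],
               archive: Archive, table: PayoffTable, config: SimConfig,
               rng: np.random.Generator) -> tuple[Agent, StepRecord]:
    """Run one full cycle (death-birth, learning, innovation) for one agent.

    Mutates ``agents`` in place if the focal agent dies; returns the (possibly
    new) agent together with a :class:`StepRecord` of what happened.
    """
    rec = StepRecord()
    focal, rec.replaced = death_birth(focal, config.q, config.B, rng)
    if rec.replaced:
        agents[focal.node_id] = focal

    if config.r > 0.0 and rng.random() < config.r:
        rec.learning_mode = "algorithmic"
        rec.learning_outcome = algorithmic_learn(focal, archive, config.Cr,
                                                 rng)
    else:
        rec.learning_mode = "social"
        nbr = [agents[j] for j in net.neighbours(focal.node_id)]
        teacher = select_neighbour(config.strategy, focal, nbr, rng)
        if teacher is None:
            rec.learning_outcome = Outcome.FAIL_NO_TEACHER
        else:
            rec.learning_outcome = social_learn(focal, teacher, config.Cs)

    if rec.learning_outcome is not Outcome.SUCCESS:
        rec.innovation_outcome = innovate(focal, table, archive, config.Ci,
                                          config.X, rng)
    return focal, rec


def time_step(population: list[Agent], net: SocialNetwork, archive: Archive,
              table: PayoffTable, config: SimConfig,
              rng: np.random.Generator,
              records: Optional[list[StepRecord]] = None) -> list[Agent]:
    """Run one time step: every agent acts once, in fresh random order.

    Updates are sequential — an agent acting later in the step sees all
    earlier intra-step changes.  Mutates and returns ``population``.
    """
    for i in rng.permutation(len(population)):
        _, rec = agent_step(population[i], net, population, archive, table,
                            config, rng)
        if records is not None:
            records.append(rec)
    return population


def init_population(config: SimConfig) -> list[Agent]:
    """An all-naive population: empty repertoires, full budgets."""
    return [Agent(i, config.B) for i in range(config.N)]
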