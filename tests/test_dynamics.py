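"""The per-agent cycle: death-birth, learning, recommendation, innovation."""

import numpy as np
import pytest

from culturesim import (Agent, Archive, Outcome, PayoffTable, SimConfig,
                        Trait, agent_step, algorithmic_learn, build_network,
                        death_birth, init_population, innovate, recommend,
                        select_neighbour, social_learn, time_step)


def make_agent(node_id=0, budget=1000.0, payoffs=()):
    """An agent holding viable traits with the given payoffs on levels 1.."""
    a = Agent(node_id, budget)
    for lvl, z in enumerate(payoffs, start=1):
        a.acquire(Trait(branch=1, level=lvl, payoff=z))
    return a


def preset_table(entries, branch_count=10):
    """A payoff table with chosen (branch, level) -> payoff entries."""
    t = PayoffTable(branch_count, seed=0)
    t._materialized.update(entries)
    return t


class TestDeathBirth:
    def test_q_zero_never_replaces(self, rng):
        a = make_agent(payoffs=[5, 7])
        for _ in range(100):
            out, replaced = death_birth(a, 0.0, 1000.0, rng)
            assert out is a and not replaced

    def test_q_one_always_replaces_with_naive(self, rng):
        a = make_agent(node_id=3, budget=17.0, payoffs=[5])
        out, replaced = death_birth(a, 1.0, 1000.0, rng)
        assert replaced
        assert out.node_id == 3          # newborn inherits the position
        assert out.max_level == 0 and out.cumulative_payoff == 0
        assert out.budget == 1000.0

    def test_replacement_probability(self, rng):
        a = make_agent()
        hits = sum(death_birth(a, 0.3, 1000.0, rng)[1] for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(0.3, abs=0.02)


class TestSelectNeighbour:
    def test_empty_set_returns_none(self, rng):
        assert select_neighbour("payoff_biased", make_agent(), [], rng) is None

    @pytest.mark.parametrize("strategy",
                             ["payoff_biased", "level_biased",
                              "random_neighbour"])
    def test_single_neighbour_chosen(self, strategy, rng):
        nb = make_agent(node_id=1, payoffs=[4])
        assert select_neighbour(strategy, make_agent(), [nb], rng) is nb

    def test_payoff_bias_breaks_ties_uniformly(self, rng):
        a, b, c = (make_agent(node_id=i, payoffs=p)
                   for i, p in enumerate([[10], [30], [30]]))
        picks = [select_neighbour("payoff_biased", make_agent(9), [a, b, c],
                                  rng) for _ in range(10_000)]
        assert a not in picks
        assert picks.count(b) / 10_000 == pytest.approx(0.5, abs=0.05)

    def test_level_bias_prefers_deepest_repertoire(self, rng):
        shallow = make_agent(node_id=1, payoffs=[100])
        deep = make_agent(node_id=2, payoffs=[1, 1, 1])
        assert select_neighbour("level_biased", make_agent(),
                                [shallow, deep], rng) is deep

    def test_random_strategy_is_uniform(self, rng):
        nbs = [make_agent(node_id=i, payoffs=[i + 1]) for i in range(4)]
        picks = [select_neighbour("random_neighbour", make_agent(9), nbs, rng)
                 for _ in range(8000)]
        for nb in nbs:
            assert picks.count(nb) / 8000 == pytest.approx(0.25, abs=0.03)

    def test_unknown_strategy_rejected(self, rng):
        with pytest.raises(ValueError):
            select_neighbour("conformist", make_agent(), [make_agent(1)], rng)


class TestSocialLearn:
    def test_success_copies_next_level_trait(self):
        focal = make_agent(budget=100.0, payoffs=[3, 4])
        teacher = make_agent(node_id=1, payoffs=[1, 1, 9, 2, 2])
        assert social_learn(focal, teacher, Cs=5.0) is Outcome.SUCCESS
        assert focal.budget == 95.0
        assert focal.max_level == 3
        assert focal.trait_at(3) == teacher.trait_at(3)
        assert focal.cumulative_payoff == 3 + 4 + 9

    def test_teacher_at_same_level_fails_without_cost(self):
        focal = make_agent(budget=100.0, payoffs=[3, 4])
        teacher = make_agent(node_id=1, payoffs=[9, 9])
        assert social_learn(focal, teacher, Cs=5.0) is Outcome.FAIL_LEVEL
        assert focal.budget == 100.0 and focal.max_level == 2

    def test_insufficient_budget_fails_without_cost(self):
        focal = make_agent(budget=3.0, payoffs=[3, 4])
        teacher = make_agent(node_id=1, payoffs=[1] * 5)
        assert social_learn(focal, teacher, Cs=5.0) is Outcome.FAIL_BUDGET
        assert focal.budget == 3.0 and focal.max_level == 2


class TestRecommend:
    def test_picks_highest_payoff_at_level(self, rng):
        archive = Archive()
        for b, z in enumerate([4, 17, 9], start=1):
            archive.add(Trait(b, 3, z))
        assert recommend(archive, 3, rng).payoff == 17

    def test_empty_level_returns_none(self, rng):
        archive = Archive()
        archive.add(Trait(1, 1, 5))
        assert recommend(archive, 2, rng) is None
        with pytest.raises(ValueError):
            recommend(archive, 0, rng)

    def test_matches_brute_force_oracle(self, rng):
        """Incrementally maintained per-level best equals a linear scan."""
        for _ in range(1000):
            archive = Archive()
            n = int(rng.integers(1, 30))
            for _ in range(n):
                archive.add(Trait(int(rng.integers(1, 8)),
                                  int(rng.integers(1, 5)),
                                  int(rng.integers(1, 30))))
            level = int(rng.integers(1, 5))
            got = recommend(archive, level, rng)
            pool = list(archive.traits_by_level.get(level, {}).values())
            if not pool:
                assert got is None
            else:
                assert got.payoff == max(t.payoff for t in pool)


class TestAlgorithmicLearn:
    def test_naive_agent_gets_best_level_one_trait(self, rng):
        archive = Archive()
        archive.add(Trait(1, 1, 2))
        archive.add(Trait(2, 1, 8))
        focal = make_agent(budget=10.0)
        assert algorithmic_learn(focal, archive, Cr=1.0, rng=rng) is \
            Outcome.SUCCESS
        assert focal.budget == 9.0
        assert focal.trait_at(1) == Trait(2, 1, 8)

    def test_empty_archive_fails_without_cost(self, rng):
        focal = make_agent(budget=10.0)
        assert algorithmic_learn(focal, Archive(), Cr=1.0, rng=rng) is \
            Outcome.FAIL_EMPTY
        assert focal.budget == 10.0

    def test_insufficient_budget_fails_without_cost(self, rng):
        archive = Archive()
        archive.add(Trait(1, 1, 2))
        focal = make_agent(budget=0.5)
        assert algorithmic_learn(focal, archive, Cr=1.0, rng=rng) is \
            Outcome.FAIL_BUDGET
        assert focal.budget == 0.5


class TestInnovate:
    def test_insufficient_budget_no_attempt(self, rng):
        focal = make_agent(budget=8.0)
        table = preset_table({})
        assert innovate(focal, table, Archive(), Ci=10.0, X=10, rng=rng) is \
            Outcome.FAIL_BUDGET
        assert focal.budget == 8.0 and focal.n_innovation_attempts == 0

    def test_unviable_trait_costs_but_is_not_acquired(self, rng):
        focal = make_agent(budget=100.0)
        table = preset_table({(b, 1): 0 for b in range(1, 11)})
        archive = Archive()
        assert innovate(focal, table, archive, Ci=10.0, X=10, rng=rng) is \
            Outcome.FAIL_UNVIABLE
        assert focal.budget == 90.0
        assert focal.max_level == 0 and archive.total_count == 0

    def test_viable_trait_acquired_and_archived_once(self, rng):
        table = preset_table({(b, 1): 12 for b in range(1, 11)})
        archive = Archive()
        focal = make_agent(budget=100.0)
        assert innovate(focal, table, archive, Ci=10.0, X=10, rng=rng) is \
            Outcome.SUCCESS
        assert focal.budget == 90.0
        assert focal.trait_at(1).payoff == 12
        first_count = archive.total_count
        assert first_count == 1
        # a second innovator of the same (branch, level) adds nothing new
        other = make_agent(node_id=1, budget=100.0)
        while innovate(other, table, archive, Ci=10.0, X=10, rng=rng) is not \
                Outcome.SUCCESS:
            other = make_agent(node_id=1, budget=100.0)
        assert archive.total_count <= 10


class TestAgentStep:
    @staticmethod
    def run_lone_agent(r, steps, seed=0, q=0.0):
        """Isolated single agent stepping `steps` times; returns records."""
        cfg = SimConfig(N=1, q=q, r=r, X=100, seed=seed,
                        network_family="erdos_renyi", mean_degree=0.0,
                        horizon=steps)
        net = build_network("erdos_renyi", 1, 0.0, seed=seed)
        table = PayoffTable(cfg.X, seed=seed)
        rng = np.random.default_rng(seed)
        agents = init_population(cfg)
        archive = Archive()
        records = []
        for _ in range(steps):
            _, rec = agent_step(agents[0], net, agents, archive, table, cfg,
                                rng)
            records.append(rec)
        return agents, records

    def test_r_zero_never_dispatches_to_algorithm(self):
        _, records = self.run_lone_agent(r=0.0, steps=2000)
        assert all(rec.learning_mode == "social" for rec in records)

    def test_r_one_never_attempts_social_learning(self):
        _, records = self.run_lone_agent(r=1.0, steps=2000, q=1.0)
        assert all(rec.learning_mode == "algorithmic" for rec in records)

    def test_dispatch_fraction_matches_r(self):
        _, records = self.run_lone_agent(r=0.3, steps=10_000, q=1.0)
        frac = np.mean([rec.learning_mode == "algorithmic"
                        for rec in records])
        assert frac == pytest.approx(0.3, abs=0.01)

    def test_isolated_innovator_exhausts_budget(self):
        # a lone agent with no neighbours and no mediation innovates every
        # step until the budget drops below Ci, then idles
        agents, records = self.run_lone_agent(r=0.0, steps=150)
        agent = agents[0]
        assert agent.n_innovation_attempts == 100      # B / Ci
        assert agent.budget == 0.0
        assert all(rec.innovation_outcome is Outcome.FAIL_BUDGET
                   for rec in records[100:])


class TestTimeStep:
    def test_all_naive_first_step_forces_innovation(self):
        # without neighbours nobody can learn, so the whole naive
        # population must attempt innovation in step 1
        cfg = SimConfig(N=20, q=0.0, r=0.0, seed=4,
                        network_family="erdos_renyi", mean_degree=0.0)
        net = build_network("erdos_renyi", 20, 0.0, seed=4)
        table = PayoffTable(cfg.X, seed=4)
        rng = np.random.default_rng(4)
        pop = init_population(cfg)
        records = []
        time_step(pop, net, Archive(), table, cfg, rng, records=records)
        assert len(records) == 20
        assert all(r.learning_outcome is not Outcome.SUCCESS for r in records)
        assert all(r.innovation_outcome is not Outcome.NOT_ATTEMPTED
                   for r in records)

    def test_first_actor_in_naive_population_must_innovate(self):
        # updates are sequential: the first agent in the step order faces
        # only naive neighbours and has to innovate, while later agents may
        # already copy from earlier intra-step innovators
        cfg = SimConfig(N=20, q=0.0, r=0.0, seed=4,
                        network_family="complete")
        net = build_network("complete", 20)
        table = PayoffTable(cfg.X, seed=4)
        rng = np.random.default_rng(4)
        pop = init_population(cfg)
        records = []
        time_step(pop, net, Archive(), table, cfg, rng, records=records)
        assert records[0].learning_outcome in (Outcome.FAIL_LEVEL,
                                               Outcome.FAIL_NO_TEACHER)
        assert records[0].innovation_outcome is not Outcome.NOT_ATTEMPTED

    def test_every_agent_acts_once_per_step(self):
        cfg = SimConfig(N=10, q=0.0, r=0.0, seed=5,
                        network_family="complete")
        net = build_network("complete", 10)
        table = PayoffTable(cfg.X, seed=5)
        rng = np.random.default_rng(5)
        pop = init_population(cfg)
        archive = Archive()
        for _ in range(3):
            records = []
            time_step(pop, net, archive, table, cfg, rng, records=records)
            assert len(records) == 10


class TestSimConfig:
    def test_defaults_derive_from_population_size(self):
        cfg = SimConfig(N=250)
        assert cfg.q == pytest.approx(1 / 250)
        assert cfg.horizon == 5000

    def test_with_updates_rederives_auto_fields(self):
        cfg = SimConfig(N=100).with_updates(N=400)
        assert cfg.q == pytest.approx(1 / 400)
        assert cfg.horizon == 8000
        pinned = SimConfig(N=100, q=0.02, horizon=123).with_updates(N=400)
        assert pinned.q == 0.02 and pinned.horizon == 123

    @pytest.mark.parametrize("bad", [
        {"N": 0}, {"B": 0}, {"r": 1.5}, {"q": -0.1},
        {"Cs": 20.0},                      # violates Cs < Ci
        {"Cr": 7.0},                       # violates Cr < Cs
        {"strategy": "conformist"},
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)
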