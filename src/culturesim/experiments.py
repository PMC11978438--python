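"""Full simulation runs, stationary summaries and parameter sweeps.

Three population measures are tracked after every time step:

- performance, the mean cumulative payoff ``Zbar(t) = (1/N) sum_i Z_i(t)``;
- complexity, the mean repertoire level ``Lbar(t) = (1/N) sum_i l_i(t)``;
- diversity, ``T(t)``, the number of distinct traits innovated so far.

The finite budget and the slow death-birth turnover drive the system into a
quasi-stationary state; the "maximally achievable" summaries (``Z_max``,
``L_max``, ``T_max``) are means over the final stationary window of each
realization, averaged over independent realizations with between-realization
standard errors.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .cultural_space import PayoffTable
from .dynamics import SimConfig, Archive, init_population, time_step
from .networks import SocialNetwork, build_network

__all__ = ["MetricsSeries", "StationarySummary", "run_simulation",
           "stationary_summary", "sweep", "grid_from_base"]

log = logging.getLogger("culturesim")


@dataclass
class MetricsSeries:
    """Per-time-step population aggregates of one realization."""

    mean_payoff: np.ndarray     # Zbar(t)
    mean_level: np.ndarray      # Lbar(t)
    distinct_traits: np.ndarray  # T(t), non-decreasing

    def __len__(self) -> int:
        return len(self.mean_payoff)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": np.arange(1, len(self) + 1),
            "mean_payoff": self.mean_payoff,
            "mean_level": self.mean_level,
            "distinct_traits": self.distinct_traits,
        })


@dataclass
class StationarySummary:
    """Window means of the three measures, averaged over realizations."""

    Z_max: float
    L_max: float
    T_max: float
    se_Z: float
    se_L: float
    se_T: float
    realizations: int
    window: int


def _seed_for(master: int, *key: int) -> int:
    """A reproducible sub-seed below 2**31 for (master, *key)."""
    ss = np.random.SeedSequence([int(master), *map(int, key)])
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))


def _build_net(config: SimConfig) -> SocialNetwork:
    return build_network(
        config.network_family, config.N, config.mean_degree,
        seed=_seed_for(config.seed, 0),
        rewiring_prob=config.rewiring_prob,
        edge_list_path=config.edge_list_path,
    )


def run_simulation(config: SimConfig, engine: str = "kernel",
                   network: SocialNetwork | None = None) -> MetricsSeries:
    """Run one realization from an all-naive population and empty archive.

    Deterministic given ``config.seed``: the seed spawns separate substreams
    for the topology and for the payoff/dynamics randomness.

    Parameters
    ----------
    config
        Simulation configuration (horizon defaults to 20 N steps).
    engine
        ``"kernel"`` (compiled, default) or ``"python"`` (the readable
        object engine; identical rules, different random streams).
    network
        Optionally reuse an existing topology instead of generating one.
    """
    net = network if network is not None else _build_net(config)
    if net.node_count != config.N:
        raise ValueError("network size does not match config.N")

    if engine == "kernel":
        indptr, indices = net.csr()
        zbar, lbar, tser = _kernel.simulate(
            indptr, indices, N=config.N, B=config.B, Ci=config.Ci,
            Cs=config.Cs, Cr=config.Cr, X=config.X, r=config.r, q=config.q,
            horizon=config.horizon, payoff_rate=config.payoff_rate,
            strategy=config.strategy, seed=_seed_for(config.seed, 1),
        )
        return MetricsSeries(zbar, lbar, tser)

    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")

    table = PayoffTable(config.X, rate=config.payoff_rate,
                        seed=_seed_for(config.seed, 2))
    rng = np.random.default_rng(_seed_for(config.seed, 3))
    population = init_population(config)
    archive = Archive()
    zbar = np.empty(config.horizon)
    lbar = np.empty(config.horizon)
    tser = np.empty(config.horizon, dtype=np.int64)
    for t in range(config.horizon):
        time_step(population, net, archive, table, config, rng)
        zbar[t] = sum(a.cumulative_payoff for a in population) / config.N
        lbar[t] = sum(a.max_level for a in population) / config.N
        tser[t] = archive.total_count
    return MetricsSeries(zbar, lbar, tser)


def stationary_summary(series: Sequence[MetricsSeries],
                       window: int) -> StationarySummary:
    """Summarize realizations by their final-window means.

    Each realization contributes the mean of each measure over its last
    ``window`` steps; the summary is the grand mean with the standard error
    of the between-realization spread.
    """
    if not series:
        raise ValueError("need at least one realization")
    if window < 1:
        raise ValueError("window must be >= 1")
    for s in series:
        if len(s) < window:
            raise ValueError(
                f"series of length {len(s)} shorter than window {window}")
    z = np.array([s.mean_payoff[-window:].mean() for s in series])
    l = np.array([s.mean_level[-window:].mean() for s in series])
    t = np.array([s.distinct_traits[-window:].mean() for s in series])
    n = len(series)

    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")

    return StationarySummary(float(z.mean()), float(l.mean()),
                             float(t.mean()), se(z), se(l), se(t), n, window)


def _run_point(config: SimConfig, realizations: int, master_seed: int,
               grid_index: int, engine: str) -> StationarySummary:
    series = []
    for ri in range(realizations):
        cfg = config.with_updates(
            seed=_seed_for(master_seed, grid_index, ri))
        series.append(run_simulation(cfg, engine=engine))
    return stationary_summary(series, config.stationary_window)


_GRID_COLUMNS = ("N", "mean_degree", "r", "strategy", "network_family",
                 "B", "Ci", "Cs", "Cr", "X")


def sweep(grid: Iterable[SimConfig], realizations: int, seed: int,
          engine: str = "kernel") -> pd.DataFrame:
    """Run a grid of configurations, each over independent realizations.

    Per-realization seeds are derived deterministically from
    ``(seed, grid index, realization index)``, so results do not depend on
    execution order.  Returns one row per grid point with the stationary
    summaries and their standard errors.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty configuration grid")
    rows = []
    for gi, cfg in enumerate(grid):
        t0 = time.perf_counter()
        summ = _run_point(cfg, realizations, seed, gi, engine)
        row = {col: getattr(cfg, col) for col in _GRID_COLUMNS}
        row.update(Z_max=summ.Z_max, L_max=summ.L_max, T_max=summ.T_max,
                   se_Z=summ.se_Z, se_L=summ.se_L, se_T=summ.se_T,
                   realizations=summ.realizations)
        rows.append(row)
        log.info("sweep point %d/%d (k=%s, r=%s): Z_max=%.1f [%.1fs]",
                 gi + 1, len(grid), cfg.mean_degree, cfg.r, summ.Z_max,
                 time.perf_counter() - t0)
    return pd.DataFrame(rows)


def grid_from_base(base: SimConfig, **axes: Sequence) -> list[SimConfig]:
    """Cartesian product of parameter axes over a base configuration.

    ``grid_from_base(cfg, r=[0, 0.5, 1], mean_degree=[1, 8])`` yields six
    configs ordered with the last axis varying fastest.
    """
    valid = {f.name for f in fields(SimConfig)}
    for name in axes:
        if name not in valid:
            raise ValueError(f"unknown SimConfig field {name!r}")
    names = list(axes)
    out = []
    for combo in itertools.product(*(axes[n] for n in names)):
        out.append(base.with_updates(**dict(zip(names, combo))))
    return out
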