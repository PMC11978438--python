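"""Open-ended cultural trait space.

A cultural trait is identified by the branch it belongs to (one of ``X``
parallel development paths) and its complexity level (position in the
functional-dependency chain: acquiring a level-``l`` trait requires owning
some trait at level ``l - 1``).  Every ``(branch, level)`` pair carries a
single, world-level integer payoff ``z`` drawn once on first touch; traits
with ``z = 0`` are unviable and can never be acquired.

Payoffs follow the chain *exponential draw -> square -> double -> round to
integer*, which makes high-payoff innovations rare among many worthless
attempts.  The default exponential rate is ``2 ln 2``, calibrated so the
probability of an unviable draw is exactly one half.
"""

from __future__ import annotations

import math
from typing import Iterator, NamedTuple

import numpy as np

__all__ = [
    "DEFAULT_RATE",
    "Trait",
    "PayoffTable",
    "sample_payoff",
    "is_viable",
]

#: Default rate of the exponential payoff draw, chosen so that P(z = 0) = 1/2.
DEFAULT_RATE: float = 2.0 * math.log(2.0)


class Trait(NamedTuple):
    """An atomic cultural item: a (branch, level) position with its payoff."""

    branch: int
    level: int
    payoff: int


def sample_payoff(rng_draw: float) -> int:
    """Map one exponential variate to an integer payoff.

    The draw is squared, doubled and rounded half-up:
    ``z = round(2 * draw**2)``.

    Parameters
    ----------
    rng_draw
        A single non-negative exponential variate.

    Returns
    -------
    int
        The integer payoff, ``>= 0``.
    """
    if rng_draw < 0:
        raise ValueError(f"exponential draw must be non-negative, got {rng_draw!r}")
    # round-half-up; the half-integer boundary has probability zero but the
    # convention is fixed for reproducibility (np.round would round half-even)
    return int(math.floor(2.0 * rng_draw * rng_draw + 0.5))


def is_viable(payoff: int) -> bool:
    """A trait is viable (acquirable) iff its payoff is strictly positive."""
    return payoff > 0


class PayoffTable:
    """Lazily materialized map ``(branch, level) -> payoff``.

    The level axis is unbounded, so payoffs are drawn on first query from a
    private random stream and memoized: the world is consistent across all
    agents and all times, and an unviable ``(branch, level)`` stays unviable
    forever.  Given the same seed and the same sequence of first-touch
    queries, two tables materialize bit-identical payoff maps.

    Parameters
    ----------
    branch_count
        Number of parallel cultural branches ``X``.
    rate
        Rate of the exponential payoff draw (default ``2 ln 2``).
    seed
        Seed of the private payoff stream.
    """

    def __init__(self, branch_count: int, rate: float = DEFAULT_RATE,
                 seed: int | np.random.SeedSequence | None = None) -> None:
        if branch_count < 1:
            raise ValueError(f"branch_count must be >= 1, got {branch_count}")
        if rate <= 0:
            raise ValueError(f"rate must be positive, got {rate}")
        self.branch_count = branch_count
        self.rate = rate
        self._rng = np.random.default_rng(seed)
        self._materialized: dict[tuple[int, int], int] = {}

    def __len__(self) -> int:
        return len(self._materialized)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self._materialized)

    def get_payoff(self, branch: int, level: int) -> int:
        """Return the payoff of ``(branch, level)``, drawing it if new.

        Raises
        ------
        ValueError
            If ``branch`` is outside ``1..X`` or ``level < 1``.
        """
        if not 1 <= branch <= self.branch_count:
            raise ValueError(
                f"branch must be in 1..{self.branch_count}, got {branch}")
        if level < 1:
            raise ValueError(f"level must be >= 1, got {level}")
        key = (branch, level)
        z = self._materialized.get(key)
        if z is None:
            z = sample_payoff(self._rng.exponential(1.0 / self.rate))
            self._materialized[key] = z
        return z

    def trait(self, branch: int, level: int) -> Trait:
        """Convenience wrapper returning a full :class:`Trait`."""
        return Trait(branch, level, self.get_payoff(branch, level))

    # ------------------------------------------------------------------
    # post-mortem dump/load of the materialized map
    # ------------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the materialized map as CSV (columns branch, level, payoff)."""
        import pandas as pd

        rows = [(b, l, z) for (b, l), z in sorted(self._materialized.items())]
        pd.DataFrame(rows, columns=["branch", "level", "payoff"]).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path, branch_count: int, rate: float = DEFAULT_RATE,
                 seed: int | None = None) -> "PayoffTable":
        """Rebuild a table whose materialized entries are read from CSV.

        Unmaterialized entries are still drawn lazily from the (fresh) stream,
        so this is for post-mortems of a finished run, not for resuming one.
        """
        import pandas as pd

        table = cls(branch_count, rate=rate, seed=seed)
        df = pd.read_csv(path)
        for b, l, z in df[["branch", "level", "payoff"]].itertuples(index=False):
            table._materialized[(int(b), int(l))] = int(z)
        return table
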