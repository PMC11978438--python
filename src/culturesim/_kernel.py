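"""Compiled simulation kernel.

Implements exactly the per-agent cycle of :mod:`culturesim.dynamics`
(death-birth, learning with probability-``r`` dispatch to the recommender,
innovation) over flat numpy arrays, jitted with numba.  The parameter sweeps
of the experiments need on the order of 10^8 agent-steps, which is far out
of reach of the object engine; this kernel runs them in seconds.

State layout (``CAP`` is the current level capacity, grown by doubling):

- ``budget[N]``, ``lvl[N]``, ``Z[N]``: per-agent budget, repertoire depth,
  cumulative payoff.
- ``rep_branch[N, CAP]``, ``rep_payoff[N, CAP]``: per-agent repertoire;
  row ``i`` is valid up to ``lvl[i]`` (level ``l`` lives at column ``l-1``).
- ``tab[X, CAP]``: lazily drawn payoff table, -1 = not yet drawn.
- ``archived[X, CAP]``: which (branch, level) pairs the archive holds.
- ``best_z[CAP]``, ``best_n[CAP]``, ``best_branch[CAP, X]``: per level the
  maximum archived payoff and the branches attaining it (for uniform
  tie-breaking in recommendations).

The kernel uses numba's single global seeded RNG stream; identical seeds
give bit-identical trajectories.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STRATEGY_CODES = {"payoff_biased": 0, "level_biased": 1,
                  "random_neighbour": 2}


@njit(cache=True)
def _simulate(indptr, indices, N, B, Ci, Cs, Cr, X, r, q, horizon,
              scale, strategy, seed):  # pragma: no cover - jitted
    np.random.seed(seed)

    CAP = 128
    budget = np.full(N, B)
    lvl = np.zeros(N, dtype=np.int64)
    Z = np.zeros(N, dtype=np.int64)
    rep_branch = np.zeros((N, CAP), dtype=np.int32)
    rep_payoff = np.zeros((N, CAP), dtype=np.int32)
    tab = np.full((X, CAP), -1, dtype=np.int32)
    archived = np.zeros((X, CAP), dtype=np.bool_)
    best_z = np.zeros(CAP, dtype=np.int32)
    best_n = np.zeros(CAP, dtype=np.int32)
    best_branch = np.zeros((CAP, X), dtype=np.int32)
    T = 0

    Zbar = np.empty(horizon)
    Lbar = np.empty(horizon)
    Tser = np.empty(horizon, dtype=np.int64)

    for t in range(horizon):
        order = np.random.permutation(N)
        for oi in range(N):
            i = order[oi]
            # (i) death-birth
            if q > 0.0 and np.random.random() < q:
                lvl[i] = 0
                Z[i] = 0
                budget[i] = B
            li = lvl[i]
            nl = li  # column of level li + 1

            # grow capacity before any access at column nl
            if nl >= CAP:
                NEW = CAP * 2
                rb = np.zeros((N, NEW), dtype=np.int32)
                rp = np.zeros((N, NEW), dtype=np.int32)
                rb[:, :CAP] = rep_branch
                rp[:, :CAP] = rep_payoff
                rep_branch, rep_payoff = rb, rp
                tb = np.full((X, NEW), -1, dtype=np.int32)
                tb[:, :CAP] = tab
                tab = tb
                av = np.zeros((X, NEW), dtype=np.bool_)
                av[:, :CAP] = archived
                archived = av
                bz = np.zeros(NEW, dtype=np.int32)
                bn = np.zeros(NEW, dtype=np.int32)
                bb = np.zeros((NEW, X), dtype=np.int32)
                bz[:CAP] = best_z
                bn[:CAP] = best_n
                bb[:CAP, :] = best_branch
                best_z, best_n, best_branch = bz, bn, bb
                CAP = NEW

            # (ii) learning
            learned = False
            if r > 0.0 and np.random.random() < r:
                # algorithmic mediation: best archived trait at level li+1
                if best_n[nl] > 0 and budget[i] >= Cr:
                    if best_n[nl] == 1:
                        br = best_branch[nl, 0]
                    else:
                        br = best_branch[nl, np.random.randint(best_n[nl])]
                    rep_branch[i, nl] = br
                    rep_payoff[i, nl] = best_z[nl]
                    Z[i] += best_z[nl]
                    lvl[i] = li + 1
                    budget[i] -= Cr
                    learned = True
            else:
                # social learning from the selected neighbour
                lo, hi = indptr[i], indptr[i + 1]
                if hi > lo:
                    if strategy == 2:
                        teacher = indices[lo + np.random.randint(hi - lo)]
                    else:
                        best_score = np.int64(-1)
                        ties = 0
                        for e in range(lo, hi):
                            j = indices[e]
                            s = Z[j] if strategy == 0 else lvl[j]
                            if s > best_score:
                                best_score = s
                                ties = 1
                            elif s == best_score:
                                ties += 1
                        pick = 0 if ties == 1 else np.random.randint(ties)
                        teacher = -1
                        for e in range(lo, hi):
                            j = indices[e]
                            s = Z[j] if strategy == 0 else lvl[j]
                            if s == best_score:
                                if pick == 0:
                                    teacher = j
                                    break
                                pick -= 1
                    if lvl[teacher] >= li + 1 and budget[i] >= Cs:
                        rep_branch[i, nl] = rep_branch[teacher, nl]
                        rep_payoff[i, nl] = rep_payoff[teacher, nl]
                        Z[i] += rep_payoff[teacher, nl]
                        lvl[i] = li + 1
                        budget[i] -= Cs
                        learned = True

            # (iii) innovation, only if learning did not succeed
            if not learned and budget[i] >= Ci:
                budget[i] -= Ci
                bx = np.random.randint(X)
                zv = tab[bx, nl]
                if zv < 0:
                    draw = np.random.exponential(scale)
                    zv = np.int32(np.floor(2.0 * draw * draw + 0.5))
                    tab[bx, nl] = zv
                if zv > 0:
                    rep_branch[i, nl] = bx
                    rep_payoff[i, nl] = zv
                    Z[i] += zv
                    lvl[i] = li + 1
                    if not archived[bx, nl]:
                        archived[bx, nl] = True
                        T += 1
                        if zv > best_z[nl]:
                            best_z[nl] = zv
                            best_n[nl] = 1
                            best_branch[nl, 0] = bx
                        elif zv == best_z[nl]:
                            best_branch[nl, best_n[nl]] = bx
                            best_n[nl] += 1

        Zbar[t] = Z.mean()
        Lbar[t] = lvl.mean()
        Tser[t] = T

    return Zbar, Lbar, Tser


def simulate(indptr: np.ndarray, indices: np.ndarray, *, N: int, B: float,
             Ci: float, Cs: float, Cr: float, X: int, r: float, q: float,
             horizon: int, payoff_rate: float, strategy: str, seed: int):
    """Run one realization on the compiled kernel.

    Returns ``(Zbar, Lbar, T)`` per-step series of the mean cumulative
    payoff, mean repertoire level and distinct-trait count.
    """
    code = STRATEGY_CODES[strategy]
    return _simulate(
        indptr.astype(np.int64), indices.astype(np.int64),
        np.int64(N), float(B), float(Ci), float(Cs), float(Cr),
        np.int64(X), float(r), float(q), np.int64(horizon),
        1.0 / float(payoff_rate), np.int64(code), np.int64(seed),
    )
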