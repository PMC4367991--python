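"""Spatial simulator: two fixed groups on a periodic square lattice.

Each site holds a player with an immutable group label (1 or 2) and a
mutable behavior (1 or 2).  Every round a player accumulates payoff from
2x2 games against its four von Neumann neighbors -- the matrix depends on
the group pair -- and then all players simultaneously adopt the behavior of
the highest-payoff member of {self, N, E, S, W}.  Ties prefer self, then the
fixed neighbor order N, E, S, W, so the dynamics are fully deterministic
given the initial grids.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .game_core import SimplifiedGameSet
from .observables import ConvergenceSpec, Trajectory

#: np.roll shifts that place the N, E, S, W neighbor's value at the focal site.
NEIGHBOR_SHIFTS: Tuple[Tuple[int, int], ...] = ((1, 0), (0, -1), (-1, 0), (0, 1))


class ConfigError(ValueError):
    """Invalid lattice / initialization configuration."""


@dataclass(frozen=True)
class LatticeConfig:
    """Initialization parameters for one run.

    L
        Lattice side; the population has L*L sites, periodic boundaries.
    f
        Probability that a site belongs to small group 1 (i.i.d. per site).
    init_behavior1_prob
        Probability that a site starts with behavior 1 (default 0.5).
    seed
        Seed for the initialization RNG; the dynamics themselves are
        deterministic, so the seed fixes the entire run.
    """

    L: int = 100
    f: float = 0.5
    init_behavior1_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ConfigError(f"L must be >= 2, got {self.L}")
        if not 0.0 <= self.f <= 1.0:
            raise ConfigError(f"f must lie in [0, 1], got {self.f}")
        if not 0.0 <= self.init_behavior1_prob <= 1.0:
            raise ConfigError(
                f"init_behavior1_prob must lie in [0, 1], got {self.init_behavior1_prob}"
            )
        if self.seed < 0:
            raise ConfigError(f"seed must be non-negative, got {self.seed}")


@dataclass
class PopulationState:
    """Paired grids of immutable group labels and mutable behaviors."""

    group: np.ndarray
    behavior: np.ndarray
    step: int = 0

    def copy(self) -> "PopulationState":
        return PopulationState(self.group, self.behavior.copy(), self.step)


def initialize_population(config: LatticeConfig) -> PopulationState:
    """Draw i.i.d. group labels (P[group 1] = f) and behaviors per site."""
    rng = np.random.default_rng(config.seed)
    shape = (config.L, config.L)
    group = np.where(rng.random(shape) < config.f, 1, 2).astype(np.int8)
    behavior = np.where(
        rng.random(shape) < config.init_behavior1_prob, 1, 2
    ).astype(np.int8)
    group.setflags(write=False)
    return PopulationState(group=group, behavior=behavior, step=0)


@functools.lru_cache(maxsize=128)
def payoff_lookup(games: SimplifiedGameSet) -> np.ndarray:
    """Focal-player payoff table indexed [g_a-1, b_a-1, g_b-1, b_b-1].

    Entry (a, b) is the payoff to player a from one game against player b:
    group pair (1,1) reads the within-group-1 matrix, (2,2) the
    within-group-2 matrix, and mixed pairs the between-group matrix with the
    group-1 member on the row axis regardless of argument order.
    """
    g = games
    lut = np.zeros((2, 2, 2, 2))
    # both group 1: focal is a row player of the within-group-1 matrix
    lut[0, 0, 0, 0] = g.C1
    lut[0, 0, 0, 1] = g.B1
    # both group 2: row player of the within-group-2 matrix
    lut[1, 1, 1, 0] = g.B2
    lut[1, 1, 1, 1] = g.C2
    # focal group 1 vs group 2: row player of the between-group matrix
    lut[0, 0, 1, 0] = g.C3
    lut[0, 0, 1, 1] = g.B3
    # focal group 2 vs group 1: column player (row behavior is the opponent's)
    lut[1, 1, 0, 0] = g.B4
    lut[1, 1, 0, 1] = g.C4
    lut.setflags(write=False)
    return lut


def pairwise_payoffs(
    games: SimplifiedGameSet,
    group_a: int, behavior_a: int,
    group_b: int, behavior_b: int,
) -> Tuple[float, float]:
    """Payoffs (to a, to b) from one game between players a and b."""
    for label in (group_a, behavior_a, group_b, behavior_b):
        if label not in (1, 2):
            raise ValueError(f"labels must be 1 or 2, got {label}")
    lut = payoff_lookup(games)
    return (
        float(lut[group_a - 1, behavior_a - 1, group_b - 1, behavior_b - 1]),
        float(lut[group_b - 1, behavior_b - 1, group_a - 1, behavior_a - 1]),
    )


def _accumulate(group0: np.ndarray, behavior0: np.ndarray, lut: np.ndarray) -> np.ndarray:
    total = np.zeros(behavior0.shape)
    for shift in NEIGHBOR_SHIFTS:
        gn = np.roll(group0, shift, (0, 1))
        bn = np.roll(behavior0, shift, (0, 1))
        total += lut[group0, behavior0, gn, bn]
    return total


def accumulate_payoffs(state: PopulationState, games: SimplifiedGameSet) -> np.ndarray:
    """Per-site payoff summed over the four von Neumann neighbor games.

    Payoffs are recomputed from zero each round; nothing carries over.
    """
    if state.group.shape != state.behavior.shape:
        raise ValueError("group and behavior grids must have the same shape")
    return _accumulate(state.group - 1, state.behavior - 1, payoff_lookup(games))


def _imitate(behavior: np.ndarray, payoffs: np.ndarray) -> np.ndarray:
    # candidate order self, N, E, S, W; argmax takes the first maximum, which
    # implements "prefer self, then fixed neighbor order" tie-breaking
    cand_pay = np.stack(
        [payoffs] + [np.roll(payoffs, s, (0, 1)) for s in NEIGHBOR_SHIFTS]
    )
    cand_beh = np.stack(
        [behavior] + [np.roll(behavior, s, (0, 1)) for s in NEIGHBOR_SHIFTS]
    )
    best = cand_pay.argmax(axis=0)
    return np.take_along_axis(cand_beh, best[None, ...], axis=0)[0]


def synchronous_update(state: PopulationState, payoffs: np.ndarray) -> PopulationState:
    """All sites simultaneously copy the best-payoff candidate's behavior.

    The candidate set is {self, N, E, S, W}; a site keeps its behavior
    whenever it is itself (weakly) maximal.  Group labels never change.
    """
    new_behavior = _imitate(state.behavior, payoffs)
    return PopulationState(state.group, new_behavior, state.step + 1)


def _extend_cyclic(series: np.ndarray, period: int, length: int) -> np.ndarray:
    """Continue a series that has locked into an exact period-1/2 cycle."""
    cur = len(series)
    if cur >= length:
        return series
    out = np.empty(length)
    out[:cur] = series
    if period == 1:
        out[cur:] = series[-1]
    else:
        idx = np.arange(cur, length)
        out[cur:] = np.where((idx - cur) % 2 == 0, series[-2], series[-1])
    return out


def run(
    config: LatticeConfig,
    games: SimplifiedGameSet,
    spec: Optional[ConvergenceSpec] = None,
    *,
    initial_state: Optional[PopulationState] = None,
    min_steps: int = 0,
) -> Trajectory:
    """Iterate payoff accumulation and synchronous imitation to steady state.

    Records the population and per-group behavior-1 fractions each round.
    The loop stops once the convergence protocol has fired and the averaging
    window is complete, or at ``max_steps`` (flagged as non-converged).
    Because the update is deterministic, the state frequently locks into an
    exact fixed point or 2-cycle; the loop detects this by state equality
    and continues the series analytically, which is exact and avoids
    simulating thousands of identical rounds.  ``min_steps`` guarantees a
    minimum recorded series length (useful for time-course output).

    ``initial_state`` overrides the seeded initialization, e.g. to start
    from a transformed copy of another run's initial grids.
    """
    spec = spec if spec is not None else ConvergenceSpec()
    state = initial_state.copy() if initial_state is not None else initialize_population(config)
    group = state.group
    group0 = (group - 1).astype(np.int8)
    g1 = group == 1
    n = group.size
    n1 = int(g1.sum())
    n2 = n - n1
    w = n1 / n
    lut = payoff_lookup(games)

    def _fracs(beh):
        b1 = beh == 1
        r = b1.sum() / n
        r1 = (b1 & g1).sum() / n1 if n1 else 0.0
        r2 = (b1 & ~g1).sum() / n2 if n2 else 0.0
        return r, r1, r2

    behavior = state.behavior.copy()
    r, r1, r2 = _fracs(behavior)
    rho = [r]
    rho_g1 = [r1]
    rho_g2 = [r2]
    prev: Optional[np.ndarray] = None
    consecutive = 0
    fluct_step: Optional[int] = None
    period: Optional[int] = None

    for t in range(1, spec.max_steps + 1):
        payoffs = _accumulate(group0, behavior - 1, lut)
        new = _imitate(behavior, payoffs)
        if np.array_equal(new, behavior):
            period = 1
        elif prev is not None and np.array_equal(new, prev):
            period = 2
        prev = behavior
        behavior = new
        r, r1, r2 = _fracs(behavior)
        rho.append(r)
        rho_g1.append(r1)
        rho_g2.append(r2)
        if abs(rho[-1] - rho[-2]) < spec.fluct_tol:
            consecutive += 1
            if fluct_step is None and consecutive >= spec.window:
                fluct_step = t
        else:
            consecutive = 0
        if period is not None:
            break
        if (
            fluct_step is not None
            and t >= fluct_step + spec.average_window
            and t >= min_steps
        ):
            break

    rho_a = np.asarray(rho)
    rho_g1_a = np.asarray(rho_g1)
    rho_g2_a = np.asarray(rho_g2)
    T = len(rho_a) - 1
    converged = False
    converged_at: Optional[int] = None

    if period is not None:
        amplitude = abs(rho_a[-1] - rho_a[-2]) if period == 2 else 0.0
        if amplitude < spec.fluct_tol:
            converged = True
            converged_at = T - period  # step the cycle was entered
        elif fluct_step is not None:
            converged = True
            converged_at = fluct_step
        if converged:
            target = max(converged_at + spec.average_window, min_steps)
        else:
            target = max(T, min_steps)
        rho_a = _extend_cyclic(rho_a, period, target + 1)
        rho_g1_a = _extend_cyclic(rho_g1_a, period, target + 1)
        rho_g2_a = _extend_cyclic(rho_g2_a, period, target + 1)
    elif fluct_step is not None and T >= fluct_step + spec.average_window:
        converged = True
        converged_at = fluct_step

    if converged:
        steady = float(
            rho_a[converged_at + 1 : converged_at + 1 + spec.average_window].mean()
        )
    else:
        steady = float(rho_a[-spec.average_window :].mean())

    final = PopulationState(group, behavior, state.step + T)
    return Trajectory(
        rho1=rho_a,
        rho1_g1=rho_g1_a,
        rho1_g2=rho_g2_a,
        group1_fraction=w,
        converged_at=converged_at,
        converged=converged,
        steady_rho1=steady,
        cycle_period=period,
        n_simulated_steps=T,
        final_state=final,
    )
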