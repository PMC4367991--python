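"""Replicated runs, parameter sweeps and snapshot capture.

Three experiment designs probe the model: sweeping the group-1 fraction f at
equal cohesion (q = 1), sweeping the cohesion ratio q at fixed f (realized by
scaling the group-2 stakes, C2 = C1/q and C4 = C3/q), and the full f x q
factorial surface.  Each grid point is averaged over independent seeded
replicates because the random initial grids add run-to-run dispersion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .game_core import SimplifiedGameSet, compute_q_general
from .lattice import LatticeConfig, PopulationState, initialize_population, run
from .lattice import accumulate_payoffs, synchronous_update
from .observables import ConvergenceSpec, Trajectory

logger = logging.getLogger(__name__)

#: Benchmark parameter set [B1,B2,B3,B4,C1,C2,C3,C4]: harmony games inside
#: both groups, snowdrift between, equal cohesion (q = 1).
REFERENCE_PARAMS = SimplifiedGameSet.from_vector((2, 2, -1, -1, 1, 1, 2, 2))

#: Six parameter sets that all have q = 1 but different payoff magnitudes;
#: used to check that the f-dependence of the steady state is robust to the
#: particular payoffs once the cohesion ratio is held fixed.
EQUAL_COHESION_PARAMETER_GROUPS: Tuple[Tuple[float, ...], ...] = (
    (2, 2, -1, -1, 1, 1, 2, 2),
    (1, 1, -1, -1, 1, 1, 2, 2),
    (2, 2, -2, -2, 1, 1, 2, 2),
    (1, 1, -2, -2, 1, 1, 2, 2),
    (2, 2, -1, -1, 2, 2, 2, 2),
    (2, 2, -1, -1, 1, 1, 3, 3),
)

#: Standard q-grid for cohesion sweeps.
DEFAULT_Q_GRID: Tuple[float, ...] = (1 / 9, 1 / 3, 1.0, 3.0, 9.0)


@dataclass(frozen=True)
class QScheme:
    """Base parameters plus the rule that realizes a target cohesion ratio q.

    Holds [B1, B2, B3, B4, C1, C3] fixed and sets C2 = C1/q, C4 = C3/q, so
    q = (C3 + C1) / (C4 + C2) holds exactly while the within/between game
    types (harmony / snowdrift) are preserved for every q > 0.
    """

    B1: float = 2.0
    B2: float = 2.0
    B3: float = -1.0
    B4: float = -1.0
    C1: float = 1.0
    C3: float = 2.0

    def games_for(self, q: float) -> SimplifiedGameSet:
        if q <= 0:
            raise ValueError(f"q must be positive, got {q}")
        return SimplifiedGameSet(
            B1=self.B1, B2=self.B2, B3=self.B3, B4=self.B4,
            C1=self.C1, C2=self.C1 / q, C3=self.C3, C4=self.C3 / q,
        )


DEFAULT_QSCHEME = QScheme()

SWEEP_COLUMNS = (
    "f", "q", "parameter_set_id", "replicate", "seed", "steady_rho1", "converged",
)


@dataclass
class ReplicateSummary:
    """Steady-state fractions from independent seeded replicates."""

    mean_steady_rho1: float
    steady_rho1: np.ndarray
    seeds: np.ndarray
    converged: np.ndarray
    trajectories: Optional[List[Trajectory]] = None


def run_replicates(
    config: LatticeConfig,
    games: SimplifiedGameSet,
    spec: Optional[ConvergenceSpec] = None,
    n_reps: int = 10,
    seed0: Optional[int] = None,
    *,
    keep_trajectories: bool = False,
    min_steps: int = 0,
) -> ReplicateSummary:
    """Run ``n_reps`` independent replicates with seeds seed0, seed0+1, ..."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seed0 = config.seed if seed0 is None else seed0
    seeds = np.arange(seed0, seed0 + n_reps)
    values = np.empty(n_reps)
    converged = np.empty(n_reps, dtype=bool)
    trajectories: List[Trajectory] = []
    for k, seed in enumerate(seeds):
        traj = run(replace(config, seed=int(seed)), games, spec, min_steps=min_steps)
        values[k] = traj.steady_rho1
        converged[k] = traj.converged
        if keep_trajectories:
            trajectories.append(traj)
    return ReplicateSummary(
        mean_steady_rho1=float(values.mean()),
        steady_rho1=values,
        seeds=seeds,
        converged=converged,
        trajectories=trajectories if keep_trajectories else None,
    )


def _sweep_rows(
    points: Sequence[Tuple[float, float, int, SimplifiedGameSet]],
    L: int,
    init_behavior1_prob: float,
    spec: Optional[ConvergenceSpec],
    n_reps: int,
    seed0: int,
) -> pd.DataFrame:
    rows = []
    for i, (f, q, param_id, games) in enumerate(points):
        config = LatticeConfig(L=L, f=f, init_behavior1_prob=init_behavior1_prob)
        summary = run_replicates(
            config, games, spec, n_reps=n_reps, seed0=seed0 + i * n_reps
        )
        logger.info(
            "sweep point f=%.3g q=%.3g set=%d: mean steady rho1=%.4f",
            f, q, param_id, summary.mean_steady_rho1,
        )
        for k in range(n_reps):
            rows.append({
                "f": f,
                "q": q,
                "parameter_set_id": param_id,
                "replicate": k,
                "seed": int(summary.seeds[k]),
                "steady_rho1": summary.steady_rho1[k],
                "converged": bool(summary.converged[k]),
            })
    return pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))


def sweep_f(
    f_values: Iterable[float],
    games: SimplifiedGameSet = REFERENCE_PARAMS,
    *,
    L: int = 100,
    init_behavior1_prob: float = 0.5,
    spec: Optional[ConvergenceSpec] = None,
    n_reps: int = 10,
    seed0: int = 0,
    parameter_set_id: int = 0,
) -> pd.DataFrame:
    """Steady-state table over a grid of group-1 fractions at fixed payoffs."""
    q = compute_q_general(games)
    points = [(float(f), q, parameter_set_id, games) for f in f_values]
    return _sweep_rows(points, L, init_behavior1_prob, spec, n_reps, seed0)


def sweep_q(
    q_values: Iterable[float] = DEFAULT_Q_GRID,
    scheme: QScheme = DEFAULT_QSCHEME,
    *,
    f: float = 0.5,
    L: int = 100,
    init_behavior1_prob: float = 0.5,
    spec: Optional[ConvergenceSpec] = None,
    n_reps: int = 10,
    seed0: int = 0,
    parameter_set_id: int = 0,
) -> pd.DataFrame:
    """Steady-state table over a grid of cohesion ratios at fixed f."""
    points = [
        (float(f), float(q), parameter_set_id, scheme.games_for(float(q)))
        for q in q_values
    ]
    return _sweep_rows(points, L, init_behavior1_prob, spec, n_reps, seed0)


def sweep_fq(
    f_values: Iterable[float],
    q_values: Iterable[float],
    scheme: QScheme = DEFAULT_QSCHEME,
    *,
    L: int = 100,
    init_behavior1_prob: float = 0.5,
    spec: Optional[ConvergenceSpec] = None,
    n_reps: int = 10,
    seed0: int = 0,
    parameter_set_id: int = 0,
) -> pd.DataFrame:
    """Full factorial steady-state surface over f and q grids."""
    points = []
    for f in f_values:
        for q in q_values:
            points.append(
                (float(f), float(q), parameter_set_id, scheme.games_for(float(q)))
            )
    return _sweep_rows(points, L, init_behavior1_prob, spec, n_reps, seed0)


def encode_states(group: np.ndarray, behavior: np.ndarray) -> np.ndarray:
    """Encode (group, behavior) into the 4 snapshot states 0..3.

    0 = behavior 1 in group 1, 1 = behavior 2 in group 1,
    2 = behavior 1 in group 2, 3 = behavior 2 in group 2.
    """
    return ((np.asarray(group) - 1) * 2 + (np.asarray(behavior) - 1)).astype(np.int8)


def capture_snapshots(
    config: LatticeConfig,
    games: SimplifiedGameSet,
    steps: Iterable[int] = (1, 3, 100, 500),
) -> Dict[int, np.ndarray]:
    """Run a single simulation and record 4-state grids at the given steps.

    Step indices are 1-based update rounds; step 0 is the initial state.
    """
    wanted = sorted(set(int(s) for s in steps))
    if wanted and wanted[0] < 0:
        raise ValueError(f"snapshot steps must be non-negative, got {wanted[0]}")
    state = initialize_population(config)
    grids: Dict[int, np.ndarray] = {}
    if wanted and wanted[0] == 0:
        grids[0] = encode_states(state.group, state.behavior)
    last = wanted[-1] if wanted else 0
    for t in range(1, last + 1):
        payoffs = accumulate_payoffs(state, games)
        state = synchronous_update(state, payoffs)
        if t in wanted:
            grids[t] = encode_states(state.group, state.behavior)
    return grids


def swapped_initial_state(state: PopulationState) -> PopulationState:
    """Label-swapped copy of an initial state (group 1<->2, behavior 1<->2).

    Running the swapped state under :meth:`SimplifiedGameSet.swapped`
    parameters reproduces the original trajectory with labels exchanged,
    i.e. rho1'(t) = 1 - rho1(t) exactly at every step.
    """
    group = (3 - state.group).astype(np.int8)
    group.setflags(write=False)
    behavior = (3 - state.behavior).astype(np.int8)
    return PopulationState(group=group, behavior=behavior, step=state.step)
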