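"""Lattice dynamics: initialization, payoffs, imitation, full runs."""

import numpy as np
import pytest

import groupnorms as gn
from groupnorms.lattice import NEIGHBOR_SHIFTS


# ----------------------------------------------------------- initialization

def test_initialize_extreme_group_fractions():
    all_one = gn.initialize_population(gn.LatticeConfig(L=10, f=1.0, seed=1))
    assert (all_one.group == 1).all()
    all_two = gn.initialize_population(gn.LatticeConfig(L=10, f=0.0, seed=1))
    assert (all_two.group == 2).all()


def test_initialize_realized_fraction_within_binomial_bound():
    # 3 binomial sigma at L=100, f=0.5 is 0.015
    for seed in (0, 1, 2):
        state = gn.initialize_population(gn.LatticeConfig(L=100, f=0.5, seed=seed))
        assert abs((state.group == 1).mean() - 0.5) <= 0.015


def test_initialize_is_deterministic_per_seed():
    cfg = gn.LatticeConfig(L=20, f=0.4, seed=42)
    a, b = gn.initialize_population(cfg), gn.initialize_population(cfg)
    assert np.array_equal(a.group, b.group) and np.array_equal(a.behavior, b.behavior)
    c = gn.initialize_population(gn.LatticeConfig(L=20, f=0.4, seed=43))
    assert not (
        np.array_equal(a.group, c.group) and np.array_equal(a.behavior, c.behavior)
    )


@pytest.mark.parametrize(
    "kwargs", [dict(f=1.2), dict(f=-0.1), dict(L=1), dict(init_behavior1_prob=2.0)]
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(gn.ConfigError):
        gn.LatticeConfig(**{"L": 10, **kwargs})


# ---------------------------------------------------------------- payoffs

@pytest.mark.parametrize(
    "labels, expected",
    [
        ((1, 1, 1, 1), (1.0, 1.0)),    # mutual behavior 1 inside group 1 -> C1
        ((1, 1, 2, 2), (-1.0, -1.0)),  # between groups at (1,2) -> (B3, B4)
        ((2, 1, 1, 2), (0.0, 0.0)),    # group-2 player listed first: profile (2,1)
        ((2, 2, 2, 2), (1.0, 1.0)),    # mutual behavior 2 inside group 2 -> C2
    ],
)
def test_pairwise_payoff_examples(ref_params, labels, expected):
    assert gn.pairwise_payoffs(ref_params, *labels) == expected


def test_pairwise_payoffs_are_order_symmetric(ref_params):
    """Listing the players in either order reports the same two payoffs."""
    for ga in (1, 2):
        for ba in (1, 2):
            for gb in (1, 2):
                for bb in (1, 2):
                    ab = gn.pairwise_payoffs(ref_params, ga, ba, gb, bb)
                    ba_ = gn.pairwise_payoffs(ref_params, gb, bb, ga, ba)
                    assert ab == (ba_[1], ba_[0])


def test_accumulate_monomorphic_grid(ref_params):
    state = gn.PopulationState(
        group=np.ones((6, 6), dtype=np.int8),
        behavior=np.ones((6, 6), dtype=np.int8),
    )
    assert (gn.accumulate_payoffs(state, ref_params) == 4 * ref_params.C1).all()


def test_accumulate_isolated_site_against_other_group(ref_params):
    group = np.full((5, 5), 2, dtype=np.int8)
    behavior = np.full((5, 5), 2, dtype=np.int8)
    group[2, 2] = 1
    behavior[2, 2] = 1
    state = gn.PopulationState(group=group, behavior=behavior)
    payoffs = gn.accumulate_payoffs(state, ref_params)
    assert payoffs[2, 2] == 4 * ref_params.B3  # -4


def test_accumulate_matches_per_edge_oracle(rng, ref_params):
    """Vectorized accumulation equals a brute-force loop over all edges."""
    L = 6
    games = gn.SimplifiedGameSet.from_vector([1.5, 2, -1, -0.5, 1, 0.7, 2, 1.1])
    state = gn.PopulationState(
        group=rng.integers(1, 3, size=(L, L)).astype(np.int8),
        behavior=rng.integers(1, 3, size=(L, L)).astype(np.int8),
    )
    expected = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            for di, dj in ((-1, 0), (0, 1), (1, 0), (0, -1)):
                ni, nj = (i + di) % L, (j + dj) % L
                expected[i, j] += gn.pairwise_payoffs(
                    games,
                    state.group[i, j], state.behavior[i, j],
                    state.group[ni, nj], state.behavior[ni, nj],
                )[0]
    assert np.allclose(gn.accumulate_payoffs(state, games), expected)


# --------------------------------------------------------------- imitation

def _state(group, behavior):
    return gn.PopulationState(
        group=np.asarray(group, dtype=np.int8),
        behavior=np.asarray(behavior, dtype=np.int8),
    )


def test_monomorphic_behavior_is_fixed_point(rng, ref_params):
    for value in (1, 2):
        state = _state(rng.integers(1, 3, (8, 8)), np.full((8, 8), value))
        payoffs = gn.accumulate_payoffs(state, ref_params)
        assert (gn.synchronous_update(state, payoffs).behavior == value).all()


def test_update_adopts_strictly_best_neighbor():
    behavior = np.array([[1, 1, 1], [1, 1, 2], [1, 1, 1]], dtype=np.int8)
    payoffs = np.zeros((3, 3))
    payoffs[1, 2] = 5.0  # the east neighbor of the center dominates
    state = _state(np.ones((3, 3)), behavior)
    new = gn.synchronous_update(state, payoffs)
    assert new.behavior[1, 1] == 2


def test_update_keeps_self_when_maximal():
    behavior = np.array([[2, 2, 2], [2, 1, 2], [2, 2, 2]], dtype=np.int8)
    payoffs = np.zeros((3, 3))
    payoffs[1, 1] = 5.0
    new = gn.synchronous_update(_state(np.ones((3, 3)), behavior), payoffs)
    assert new.behavior[1, 1] == 1


def test_update_tie_prefers_self_then_fixed_neighbor_order(rng):
    # all payoffs equal: everyone keeps their behavior
    behavior = rng.integers(1, 3, (5, 5)).astype(np.int8)
    state = _state(np.ones((5, 5)), behavior)
    new = gn.synchronous_update(state, np.zeros((5, 5)))
    assert np.array_equal(new.behavior, behavior)
    # north and east neighbors tie strictly above self: north (first in
    # N, E, S, W order) wins, so the center adopts north's behavior 2 and
    # not east's behavior 1
    behavior = np.array([[1, 2, 1], [1, 1, 1], [1, 1, 1]], dtype=np.int8)
    payoffs = np.zeros((3, 3))
    payoffs[0, 1] = 3.0  # north of center
    payoffs[1, 2] = 3.0  # east of center
    new = gn.synchronous_update(_state(np.ones((3, 3)), behavior), payoffs)
    assert new.behavior[1, 1] == 2  # north's behavior


# -------------------------------------------------------------------- runs

def test_run_monomorphic_init_converges_at_step_zero(ref_params):
    cfg = gn.LatticeConfig(L=10, f=0.5, init_behavior1_prob=0.0, seed=0)
    traj = gn.run(cfg, ref_params)
    assert traj.converged and traj.converged_at == 0
    assert traj.steady_rho1 == 0.0
    assert traj.cycle_period == 1


def test_run_is_deterministic(ref_params):
    cfg = gn.LatticeConfig(L=30, f=0.4, seed=11)
    a = gn.run(cfg, ref_params)
    b = gn.run(cfg, ref_params)
    assert np.array_equal(a.rho1, b.rho1)
    assert a.converged_at == b.converged_at
    assert a.steady_rho1 == b.steady_rho1


def test_run_conserves_group_grid(ref_params):
    cfg = gn.LatticeConfig(L=20, f=0.3, seed=5)
    init = gn.initialize_population(cfg)
    traj = gn.run(cfg, ref_params, initial_state=init)
    assert np.array_equal(traj.final_state.group, init.group)
    assert not traj.final_state.group.flags.writeable


def test_run_weighted_group_fraction_identity(ref_params):
    traj = gn.run(gn.LatticeConfig(L=20, f=0.3, seed=9), ref_params)
    w = traj.group1_fraction
    recombined = w * traj.rho1_g1 + (1 - w) * traj.rho1_g2
    assert np.allclose(traj.rho1, recombined, atol=1e-12)


def test_mirror_symmetry_of_full_trajectories():
    """Label-swapping groups, behaviors and parameters mirrors the run exactly."""
    games = gn.SimplifiedGameSet.from_vector([2, 1, -1, -2, 1, 0.5, 2, 1.5])
    cfg = gn.LatticeConfig(L=40, f=0.3, seed=7)
    init = gn.initialize_population(cfg)
    fwd = gn.run(cfg, games, initial_state=init)
    rev = gn.run(cfg, games.swapped(), initial_state=gn.swapped_initial_state(init))
    n = min(len(fwd.rho1), len(rev.rho1))
    assert np.max(np.abs(rev.rho1[:n] - (1 - fwd.rho1[:n]))) <= 1e-12
    assert np.array_equal(rev.final_state.behavior, 3 - fwd.final_state.behavior)
    assert np.array_equal(rev.final_state.group, 3 - fwd.final_state.group)


def test_run_nonconvergence_is_flagged(ref_params):
    spec = gn.ConvergenceSpec(fluct_tol=1e-9, window=50, average_window=50,
                              max_steps=60)
    traj = gn.run(gn.LatticeConfig(L=30, f=0.5, seed=2), ref_params, spec)
    if not traj.converged:
        assert traj.converged_at is None
        assert 0.0 <= traj.steady_rho1 <= 1.0
    else:
        # an exact fixed point or zero-amplitude cycle within 60 steps also
        # satisfies a 1e-9 tolerance
        assert traj.cycle_period in (1, 2)
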