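# Methods

## Model

The population occupies an L×L square lattice (default L = 100) with
periodic boundaries. Site labels are drawn i.i.d. at initialization: group 1
with probability f, behavior 1 with probability `init_behavior1_prob`
(default 0.5). Group labels are immutable for the entire run — the groups
are fixed social units, not strategies — and the arrays enforce this
(read-only group grid, checked by tests). Because initialization is
Bernoulli rather than exact-count shuffling, the realized group fraction
fluctuates around f by a binomial standard error (~0.005 at L = 100); it is
reported alongside the nominal f in every trajectory.

Each round, a player accumulates payoff from four 2×2 games against its von
Neumann neighbors; payoffs reset every round. The matrix is selected by the
group pair: within-group-1, within-group-2, or the between-group matrix with
the group-1 member always on the row axis. All players then update
synchronously, adopting the behavior of the highest-total-payoff member of
the candidate set {self, N, E, S, W}.

Two deliberate conventions make the update a pure function of the state:

* **Self-inclusion.** A player keeps its behavior whenever it is itself
  (weakly) maximal. Excluding self would force strictly-best players to
  switch to a worse neighbor's behavior, destroying the stable monomorphic
  configurations the model is built to study; include-self is the standard
  unconditional-imitation convention.
* **Deterministic tie-breaking.** Ties prefer self; among tied neighbors the
  fixed order N, E, S, W decides (implemented as first-occurrence argmax
  over the stacked candidates). The dynamics therefore contain no randomness
  beyond the initial draw, and a seed fully determines a run.

## Game algebra

`simplify_within` / `simplify_between` map raw bimatrices to the canonical
(B, C) forms by subtracting, from each player's payoffs, a constant that
depends only on the opponent's choice (within-group: C = r − t, B = s − p;
between-group: C = R − T, B = S − P per side). Such shifts leave every
best-response difference untouched, so the pure Nash set is exactly
preserved — a property test checks this against exhaustive enumeration on
thousands of random games.

`enumerate_pure_nash` checks all four profiles with weak best responses
(ties count as equilibria). The taxonomy `classify_dilemma` uses strict
signs only; B = 0 or C = 0 raises a degenerate-game error rather than
silently picking a side, since the class boundaries are measure-zero and
carry no stable interpretation. Note the sign convention is tied to the
within-group table orientation; for the between-group game read in each
player's preference frame the roles of B and C swap, which is why the
between-group snowdrift regime is C > 0 > B.

The cohesion ratio is computed two ways and cross-checked: the general
definition sums the group-1 player's payoffs over the pure equilibria of
games 1 and 2 and divides by the group-2 player's sum over games 3 and 2;
the closed form (C₃ + C₁)/(C₄ + C₂) is valid in the harmony/snowdrift
regime, where the equilibrium sets are {(1,1)}, {(1,1),(2,2)} and {(2,2)}.
Only pure equilibria enter the definition: the closed form follows from the
general one exactly when mixed equilibria are excluded, and the two paths
agree to 1e−12 on random parameter sets in the regime.

## Convergence protocol

A run is converged once the per-step fluctuation |ρ₁(t) − ρ₁(t−1)| stays
below `fluct_tol` = 0.01 for `window` = 500 consecutive steps; the steady
state is the mean of ρ₁ over the `average_window` = 500 steps *following*
the detection step. "Fluctuation" is operationalized as the per-step
absolute difference — the simplest reading; deviation-from-window-mean was
the considered alternative and would only be stricter. A `max_steps` cap
(default 20 000) flags non-convergence instead of hanging; a non-converged
run reports the mean over its last `average_window` steps with
`converged = False`.

Because the update is deterministic, trajectories typically lock into an
exact fixed point or 2-cycle within tens of steps. `run()` detects this by
state equality and continues the ρ₁ series analytically (constant or
alternating), which is exact and avoids simulating hundreds of identical
rounds. For locked runs `converged_at` is the lock-in step (a monomorphic
initial state converges at step 0); for runs that satisfy the fluctuation
criterion without exact locking it is the criterion's firing step.
`detect_convergence` on a raw series always uses the strict trailing-window
definition (a constant series converges at step = window).

`stabilization_step` is a separate diagnostic: the first step after which
every subsequent per-step change stays below the tolerance. At f = 0.5 the
population fraction barely moves (site flips in both directions cancel), so
the median stabilization step over replicates is very small; at extreme f
the fraction travels far but still settles within a few tens of steps.

## Experiments

Default study conditions: L = 100, the 0.01/500-step protocol, and 10
independent replicates per grid point with recorded seeds seed0 + k.
The three designs are a sweep of f ∈ {0.1, …, 0.9} at equal cohesion
(q = 1), a sweep of q ∈ {1/9, 1/3, 1, 3, 9} at f = 0.5, and the full f×q
factorial. The q sweep holds [B₁, B₂, B₃, B₄, C₁, C₃] = [2, 2, −1, −1, 1, 2]
fixed and rescales only the group-2 stakes, C₂ = C₁/q and C₄ = C₃/q, so q is
realized exactly while both game types are preserved for every q > 0. Six
benchmark parameter sets share q = 1 with different payoff magnitudes and
are used to check robustness of the f-dependence.

Snapshots encode (group, behavior) as four states — behavior 1/2 in group 1,
behavior 1/2 in group 2 — exported as blue/yellow/green/red PNGs with a
plain-text integer sidecar; step indices count completed update rounds
(step 0 is the initial state).

## What the generator does and does not emulate

The initial condition is the model's own specification (i.i.d. labels), not
a stand-in for empirical data, so the simulations *are* the study system.
What passing tests consequently do not show: anything about populations with
spatially correlated group membership (households, clustered crowds),
more than two groups or behaviors, asynchronous or noisy updating, or
mobility. The monotonicity and corner results are statements about this
lattice model under deterministic imitation, not about real crowds.

## Numerical choices and limitations

* Steady-state means, fractions and payoffs are double precision; mirror
  symmetry (label-swapped initial grids plus swapped parameters give
  ρ₁′(t) = 1 − ρ₁(t)) is exact at the behavior-grid level and holds to one
  ulp (≤ 1e−12) in the recorded fractions, the rounding of k/n vs 1 − k/n.
* The monotonicity checks use one-sided Spearman tests (the claims are
  directional); on the 5-point q grid a perfect monotone ranking has exact
  one-sided p = 1/120 ≈ 0.008.
* Cycle detection covers periods 1 and 2 only; longer cycles (rare) fall
  through to the fluctuation criterion or the max-steps cap.
* Problem sizes in the test suite: game-algebra property suites run 1000
  random draws; full-lattice tests use L = 100 with 10 replicates for the
  headline claims and L = 30–50 for structural properties, sizes at which
  each deterministic run locks in within ~10–1000 rounds.
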