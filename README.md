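# groupnorms

Agent-based model of how a behavioral norm emerges in a population made of
two "small groups" with heterogeneous game preferences.

## The model

A population lives on an L×L square lattice with periodic boundaries. Each
site holds one player with two labels: an immutable **group** (small group 1
with probability *f*, otherwise small group 2) and a mutable **behavior**
(1 or 2). Group *k* prefers behavior *k*.

Pairwise interactions are 2×2 bimatrix games that depend on the group pair.
After *equivalent simplification* — subtracting an opponent-choice-dependent
constant from each player's payoffs, which preserves best responses and
hence Nash equilibria — the three games are parameterised by eight numbers
[B₁, B₂, B₃, B₄, C₁, C₂, C₃, C₄]:

|  within group 1 | b1 | b2 | | between (row = grp 1) | b1 | b2 | | within group 2 | b1 | b2 |
|---|---|---|---|---|---|---|---|---|---|---|
| **b1** | (C₁,C₁) | (B₁,0) | | **b1** | (C₃,0) | (B₃,B₄) | | **b1** | (0,0) | (0,B₂) |
| **b2** | (0,B₁) | (0,0)  | | **b2** | (0,0)  | (0,C₄)  | | **b2** | (B₂,0) | (C₂,C₂) |

The signs of (B, C) place each game in the standard taxonomy (prisoner's
dilemma, harmony, snowdrift, stag hunt). The working regime is a **harmony
game inside each group** (B₁, B₂, C₁, C₂ > 0 — members prefer to match
their group's behavior) and a **snowdrift game between groups**
(B₃, B₄ < 0 < C₃, C₄).

Each round every player accumulates payoff from games against its four von
Neumann neighbors, then all players simultaneously adopt the behavior of the
highest-payoff member of {self, N, E, S, W} (deterministic unconditional
imitation; ties prefer self, then the fixed neighbor order).

The **cohesion ratio** *q* compares how much each group stands to lose by
deviating from its internal equilibrium:

q = [Σ u₁ over pure NE of games 1, 2] / [Σ u₂ over pure NE of games 3, 2],

which in the harmony/snowdrift regime reduces to the closed form
**q = (C₃ + C₁) / (C₄ + C₂)**. The model's central result is that the
steady-state fraction of behavior 1 rises monotonically with both *f* (group
size) and *q* (relative cohesion): a minority group can still set the
population norm if its cohesion is large enough.

## Worked example

Classify the games and compute q for the parameter set
[2, 2, −1, −1, 1, 1/9, 2, 2/9] (group 1 nine times as cohesive):

```
$ groupnorms analyze-game --params "2,2,-1,-1,1,1/9,2,2/9"
within group 1:
  dilemma class: harmony (B=2, C=1)
  pure NE (1, 1): payoffs (1, 1)
between groups (row = group 1):
  group-1 side dilemma class: snowdrift (B=-1, C=2)
  group-2 side dilemma class: snowdrift (B=-1, C=0.222222)
  pure NE (1, 1): payoffs (2, 0)
  pure NE (2, 2): payoffs (0, 0.222222)
within group 2:
  dilemma class: harmony (B=2, C=0.111111)
  pure NE (2, 2): payoffs (0.111111, 0.111111)
q (Nash enumeration): 9
q (closed form):      9
```

Both groups play internal harmony games whose unique equilibria are mutual
play of the preferred behavior; the between-group game is a snowdrift with
two pure equilibria. The Nash-enumeration and closed-form paths agree:
q = (2 + 1) / (2/9 + 1/9) = 9.

Simulate one run at equal cohesion (q = 1) with group 1 in the 20% minority:

```
$ groupnorms run -L 100 --f 0.2 --seed 1 --out ts.csv
run converged at step 8; steady rho1 = 0.0491 (realized f = 0.1999); wrote ts.csv
```

The deterministic dynamics lock in after 8 rounds; behavior 1 collapses to a
few percent — the majority group's preference becomes the norm. Other entry
points: `groupnorms sweep-f`, `sweep-q`, `heatmap` (the f×q surface) and
`snapshots` (4-color lattice images: blue/yellow = behavior 1/2 in group 1,
green/red = behavior 1/2 in group 2).

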