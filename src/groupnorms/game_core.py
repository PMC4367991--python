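"""Exact algebra for the 2x2 games played within and between two small groups.

The population is split into two fixed-membership "small groups"; group *k*
prefers behavior *k*.  Pairwise interactions are 2x2 bimatrix games: one
inside each group and one between groups.  Subtracting an opponent-choice-
dependent constant from a player's payoffs ("equivalent simplification")
leaves every best-response comparison -- and hence the pure Nash set --
unchanged, and brings the three games to canonical forms parameterised by
eight numbers::

      within group 1            between groups           within group 2
         b1       b2              b1        b2              b1       b2
   b1  (C1,C1)  (B1,0)      b1  (C3,0)   (B3,B4)      b1  (0,0)   (0,B2)
   b2  (0,B1)   (0,0)       b2  (0,0)    (0,C4)       b2  (B2,0)  (C2,C2)

The row player of the between-group game is always the group-1 member.  The
signs of (B, C) place each simplified game in the standard two-strategy
taxonomy (prisoner's dilemma, harmony, snowdrift, stag hunt), and the
cohesion ratio q compares the two groups' equilibrium stakes: the group with
more to lose by deviating from its internal equilibrium holds together more
strongly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Mapping, Sequence, Tuple

Profile = Tuple[int, int]

BEHAVIORS = (1, 2)
#: All four pure-strategy profiles of a 2x2 game, row-major.
PROFILES: Tuple[Profile, ...] = ((1, 1), (1, 2), (2, 1), (2, 2))


class StructureError(ValueError):
    """Raised when a raw bimatrix does not have the required structure."""


class DegenerateGameError(ValueError):
    """Raised when a game sits on a taxonomy boundary (B = 0 or C = 0)."""


class UndefinedCohesionError(ValueError):
    """Raised when the cohesion ratio q has a zero denominator."""


class DilemmaClass(str, Enum):
    """Two-strategy dilemma taxonomy by the signs of the simplified (B, C)."""

    PRISONERS_DILEMMA = "prisoners_dilemma"  # B < 0, C < 0: all-defect
    HARMONY = "harmony"                      # B > 0, C > 0: all-cooperate
    SNOWDRIFT = "snowdrift"                  # B > 0, C < 0: anti-coordination
    STAG_HUNT = "stag_hunt"                  # B < 0, C > 0: bistable coordination


@dataclass(frozen=True)
class RawBimatrix:
    """A 2x2 bimatrix game.

    ``_flat`` stores ``(u_row, u_col)`` for the profiles in :data:`PROFILES`
    order.  Use :meth:`from_profiles` or the structured constructors.
    """

    _flat: Tuple[float, ...]

    @classmethod
    def from_profiles(
        cls, payoffs: Mapping[Profile, Tuple[float, float]]
    ) -> "RawBimatrix":
        if set(payoffs) != set(PROFILES):
            raise StructureError(
                f"need payoffs for exactly the profiles {PROFILES}, got {sorted(payoffs)}"
            )
        flat = []
        for prof in PROFILES:
            u_row, u_col = payoffs[prof]
            for u in (u_row, u_col):
                u = float(u)
                if not math.isfinite(u):
                    raise StructureError(f"non-finite payoff {u!r} at profile {prof}")
                flat.append(u)
        return cls(tuple(flat))

    @classmethod
    def within(cls, r: float, s: float, t: float, p: float) -> "RawBimatrix":
        """Symmetric within-group game [(r,r),(s,t);(t,s),(p,p)]."""
        return cls.from_profiles(
            {(1, 1): (r, r), (1, 2): (s, t), (2, 1): (t, s), (2, 2): (p, p)}
        )

    @classmethod
    def between(
        cls,
        R1: float, S1: float, T1: float, P1: float,
        P2: float, S2: float, T2: float, R2: float,
    ) -> "RawBimatrix":
        """Between-group game [(R1,P2),(S1,S2);(T1,T2),(P1,R2)], row = group 1."""
        return cls.from_profiles(
            {(1, 1): (R1, P2), (1, 2): (S1, S2), (2, 1): (T1, T2), (2, 2): (P1, R2)}
        )

    def payoff(self, row_behavior: int, col_behavior: int) -> Tuple[float, float]:
        """Return ``(row_payoff, col_payoff)`` at a pure profile."""
        i = PROFILES.index((row_behavior, col_behavior))
        return self._flat[2 * i], self._flat[2 * i + 1]

    def profiles(self) -> Iterator[Tuple[Profile, Tuple[float, float]]]:
        for i, prof in enumerate(PROFILES):
            yield prof, (self._flat[2 * i], self._flat[2 * i + 1])


@dataclass(frozen=True)
class NashSet:
    """The pure-strategy Nash equilibria of a 2x2 bimatrix.

    ``profiles`` and ``payoffs`` are aligned; payoffs are the full
    ``(row_payoff, col_payoff)`` pair at each equilibrium profile.
    """

    profiles: Tuple[Profile, ...]
    payoffs: Tuple[Tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.profiles)

    def __contains__(self, profile: Profile) -> bool:
        return profile in self.profiles

    def payoff(self, profile: Profile) -> Tuple[float, float]:
        return self.payoffs[self.profiles.index(profile)]

    def row_payoff_sum(self) -> float:
        return sum(u for u, _ in self.payoffs)

    def col_payoff_sum(self) -> float:
        return sum(u for _, u in self.payoffs)


def enumerate_pure_nash(game: RawBimatrix) -> NashSet:
    """Enumerate pure Nash equilibria by exhaustive mutual-best-response check.

    A profile is an equilibrium when neither player can *strictly* gain by a
    unilateral deviation (weak best response: payoff ties count).
    """
    profiles = []
    payoffs = []
    for (rb, cb), (u_row, u_col) in game.profiles():
        alt_row = game.payoff(3 - rb, cb)[0]
        alt_col = game.payoff(rb, 3 - cb)[1]
        if u_row >= alt_row and u_col >= alt_col:
            profiles.append((rb, cb))
            payoffs.append((u_row, u_col))
    return NashSet(tuple(profiles), tuple(payoffs))


def simplify_within(
    game: RawBimatrix, preferred_behavior: int = 1
) -> Tuple[float, float]:
    """Simplify a symmetric within-group game to its canonical ``(B, C)``.

    For ``preferred_behavior=1`` the game must have the structure
    ``[(r,r),(s,t);(t,s),(p,p)]`` and the result is ``B = s - p``,
    ``C = r - t``; the canonical matrix is then the within-group-1 form.
    ``preferred_behavior=2`` reads the mirrored structure (group-2 form,
    ``(r,r)`` on the behavior-2 diagonal).  Because the transform only
    subtracts opponent-choice-dependent constants, the pure Nash set is
    unchanged.
    """
    if preferred_behavior not in BEHAVIORS:
        raise ValueError("preferred_behavior must be 1 or 2")
    u11 = game.payoff(1, 1)
    u12 = game.payoff(1, 2)
    u21 = game.payoff(2, 1)
    u22 = game.payoff(2, 2)
    symmetric = (
        u11[0] == u11[1]
        and u22[0] == u22[1]
        and u12[0] == u21[1]
        and u12[1] == u21[0]
    )
    if not symmetric:
        raise StructureError("game is not a symmetric within-group bimatrix")
    if preferred_behavior == 1:
        r, s, t, p = u11[0], u12[0], u21[0], u22[0]
    else:
        r, s, t, p = u22[0], u21[0], u12[0], u11[0]
    return (s - p, r - t)


def simplify_between(game: RawBimatrix) -> Tuple[float, float, float, float]:
    """Simplify a between-group game (row = group-1 member) to (B3, C3, B4, C4).

    With the raw structure ``[(R1,P2),(S1,S2);(T1,T2),(P1,R2)]`` the result is
    ``B3 = S1 - P1, C3 = R1 - T1`` for the group-1 (row) player and
    ``B4 = S2 - P2, C4 = R2 - T2`` for the group-2 (column) player; the
    canonical matrix is the between-group form and the pure Nash set is
    preserved.
    """
    R1, P2 = game.payoff(1, 1)
    S1, S2 = game.payoff(1, 2)
    T1, T2 = game.payoff(2, 1)
    P1, R2 = game.payoff(2, 2)
    return (S1 - P1, R1 - T1, S2 - P2, R2 - T2)


@dataclass(frozen=True)
class SimplifiedGameSet:
    """The eight payoff differences defining the three canonical games."""

    B1: float
    B2: float
    B3: float
    B4: float
    C1: float
    C2: float
    C3: float
    C4: float

    def __post_init__(self) -> None:
        for name in ("B1", "B2", "B3", "B4", "C1", "C2", "C3", "C4"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "SimplifiedGameSet":
        """Build from the conventional order [B1, B2, B3, B4, C1, C2, C3, C4]."""
        if len(vec) != 8:
            raise ValueError(f"need 8 parameters, got {len(vec)}")
        return cls(*(float(v) for v in vec))

    def to_vector(self) -> Tuple[float, ...]:
        return (self.B1, self.B2, self.B3, self.B4,
                self.C1, self.C2, self.C3, self.C4)

    def within_group1(self) -> RawBimatrix:
        return RawBimatrix.from_profiles({
            (1, 1): (self.C1, self.C1),
            (1, 2): (self.B1, 0.0),
            (2, 1): (0.0, self.B1),
            (2, 2): (0.0, 0.0),
        })

    def between(self) -> RawBimatrix:
        """Between-group game; the row player is the group-1 member."""
        return RawBimatrix.from_profiles({
            (1, 1): (self.C3, 0.0),
            (1, 2): (self.B3, self.B4),
            (2, 1): (0.0, 0.0),
            (2, 2): (0.0, self.C4),
        })

    def within_group2(self) -> RawBimatrix:
        return RawBimatrix.from_profiles({
            (1, 1): (0.0, 0.0),
            (1, 2): (0.0, self.B2),
            (2, 1): (self.B2, 0.0),
            (2, 2): (self.C2, self.C2),
        })

    def swapped(self) -> "SimplifiedGameSet":
        """Exchange the roles of the two groups (B1<->B2, C1<->C2, B3<->B4, C3<->C4)."""
        return SimplifiedGameSet(
            B1=self.B2, B2=self.B1, B3=self.B4, B4=self.B3,
            C1=self.C2, C2=self.C1, C3=self.C4, C4=self.C3,
        )


def classify_dilemma(B: float, C: float) -> DilemmaClass:
    """Classify a simplified within-group game by the signs of (B, C).

    The taxonomy is defined for strict signs only; a boundary game raises
    :class:`DegenerateGameError`.
    """
    if B == 0 or C == 0:
        raise DegenerateGameError(
            f"taxonomy undefined on the boundary B={B}, C={C}"
        )
    if B > 0 and C > 0:
        return DilemmaClass.HARMONY
    if B < 0 and C < 0:
        return DilemmaClass.PRISONERS_DILEMMA
    if B > 0:
        return DilemmaClass.SNOWDRIFT
    return DilemmaClass.STAG_HUNT


def compute_q_general(games: SimplifiedGameSet) -> float:
    """Cohesion of group 1 relative to group 2 from pure Nash payoffs.

    Sums the group-1 player's payoffs over the pure equilibria of the
    within-group-1 and between-group games, divided by the group-2 player's
    payoff sum over the within-group-2 and between-group games.  q > 1 means
    group 1 is the more cohesive; q = 1 means equal cohesion.
    """
    ne_within1 = enumerate_pure_nash(games.within_group1())
    ne_between = enumerate_pure_nash(games.between())
    ne_within2 = enumerate_pure_nash(games.within_group2())
    numerator = ne_within1.row_payoff_sum() + ne_between.row_payoff_sum()
    denominator = ne_within2.col_payoff_sum() + ne_between.col_payoff_sum()
    if denominator == 0:
        raise UndefinedCohesionError("cohesion ratio undefined: denominator is 0")
    return numerator / denominator


def compute_q_closed(C1: float, C2: float, C3: float, C4: float) -> float:
    """Closed-form cohesion ratio q = (C3 + C1) / (C4 + C2).

    Valid in the regime of harmony games within groups (B1, B2, C1, C2 > 0)
    and a snowdrift game between groups (B3, B4 < 0; C3, C4 > 0), where the
    pure equilibria contribute exactly C1, C3 to group 1 and C2, C4 to
    group 2.
    """
    denominator = C4 + C2
    if denominator == 0:
        raise UndefinedCohesionError("cohesion ratio undefined: C4 + C2 = 0")
    return (C3 + C1) / denominator
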