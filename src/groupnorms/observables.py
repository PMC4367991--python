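"""Summary statistics, convergence detection and stabilization diagnostics.

The simulation's order parameter is the population fraction of behavior 1,
rho1(t).  A run is declared converged once the per-step fluctuation
|rho1(t) - rho1(t-1)| stays below a tolerance for a full window of
consecutive steps; the reported steady state is the mean over a second
window that follows the detection step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


class SeriesTooShortError(ValueError):
    """The series does not extend far enough past convergence: extend the run."""


@dataclass(frozen=True)
class ConvergenceSpec:
    """Convergence-and-averaging protocol.

    fluct_tol
        Per-step fluctuation threshold on rho1 (default 0.01).
    window
        Number of consecutive sub-threshold steps required (default 500).
    average_window
        Number of steps averaged after the detection step (default 500).
    max_steps
        Hard cap on simulated rounds; exceeding it flags non-convergence.
    """

    fluct_tol: float = 0.01
    window: int = 500
    average_window: int = 500
    max_steps: int = 20000

    def __post_init__(self) -> None:
        if self.fluct_tol <= 0:
            raise ValueError("fluct_tol must be positive")
        for name in ("window", "average_window", "max_steps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Trajectory:
    """Time course of one run.

    ``rho1[t]`` is the population behavior-1 fraction after t update rounds
    (index 0 is the initial state); ``rho1_g1``/``rho1_g2`` are the same
    fraction within each group.  These satisfy the exact identity
    ``rho1 = w * rho1_g1 + (1 - w) * rho1_g2`` with ``w`` the realized
    group-1 fraction.

    ``converged_at`` is the step at which the convergence protocol fired (or
    the step the dynamics locked into an exact fixed point / 2-cycle, in
    which case the protocol is guaranteed to fire and the tail of the series
    is extended analytically; ``n_simulated_steps`` counts the rounds that
    were actually simulated).  ``steady_rho1`` is the post-convergence
    average; for a non-converged run it falls back to the mean over the last
    ``average_window`` recorded steps and ``converged`` is False.
    """

    rho1: np.ndarray
    rho1_g1: np.ndarray
    rho1_g2: np.ndarray
    group1_fraction: float
    converged_at: Optional[int]
    converged: bool
    steady_rho1: float
    cycle_period: Optional[int]
    n_simulated_steps: int
    final_state: object


def fraction_behavior1(state) -> float:
    """Population fraction of sites playing behavior 1.

    Accepts a population state (anything with a ``behavior`` grid) or a bare
    behavior array.
    """
    behavior = np.asarray(getattr(state, "behavior", state))
    return float((behavior == 1).mean())


def detect_convergence(rho1, spec: Optional[ConvergenceSpec] = None) -> Optional[int]:
    """First step t whose trailing window of per-step fluctuations is small.

    Returns the smallest t such that |rho1(s) - rho1(s-1)| < ``fluct_tol``
    for every s in (t - window, t], or None if no such t exists within
    ``max_steps``.
    """
    spec = spec if spec is not None else ConvergenceSpec()
    r = np.asarray(rho1, dtype=float)
    small = np.abs(np.diff(r)) < spec.fluct_tol
    consecutive = 0
    for s, ok in enumerate(small, start=1):
        consecutive = consecutive + 1 if ok else 0
        if consecutive >= spec.window:
            if s > spec.max_steps:
                return None
            return s
    return None


def steady_state_average(
    rho1, converged_at: int, spec: Optional[ConvergenceSpec] = None
) -> float:
    """Mean of rho1 over the ``average_window`` steps following convergence."""
    spec = spec if spec is not None else ConvergenceSpec()
    if converged_at is None:
        raise ValueError("converged_at is not set; run did not converge")
    r = np.asarray(rho1, dtype=float)
    end = converged_at + spec.average_window
    if len(r) <= end:
        raise SeriesTooShortError(
            f"need the series through step {end}, have {len(r) - 1}: extend the run"
        )
    return float(r[converged_at + 1 : end + 1].mean())


def stabilization_step(rho1, tol: float = 0.01) -> int:
    """First step after which every per-step change stays below ``tol``.

    Returns 0 for a series that never fluctuates by ``tol`` or more; note the
    answer is relative to the end of the given series.
    """
    d = np.abs(np.diff(np.asarray(rho1, dtype=float)))
    big = np.nonzero(d >= tol)[0]
    return int(big[-1] + 1) if big.size else 0
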