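"""Plain-text run configuration (``key = value``) with validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Tuple, Union

from .game_core import SimplifiedGameSet
from .lattice import LatticeConfig
from .observables import ConvergenceSpec


class ConfigFileError(ValueError):
    """Malformed or out-of-range configuration."""


def parse_number(token: str) -> float:
    """Parse a float, accepting simple fractions such as ``1/9``."""
    token = token.strip()
    if "/" in token:
        num, den = token.split("/", 1)
        return float(num) / float(den)
    return float(token)


def parse_vector(text: str, n: int) -> Tuple[float, ...]:
    parts = [p for p in text.replace(";", ",").split(",") if p.strip()]
    if len(parts) != n:
        raise ConfigFileError(f"expected {n} comma-separated numbers, got {len(parts)}")
    return tuple(parse_number(p) for p in parts)


_INT_KEYS = {"L", "seed", "window", "average_window", "max_steps", "n_reps"}
_FLOAT_KEYS = {"f", "init_behavior1_prob", "fluct_tol"}


@dataclass
class RunSettings:
    """Full configuration of one simulation experiment, with defaults.

    Defaults are the standard study conditions: a 100x100 lattice, the
    benchmark payoff vector, the 0.01/500-step convergence protocol and 10
    replicates.
    """

    L: int = 100
    f: float = 0.5
    init_behavior1_prob: float = 0.5
    seed: int = 0
    params: Tuple[float, ...] = (2.0, 2.0, -1.0, -1.0, 1.0, 1.0, 2.0, 2.0)
    fluct_tol: float = 0.01
    window: int = 500
    average_window: int = 500
    max_steps: int = 20000
    n_reps: int = 10

    def validate(self) -> "RunSettings":
        if self.L < 2:
            raise ConfigFileError(f"L must be >= 2, got {self.L}")
        if not 0.0 <= self.f <= 1.0:
            raise ConfigFileError(f"f must lie in [0, 1], got {self.f}")
        if not 0.0 <= self.init_behavior1_prob <= 1.0:
            raise ConfigFileError(
                f"init_behavior1_prob must lie in [0, 1], got {self.init_behavior1_prob}"
            )
        if len(self.params) != 8:
            raise ConfigFileError("params must have 8 entries [B1,B2,B3,B4,C1,C2,C3,C4]")
        self.params = tuple(float(v) for v in self.params)
        if self.fluct_tol <= 0:
            raise ConfigFileError("fluct_tol must be positive")
        for name in ("window", "average_window", "max_steps", "n_reps"):
            if getattr(self, name) < 1:
                raise ConfigFileError(f"{name} must be >= 1")
        if self.seed < 0:
            raise ConfigFileError("seed must be non-negative")
        return self

    # ---- adapters ----------------------------------------------------
    def lattice_config(self) -> LatticeConfig:
        return LatticeConfig(
            L=self.L, f=self.f,
            init_behavior1_prob=self.init_behavior1_prob, seed=self.seed,
        )

    def games(self) -> SimplifiedGameSet:
        return SimplifiedGameSet.from_vector(self.params)

    def convergence_spec(self) -> ConvergenceSpec:
        return ConvergenceSpec(
            fluct_tol=self.fluct_tol, window=self.window,
            average_window=self.average_window, max_steps=self.max_steps,
        )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def parse_config(text: str) -> RunSettings:
    settings = RunSettings()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigFileError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        try:
            if key in _INT_KEYS:
                setattr(settings, key, int(value))
            elif key in _FLOAT_KEYS:
                setattr(settings, key, parse_number(value))
            elif key == "params":
                settings.params = parse_vector(value, 8)
            else:
                raise ConfigFileError(f"line {lineno}: unknown key {key!r}")
        except ConfigFileError:
            raise
        except ValueError as exc:
            raise ConfigFileError(f"line {lineno}: bad value for {key!r}: {exc}") from exc
    return settings.validate()


def load_config(path: Union[str, Path]) -> RunSettings:
    """Read and validate a ``key = value`` configuration file."""
    return parse_config(Path(path).read_text())


def save_config(settings: RunSettings, path: Union[str, Path]) -> None:
    """Write a configuration that :func:`load_config` reads back identically."""
    lines = []
    for f in fields(settings):
        value = getattr(settings, f.name)
        if f.name == "params":
            value = ",".join(repr(v) for v in value)
        lines.append(f"{f.name} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")
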