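import numpy as np
import pytest

import groupnorms as gn


@pytest.fixture(scope="session")
def ref_params() -> gn.SimplifiedGameSet:
    """Benchmark parameter set: harmony within, snowdrift between, q = 1."""
    return gn.REFERENCE_PARAMS


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250920)


def random_within_raw(rng: np.random.Generator) -> gn.RawBimatrix:
    r, s, t, p = rng.uniform(-10, 10, size=4)
    return gn.RawBimatrix.within(r, s, t, p)


def random_between_raw(rng: np.random.Generator) -> gn.RawBimatrix:
    vals = rng.uniform(-10, 10, size=8)
    return gn.RawBimatrix.between(*vals)


def nash_profiles(game: gn.RawBimatrix) -> set:
    return set(gn.enumerate_pure_nash(game).profiles)
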