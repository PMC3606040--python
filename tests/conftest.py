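import numpy as np
import pytest

from solvscale.reflection_model import ReflectionSet, UnitCell


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cubic_cell():
    return UnitCell(10.0, 10.0, 10.0)


def make_reflections(n, cell=None, symbol="P 1", seed=0, hmax=12):
    """Random unique Miller indices on a cell, excluding (0,0,0)."""
    rng = np.random.default_rng(seed)
    cell = cell or UnitCell(20.0, 25.0, 30.0, 85.0, 95.0, 100.0)
    seen = set()
    while len(seen) < n:
        hkl = tuple(int(x) for x in rng.integers(-hmax, hmax + 1, 3))
        if hkl != (0, 0, 0):
            seen.add(hkl)
    return ReflectionSet.from_symbol(np.array(sorted(seen)), cell, symbol)


def random_bin(rng, n=50, k_mask=0.35, noise=0.0):
    """A synthetic bin: complex F_calc/F_mask and F_obs = |F_calc + k·F_mask|."""
    f_calc = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    f_mask = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    f_obs = np.abs(f_calc + k_mask * f_mask)
    if noise:
        f_obs = f_obs * (1.0 + noise * rng.standard_normal(n))
    return f_obs, f_calc, f_mask
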