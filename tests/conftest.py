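import numpy as np
import pytest

import rnoecest as rc


@pytest.fixture(scope="session")
def invivo_grid():
    return rc.invivo_offsets()


@pytest.fixture(scope="session")
def water_mt_pools():
    return (rc.PoolSpec(0.0, 0.80, 1.4, "water"),
            rc.PoolSpec(-2.0, 0.08, 25.0, "mt"))


@pytest.fixture(scope="session")
def six_pools():
    return rc.DEFAULT_POOLS


@pytest.fixture(scope="session")
def small_phantom():
    """16x16 two-region phantom with mild noise, shared across tests."""
    spec = rc.default_phantom_spec(shape=(16, 16), noise_sd=0.001, seed=42)
    return spec, rc.simulate_phantom(spec)


def lorentzian_sum_oracle(pools, offsets):
    """Independent brute-force per-offset evaluation of the pool model."""
    out = []
    for dw in np.asarray(offsets, float):
        z = 1.0
        for p in pools:
            half = p.fwhm / 2.0
            z -= p.amplitude * half**2 / (half**2 + (dw - p.center) ** 2)
        out.append(z)
    return np.array(out)
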