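import numpy as np
import pytest

from rcnoise import CircuitParams, ResourceMode, gillespie_run


@pytest.fixture(scope="session")
def defaults() -> CircuitParams:
    return CircuitParams()


@pytest.fixture(scope="session")
def unlimited_long_run(defaults):
    """One long unlimited-mode trajectory, shared across analytic cross-checks."""
    return gillespie_run(defaults, ResourceMode.UNLIMITED, t_end=20000.0, seed=3)


@pytest.fixture(scope="session")
def bistable_run(defaults):
    """Shared-mode run inside the bistable window (I1=1)."""
    return gillespie_run(defaults, ResourceMode.SHARED, t_end=5000.0, seed=11)


def random_params(rng: np.random.Generator) -> CircuitParams:
    """Moderately perturbed parameter set (factor 0.5..2 on each rate)."""
    base = CircuitParams()
    changes = {}
    for name in ("km01", "km1", "kp1", "dm1", "dp1", "Jm1", "Jp1",
                 "km02", "km2", "kp2", "dm2", "dp2", "Jm2", "Jp2", "Kg"):
        changes[name] = getattr(base, name) * float(rng.uniform(0.5, 2.0))
    return base.replace(**changes)
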