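import numpy as np
import pytest

import steric_stepper as ss


@pytest.fixture(scope="session")
def walker36():
    """36-bp walker-foothold complex parameters (shell + tail + trench)."""
    return ss.walker36_params()


@pytest.fixture(scope="session")
def kinetics():
    """Reference transport/reactivity: D = 5e7 nm^2/s, kappa = 1 nm/s."""
    return ss.default_kinetics(1.0)


@pytest.fixture(scope="session")
def potential_cache(walker36):
    """Shared cache of effective radial potentials, keyed by
    (scenario, a, epsilon); several test modules reuse the same builds."""
    cache: dict = {}

    def get(scenario: str, a: float = 11.5, epsilon: float = 2.0,
            params=None) -> ss.RadialPotential:
        p = walker36 if params is None else params
        key = (scenario, a, epsilon, id(p) if params is not None else None)
        if key not in cache:
            rp = ss.radial_equilibrium_density(
                scenario, p, ss.TargetGeometry(a=a, epsilon=epsilon))
            cache[key] = ss.effective_potential(rp)
        return cache[key]

    return get
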