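import numpy as np
import pytest

import fracfhr as f


@pytest.fixture(scope="session")
def presets():
    return {label: f.preset(label) for label in f.PRESET_LABELS}


@pytest.fixture(scope="session")
def burst_trajectory():
    """Classical-order elliptic-bursting run (preset I, alpha=1), long enough
    to contain several bursts and interburst gaps."""
    cfg = f.SolverConfig(alpha=1.0, n_steps=200000, dt=0.1, seed=5)
    return f.simulate(f.preset("I"), cfg)


def random_assumption_a_params(rng: np.random.Generator) -> f.ParameterSet:
    """A random parameter set satisfying b*d < b + d (rejection sampling)."""
    while True:
        b, d = rng.uniform(0.2, 2.0, size=2)
        if b * d < b + d:
            break
    return f.ParameterSet(
        a=rng.uniform(-2, 2),
        b=b,
        c=rng.uniform(-2, 2),
        d=d,
        delta=rng.uniform(1e-3, 0.5),
        mu=rng.uniform(1e-4, 0.5),
        I=rng.uniform(-2, 4),
    )
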