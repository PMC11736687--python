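import numpy as np
import pytest

import mcfret as mc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_symmetric_h(rng):
    def make(n, scale=300.0):
        A = rng.standard_normal((n, n)) * scale
        return 0.5 * (A + A.T)

    return make


@pytest.fixture
def dimer_trajectory():
    """Two resonant single-site segments with OU disorder, weak coupling."""
    sigma, tau, dt, J = 300.0, 20.0, 3.0, 10.0
    n_frames = 3999 * 40 + 41
    model = mc.DisorderModel([(sigma, tau)])
    energies = mc.generate_ou_trajectory(model, 2, n_frames, dt, seed=3)
    couplings = np.array([[0.0, J], [J, 0.0]])
    return mc.HamiltonianTrajectory(energies, couplings, dt)
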