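import numpy as np
import pytest

import smrkit as sk

REFERENCE_D = 5.0e-11
REFERENCE_DELTA_T = 0.03
REFERENCE_XT_M = 4.58e-6
REFERENCE_V = 2.0e-3


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def closed_loop_runs():
    """Twenty closed-loop molecules at the reference operating point.

    ~201 cycles each (duration 6.03 s at the 30 ms reversal delay), shared
    by the controller-stability, end-to-end-recovery and acceptance tests.
    """
    runs = []
    for seed in range(20):
        gen = np.random.default_rng(seed)
        runs.append(
            sk.run_experiment(
                sk.DiffusionModel(D=REFERENCE_D),
                sk.BeamModel(),
                duration=6.03,
                rng=gen,
            )
        )
    return runs


@pytest.fixture(scope="session")
def bead_photons():
    """Immobilized bead recycled for 100 passes at the 30 ms delay."""
    gen = np.random.default_rng(7)
    return sk.simulate_immobilized_bead(
        sk.BeamModel(peak_rate=2.0e5, background=500.0),
        passes=100,
        delta_t=REFERENCE_DELTA_T,
        rng=gen,
    )
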