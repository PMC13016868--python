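import os

# pin BLAS to one thread: these are many small factorizations, where thread
# fan-out costs more than it saves
for _v in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pytest

import physofr as pf
from physofr import sofr


@pytest.fixture(scope="session")
def small_design():
    return pf.generate_design(3, seed=7)


@pytest.fixture(scope="session")
def small_truth():
    return pf.simulate_truth(pf.SimulationConfig(n_participants=3), seed=1)


@pytest.fixture(scope="session")
def quiet_config():
    """All stochastic components off: ratings are a deterministic map."""
    return pf.SimulationConfig(
        n_participants=3,
        indiv_sd={d: {c: 0.0 for c in pf.CHANNELS} for d in pf.DIMENSIONS},
        participant_sd={d: 0.0 for d in pf.DIMENSIONS},
        noise_sd={d: 0.0 for d in pf.DIMENSIONS},
        rating_noise_sd=0.0, signal_noise_sd=0.0, drift_sd=0.0, idio_sd=0.0,
        trial_fn_sd=0.0, emg_mode="direct",
    )


@pytest.fixture(scope="session")
def basis30():
    return sofr.build_basis(pf.analysis_grid(), K=8)


def brute_force_fm_depth(curves: np.ndarray) -> np.ndarray:
    """Independent double-loop evaluation of the Fraiman-Muniz depth."""
    curves = np.asarray(curves, float)
    n, T = curves.shape
    depth = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for t in range(T):
            F = np.sum(curves[:, t] <= curves[i, t]) / n
            acc += 1.0 - abs(0.5 - F)
        depth[i] = acc / T
    return depth
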