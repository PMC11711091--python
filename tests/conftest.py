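import numpy as np
import pytest

from expressome import synthgen as sg


@pytest.fixture(scope="session")
def elongating_traces():
    """Small elongating-condition translation ensemble with photophysics."""
    cfg = sg.SimConfig(n_traces=40, n_frames=2000, seed=101,
                       state_fret_sd=0.05, dwell_means=(12.8, 5.0),
                       bleach_mean_frames={"donor": 2000, "acceptor": 2500})
    traces, truths = sg.simulate_dataset(cfg)
    return cfg, traces, truths


@pytest.fixture(scope="session")
def coupling_rate_matrix():
    """Three-state chain uncoupled <-> loose <-> coupled with a 10.1 s mean
    uncoupled (recoupling) dwell."""
    return np.array([[0.0, 1.0 / 10.1, 0.0],
                     [0.04, 0.0, 0.08],
                     [0.0, 0.03, 0.0]])


@pytest.fixture(scope="session")
def coupling_traces(coupling_rate_matrix):
    cfg = sg.SimConfig(kinetic_scheme="coupling_multistate", n_traces=60,
                       n_frames=3000, frame_time=0.2,
                       state_fret_means=(0.0, 0.1, 0.3), state_fret_sd=0.03,
                       rate_matrix=coupling_rate_matrix, alex=True, seed=202,
                       bleach_mean_frames={"donor": 4000, "acceptor": 5000})
    traces, truths = sg.simulate_dataset(cfg)
    return cfg, traces, truths
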