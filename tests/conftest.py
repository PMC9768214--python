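import numpy as np
import pytest

import neurostates as ns


@pytest.fixture(scope="session")
def montage():
    return ns.standard_30_channel_montage()


@pytest.fixture(scope="session")
def resting_recording():
    """One short resting-state recording shared across read-only tests."""
    return ns.generate_state_recording("resting", duration=20.0, fs=250.0, seed=11)


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Trigger numba compilation once so per-test timings stay small."""
    from neurostates._kernels import (
        bfs_all_distances,
        local_efficiency_nodes,
        maslov_sneppen_rewire,
        pli_signs,
    )

    a = np.zeros((4, 4), dtype=np.uint8)
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
    bfs_all_distances(a)
    local_efficiency_nodes(a)
    pli_signs(np.ones((2, 4)), np.zeros((2, 4)))
    edges = np.array([[0, 1], [1, 2]], dtype=np.int64)
    maslov_sneppen_rewire(a.copy(), edges, 1, 10, 1)


def sine_recording(freq, fs=250.0, duration=10.0, montage=None, amp=1.0, phase=0.0):
    """Helper: every channel the same sinusoid (plus index to keep channels
    nonzero where needed is left to callers)."""
    montage = montage or ns.standard_30_channel_montage()
    t = np.arange(int(duration * fs)) / fs
    wave = amp * np.cos(2 * np.pi * freq * t + phase)
    data = np.tile(wave, (montage.n_channels, 1))
    return ns.EEGRecording(data=data, fs=fs, montage=montage)
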