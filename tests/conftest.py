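"""Shared fixtures: small head/sensor geometries and simulated recordings.

Everything is generated programmatically with fixed seeds; the heavier
simulated-study fixtures are session-scoped so the pipeline-level tests
share one computation.
"""

import numpy as np
import pytest

from cohnet import forward as fwd
from cohnet import synthesis as syn


@pytest.fixture(scope="session")
def head():
    return fwd.SphericalHeadModel()


@pytest.fixture(scope="session")
def sensors_small(head):
    """A light sensor array: 32 EEG, 20 magnetometers, 20 gradiometers."""
    return fwd.build_sensor_fixture(32, 20, 20, head, seed=11)


@pytest.fixture(scope="session")
def sensors_meg(head):
    return fwd.build_sensor_fixture(0, 40, 40, head, seed=12)


@pytest.fixture(scope="session")
def single_dipole_recording(head, sensors_meg):
    """One superficial tangential dipole coherent with the EMG, MEG sensors."""
    loc = np.array([-0.042, -0.0105, 0.0308])
    rhat = loc / np.linalg.norm(loc)
    q = np.cross([0.0, 0.0, 1.0], rhat)
    q /= np.linalg.norm(q)
    net = syn.TrueNetwork(
        names=["SRC"], locations=loc[None], moments=q[None],
        amplitudes=np.array([1.0]), edges=[],
    )
    ens = syn.simulate_source_network(net, n_epochs=60, seed=21)
    ens.emg = syn.simulate_emg(ens.sources[0], modulation_depth=0.9, seed=22)
    lf = fwd.build_leadfield(net.locations, head, sensors_meg)
    task, rest = syn.project_and_add_noise(ens, lf, sensors_meg, snr={"meg": 8.0}, seed=23)
    return {"net": net, "ens": ens, "task": task, "rest": rest}


@pytest.fixture(scope="session")
def study_data():
    """One simulated study realization shared by the scenario-level tests."""
    return syn.reference_study(seed=1)
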