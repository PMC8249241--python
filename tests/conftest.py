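"""Shared fixtures: simulator presets, protocols and small synthetic datasets."""

import numpy as np
import pytest

from pomcpop import synthetic
from pomcpop.spatial import PointCloud
from pomcpop.traces import StimulusProtocol


@pytest.fixture(scope="session")
def tonic_config():
    return synthetic.EphysSimConfig.tonic(seed=11)


@pytest.fixture(scope="session")
def phasic_config():
    return synthetic.EphysSimConfig.phasic_adaptive(seed=11)


@pytest.fixture(scope="session")
def step_30pa():
    return StimulusProtocol(kind="step", amplitudes=[30.0], pulse_s=1.0)


@pytest.fixture(scope="session")
def sfa_protocol():
    """10-s depolarizing stimulus for spike-frequency-adaptation fits."""
    return StimulusProtocol(kind="step", amplitudes=[30.0], pulse_s=10.0)


@pytest.fixture(scope="session")
def ramp_15pa():
    return StimulusProtocol(kind="ramp_updown", amplitudes=[15.0])


@pytest.fixture(scope="session")
def rebound_protocol():
    """2-s hyperpolarizing pre-pulses followed by a 1-s 15-pA test pulse."""
    return StimulusProtocol(
        kind="rebound", amplitudes=[-50.0, -30.0, -10.0], test_amplitude=15.0
    )


@pytest.fixture(scope="session")
def hyperpol_series():
    return StimulusProtocol(kind="hyperpol_series", amplitudes=[-2, -4, -6, -8, -10])


def arc_like_component(center, spread):
    return synthetic.MixtureComponent(
        weight=1.0, mean=center, covariance=np.diag([spread**2] * 3)
    )


@pytest.fixture(scope="session")
def null_spatial_config():
    """Identical mixtures for both groups: the spatial null hypothesis."""
    box = ((0.0, 800.0), (0.0, 600.0), (0.0, 1600.0))
    mixture = [
        synthetic.MixtureComponent(
            weight=0.6, mean=(400.0, 300.0, 500.0), covariance=np.diag([150.0**2, 100.0**2, 250.0**2])
        ),
        synthetic.MixtureComponent(
            weight=0.4, mean=(400.0, 300.0, 1100.0), covariance=np.diag([150.0**2, 100.0**2, 250.0**2])
        ),
    ]
    return synthetic.SpatialSimConfig(
        bounding_box=box,
        components={"Glp1r": mixture, "Lepr": mixture},
        neurons_per_animal=300,
        animals_per_group=5,
        seed=7,
    )


@pytest.fixture
def tiny_cloud():
    rng = np.random.default_rng(0)
    return PointCloud(
        animal_id="a1", group="Lepr", coordinates=rng.normal([100, 200, 300], 20, size=(50, 3))
    )
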