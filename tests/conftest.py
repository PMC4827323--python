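import pytest
from hypothesis import HealthCheck, settings

import omgkit as omg

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_protocol():
    """Two repetitions of the default movement sequence (64 s, 960 frames)."""
    return omg.ProtocolConfig(repetitions=2)


@pytest.fixture(scope="session")
def noiseless_deformation():
    return omg.DeformationConfig(
        noise_sd=(0.0,) * 6, drift_amplitude=(0.0,) * 6, dropout_rate=0.0, seed=1
    )


@pytest.fixture(scope="session")
def noiseless_subject(noiseless_deformation):
    """Full-length noiseless subject: deformation is exactly linear in the
    activations."""
    return omg.make_subject(deformation=noiseless_deformation)


@pytest.fixture(scope="session")
def noisy_subject():
    """One subject under the default noise/drift/dropout conditions."""
    return omg.make_subject(seed=7)


@pytest.fixture(scope="session")
def small_subject(small_protocol):
    return omg.make_subject(small_protocol, seed=3)


@pytest.fixture(scope="session")
def noisy_features(noisy_subject):
    traj, _ = noisy_subject
    return omg.build_features(omg.impute_last_known(traj))
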