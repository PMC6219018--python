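import numpy as np
import pytest

from somnapose import RunConfig, SleepPosture
from somnapose.synth import JitterSpec, body_model, generate_recording


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def zero_noise_recordings():
    """One noiseless recording per posture (medium build), with ground truth."""
    out = {}
    for posture in SleepPosture:
        out[posture] = generate_recording(
            posture, body_model("medium"), JitterSpec.none(), n_frames=1, rng=0
        )
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
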