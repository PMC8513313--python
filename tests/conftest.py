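import numpy as np
import pytest

from chirpeeg.synthgen import Recording, SimScenario


def single_channel_recording(samples: np.ndarray, fs: float = 625.0) -> Recording:
    return Recording(
        fs=fs,
        samples=np.asarray(samples, dtype=float)[None, :],
        channel_labels=["ch00"],
        region_assignment={"ch00": "LF"},
    )


@pytest.fixture(scope="session")
def small_scenario() -> SimScenario:
    """Six-channel scenario (one channel per region) used by slower tests."""
    return SimScenario(n_channels=6, seed=11, plf_profile={40.0: 0.5})


@pytest.fixture(scope="session")
def background_recording(small_scenario):
    from chirpeeg.synthgen import simulate_background

    return simulate_background(small_scenario, duration=300.0)
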