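import numpy as np
import pytest

import semgimg as sg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recordings():
    """2 subjects x 3 gestures x 10 reps of short 10-channel envelopes."""
    config = sg.SynthConfig(subjects=2, gestures=3, repetitions=10,
                            channels=10, fs=100.0, duration_s=1.0,
                            snr_db=10.0, seed=11)
    return sg.generate(config)


@pytest.fixture(scope="session")
def small_datasets(small_recordings):
    """Encoded train/test datasets from the small synthetic recordings."""
    return sg.build_dataset(small_recordings, sg.WindowSpec(200, 400))


@pytest.fixture
def random_window(rng):
    return sg.SignalWindow(data=rng.random((20, 10)), label=3, subject=2,
                           repetition=4, start_index=10)
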