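import numpy as np
import pytest

import affectlstm as al


@pytest.fixture(scope="session")
def desk_rec():
    """High-SNR desk-scale (8 trials x 8 channels) quadrant-labelled recording."""
    return al.generate_recording(al.SynthConfig.desk(seed=1, snr=4.0))


@pytest.fixture(scope="session")
def desk_fs(desk_rec):
    return al.build_feature_set(desk_rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
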