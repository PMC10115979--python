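import numpy as np
import pytest

import eegmicrostates as ems


@pytest.fixture(scope="session")
def montage():
    return ems.default_montage()


@pytest.fixture(scope="session")
def templates(montage):
    _names, pos = montage
    return ems.default_templates(pos)


@pytest.fixture(scope="session")
def clean_epoch(templates):
    """Noise-free 30-s epoch rendered straight from the canonical templates,
    with its planted label sequence."""
    truth = ems.default_truth(snr_db=300.0, seed=5)
    rng = np.random.default_rng(5)
    labels = ems.simulate_label_sequence(truth, 30.0, 200.0, rng)
    rec = ems.render_eeg(labels, truth, 200.0, rng=rng)
    return ems.ConditionEpoch("rest", rec.data, 200.0), labels, truth


@pytest.fixture(scope="session")
def noisy_epoch(templates):
    """30-s epoch at the default 10 dB SNR, with its planted labels."""
    truth = ems.default_truth(snr_db=10.0, seed=6)
    rng = np.random.default_rng(6)
    labels = ems.simulate_label_sequence(truth, 30.0, 200.0, rng)
    rec = ems.render_eeg(labels, truth, 200.0, rng=rng)
    return ems.ConditionEpoch("rest", rec.data, 200.0), labels, truth
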