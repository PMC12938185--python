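import numpy as np
import pytest

from bandstates import (
    SyntheticConfig,
    SyntheticTruth,
    TemplateSet,
    default_montage,
    make_templates,
    sample_state_sequence,
    synthesize_eeg,
)


@pytest.fixture(scope="session")
def montage():
    return default_montage(52)


@pytest.fixture(scope="session")
def small_montage():
    return default_montage(16)


@pytest.fixture(scope="session")
def templates(montage):
    return make_templates(montage, 4, seed=1)


@pytest.fixture(scope="session")
def template_set(templates):
    return TemplateSet(templates, ("A", "B", "C", "D"), band="alpha")


@pytest.fixture(scope="session")
def noiseless_recording(montage, templates):
    """60 s alpha-band recording with known state sequence and no noise."""
    cfg = SyntheticConfig(duration=60.0, band=(8.0, 13.0), snr=np.inf, seed=11)
    labels, segments = sample_state_sequence(cfg)
    truth = SyntheticTruth(templates, labels, cfg.transition_matrix, segments)
    rec = synthesize_eeg(cfg, truth, montage)
    return rec, truth, cfg


@pytest.fixture(scope="session")
def noisy_recording(montage, templates):
    """60 s alpha-band recording at SNR 3."""
    cfg = SyntheticConfig(duration=60.0, band=(8.0, 13.0), snr=3.0, seed=12)
    labels, segments = sample_state_sequence(cfg)
    truth = SyntheticTruth(templates, labels, cfg.transition_matrix, segments)
    rec = synthesize_eeg(cfg, truth, montage)
    return rec, truth, cfg
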