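import logging

import numpy as np
import pytest

import mstates as ms

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def templates59():
    return ms.generate_templates(59, 5, min_separation=0.5, seed=1)


@pytest.fixture(scope="session")
def snr2_recording(templates59):
    """One minute of 5-state synthetic EEG at snr 2 with known ground truth."""
    cfg = ms.SimulationConfig(duration_s=60.0, snr=2.0, seed=3, templates=templates59)
    rec, gt = ms.generate_microstate_eeg(cfg)
    return rec, gt


@pytest.fixture(scope="session")
def prepared_recording(snr2_recording):
    """The same recording band-filtered to 1-20 Hz and average-referenced."""
    rec, gt = snr2_recording
    prep = ms.rereference_average(ms.bandpass_zero_phase(rec, 1.0, 20.0))
    return prep, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
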