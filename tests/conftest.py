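from __future__ import annotations

import numpy as np
import pytest

from scgbeat.preprocess import preprocess_record
from scgbeat.synthetic import SynthConfig, generate_record


@pytest.fixture(scope="session")
def clean_synth():
    """60 s noiseless record at 60 bpm with zero RR variability."""
    return generate_record(
        SynthConfig(
            duration_s=60.0,
            fs=256.0,
            mean_hr_bpm=60.0,
            rr_jitter_sd_ms=0.0,
            rsa_depth_ms=0.0,
            snr_db=np.inf,
            seed=0,
        )
    )


@pytest.fixture(scope="session")
def noisy_synth():
    """60 s record at 70 bpm, SNR 40 dB, physiological RR variability."""
    return generate_record(SynthConfig(duration_s=60.0, mean_hr_bpm=70.0, snr_db=40.0, seed=1))


@pytest.fixture(scope="session")
def noisy_preprocessed(noisy_synth):
    return preprocess_record(noisy_synth.record)


@pytest.fixture(scope="session")
def clean_preprocessed(clean_synth):
    return preprocess_record(clean_synth.record)
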