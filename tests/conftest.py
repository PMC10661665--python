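"""Shared fixtures: synthetic records with known ground truth."""

import numpy as np
import pytest

from stvrepol import SynthConfig, detect_senses, synthesize_record


def truth_landmarks(gt):
    """Template (q_onset, t_end) offsets relative to the R peak, from truth."""
    q = float(np.mean(gt.qrs_onset - gt.r_peak))
    t = float(np.mean(gt.t_end - gt.r_peak))
    return q, t


@pytest.fixture(scope="session")
def clean_ecg():
    """Noise-free ECG-style record, constant repolarization, jittered RR."""
    cfg = SynthConfig.ecg(n_beats=33, repol_jitter_sd=0.0, rr_jitter_sd=15.0,
                          noise_sd=0.0, seed=11)
    record, truth = synthesize_record(cfg)
    return cfg, record, truth


@pytest.fixture(scope="session")
def clean_egm():
    """Noise-free EGM-style record with 5 ms repolarization jitter."""
    cfg = SynthConfig.egm(n_beats=33, repol_jitter_sd=5.0, rr_jitter_sd=15.0,
                          noise_sd=0.0, seed=21)
    record, truth = synthesize_record(cfg)
    return cfg, record, truth


@pytest.fixture(scope="session")
def sensed_egm(clean_egm):
    _, record, truth = clean_egm
    return detect_senses(record, "I2")
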