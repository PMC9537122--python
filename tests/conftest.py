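import numpy as np
import pytest

from ppgmark import synthetic as syn
from ppgmark.markers import beat_markers
from ppgmark.preprocess import delineate_beats, normalize_beat


@pytest.fixture(scope="session")
def small_noiseless_cohort():
    """4+4 subjects, 30 s, all noise sources silenced."""
    cfg = syn.noiseless(syn.CohortConfig(n_subjects_per_class=4,
                                         record_seconds=30, seed=7))
    return syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """4+4 subjects, 30 s, default noise."""
    cfg = syn.CohortConfig(n_subjects_per_class=4, record_seconds=30, seed=7)
    return syn.generate_cohort(cfg)


def closed_form_markers(shape, fs=250.0, period=0.8):
    """Markers of one pulse shape measured from its ideal sampled waveform.

    Three identical beats are concatenated and the middle one delineated,
    so edge effects cannot contaminate the measurement.  This bypasses the
    smoothing/baseline stages entirely.
    """
    b = syn.generate_beat(shape, period, fs)
    sig = np.concatenate([b, b, b])
    lms = delineate_beats(sig, fs)
    if not lms:
        return None
    beat = normalize_beat(sig, lms[len(lms) // 2], fs)
    return beat_markers(beat)
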