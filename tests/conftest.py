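import numpy as np
import pytest
from hypothesis import settings

from hgmap import strf, synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from hgmap.containers import HighGammaResponse


@pytest.fixture(scope="session")
def small_cohort():
    """Ten sites, 60 s stimulus, four speakers."""
    return synth.generate_cohort(10, duration_s=60.0, seed=100)


@pytest.fixture(scope="session")
def small_design(small_cohort):
    return strf.LaggedStimulusDesign(small_cohort.stimulus)


@pytest.fixture(scope="session")
def small_sound_set():
    return synth.generate_sound_set(seed=200, mean_trial_s=2.0, silence_s=10.0)


def make_strf_model(weights, frame_rate=100.0, band_centers=None):
    """Wrap a weight matrix in an STRFModel for extraction tests."""
    from hgmap.frontend import DEFAULT_BAND_CENTERS
    weights = np.asarray(weights, dtype=float)
    return strf.STRFModel(
        weights=weights,
        lags_ms=np.arange(weights.shape[0]) * 1000.0 / frame_rate,
        frame_rate=frame_rate,
        band_centers=DEFAULT_BAND_CENTERS if band_centers is None else band_centers,
        ridge_param=0.0, sparseness_param=0.0,
        prediction_r=1.0, fold_rs=np.ones(20))


@pytest.fixture(scope="session")
def evoked_invariant():
    """Population evoked matrix from a speaker-invariant cohort."""
    from hgmap.phonemes import CLASSIFIER_WINDOW_MS, segment_evoked
    cohort = synth.generate_cohort(5, duration_s=180.0, seed=3,
                                   invariance_mode="speaker_invariant")
    resp = synth.generate_responses(cohort, snr_db=6.0)
    hg = HighGammaResponse(values=resp, frame_rate=100.0)
    return segment_evoked(hg, cohort.phoneme_table, CLASSIFIER_WINDOW_MS)
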