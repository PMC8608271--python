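"""Speech sensitivity: silence-normalised trial averages and the speech vs
nonspeech t statistic, for measured responses and for STRF predictions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import Spectrogram
from .strf import STRFModel, predict_response

SPEECH, NONSPEECH = "speech", "nonspeech"


@dataclass
class SensitivityResult:
    site_id: str
    t_value: float
    p_value: float
    q_value: float
    significant: bool          # more responsive to speech, FDR q < threshold
    n_speech: int
    n_nonspeech: int
    predicted_t: float = np.nan
    predicted_defined: bool = False


def trial_mean_matrix(values: np.ndarray, frame_rate: float,
                      trials: pd.DataFrame,
                      silence_window: tuple[float, float]) -> np.ndarray:
    """Silence-normalised per-trial mean response, sites x trials.

    Each site is z-scored by the mean and SD of its response during the
    silent interval, then averaged over each trial window.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    t0, t1 = silence_window
    i0, i1 = int(np.floor(t0 * frame_rate)), int(np.floor(t1 * frame_rate))
    if i1 - i0 < 2 or i1 > values.shape[1]:
        raise ValueError("silence window missing or outside the recording")
    sil = values[:, i0:i1]
    mu = sil.mean(axis=1)
    sd = sil.std(axis=1, ddof=0)
    if np.any(sd <= 1e-12):
        raise ValueError("zero-variance silence segment; cannot normalise")
    z = (values - mu[:, None]) / sd[:, None]
    out = np.empty((values.shape[0], len(trials)))
    for j, (s, e) in enumerate(zip(trials["start_s"], trials["end_s"])):
        a, b = int(np.floor(s * frame_rate)), int(np.floor(e * frame_rate))
        out[:, j] = z[:, a:b].mean(axis=1)
    return out


def sensitivity_t(trial_means: np.ndarray, labels: np.ndarray,
                  equal_var: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Unpaired t statistic (speech minus nonspeech) per site, with p-values."""
    labels = np.asarray(labels)
    sp = trial_means[:, labels == SPEECH]
    ns = trial_means[:, labels == NONSPEECH]
    if sp.shape[1] < 2 or ns.shape[1] < 2:
        raise ValueError("need at least 2 trials per label")
    t, p = stats.ttest_ind(sp, ns, axis=1, equal_var=equal_var)
    return np.asarray(t, dtype=float), np.asarray(p, dtype=float)


def speech_sensitivity(values: np.ndarray, frame_rate: float,
                       trials: pd.DataFrame,
                       silence_window: tuple[float, float],
                       q_threshold: float = 0.01, equal_var: bool = True,
                       site_ids: list[str] | None = None
                       ) -> list[SensitivityResult]:
    """Per-site speech sensitivity with BH-FDR significance flags.

    A site is flagged significantly more responsive to speech when its
    positive t survives FDR correction across sites at ``q_threshold``.
    """
    tm = trial_mean_matrix(values, frame_rate, trials, silence_window)
    labels = trials["label"].to_numpy()
    t, p = sensitivity_t(tm, labels, equal_var=equal_var)
    _, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    flags = (q < q_threshold) & (t > 0)
    n_sp = int(np.sum(labels == SPEECH))
    n_ns = int(np.sum(labels == NONSPEECH))
    ids = site_ids or [f"e{i:03d}" for i in range(tm.shape[0])]
    return [SensitivityResult(site_id=ids[i], t_value=float(t[i]),
                              p_value=float(p[i]), q_value=float(q[i]),
                              significant=bool(flags[i]),
                              n_speech=n_sp, n_nonspeech=n_ns)
            for i in range(tm.shape[0])]


def predicted_sensitivity(models: list[STRFModel], timeline: Spectrogram,
                          trials: pd.DataFrame,
                          silence_window: tuple[float, float],
                          equal_var: bool = True
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Speech sensitivity of STRF-predicted responses.

    Each site's response to the trial timeline is simulated as its STRF
    prediction and passed through the identical statistic; predictions are
    normalised by their own silent-interval output.  Returns (t values,
    defined flags); a site with an all-zero filter or a degenerate silent
    prediction is flagged undefined (NaN t).
    """
    fr = timeline.frame_rate
    t_out = np.full(len(models), np.nan)
    defined = np.zeros(len(models), dtype=bool)
    labels = trials["label"].to_numpy()
    for i, m in enumerate(models):
        if not np.any(m.weights):
            continue
        pred = predict_response(m, timeline)[None, :]
        try:
            tm = trial_mean_matrix(pred, fr, trials, silence_window)
        except ValueError:
            continue
        t, _ = sensitivity_t(tm, labels, equal_var=equal_var)
        t_out[i] = t[0]
        defined[i] = True
    return t_out, defined
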