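"""Signal front ends: cochlear-model auditory spectrogram and high-gamma envelope.

The acoustic front end emulates early auditory processing: a bank of 128
asymmetric bandpass filters equally spaced on a log-frequency axis, envelope
extraction, static compressive nonlinearity, a first-order derivative across
the spectral axis with half-wave rectification (lateral inhibition), temporal
integration to the analysis frame rate, and pooling to 16 log-spaced bands.

The neural front end converts raw multichannel recordings to the high-gamma
(70-150 Hz) amplitude envelope: resample to 500 Hz, first-order 1 Hz
Butterworth high-pass, 1-Hz-wide second-order notches at 60/120/180/240 Hz,
eight 10-Hz sub-bands across 70-150 Hz, per-band analytic-signal magnitude,
averaging across sub-bands, resampling to the analysis frame rate and
z-scoring against a prestimulus silent baseline.  All filtering is applied
forward-backward so response latencies are not biased by group delay.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import N_BANDS, HighGammaResponse, Spectrogram

# Cochlear filterbank span.  The upper edge reflects the Nyquist limit of
# 11.025 kHz speech material: best frequencies above 5.5 kHz are not
# representable.
F_LO = 180.0
F_HI = 5500.0
N_CHANNELS = 128
DEFAULT_FRAME_RATE = 100.0

# High-gamma band definition: eight equal-width sub-bands over 70-150 Hz.
HG_LO, HG_HI = 70.0, 150.0
N_HG_BANDS = 8
HG_RATE = 500.0  # internal processing rate, Hz
NOTCH_FREQS = (60.0, 120.0, 180.0, 240.0)


def channel_centers() -> np.ndarray:
    """Centre frequencies (Hz) of the 128 cochlear channels."""
    return np.geomspace(F_LO, F_HI, N_CHANNELS)


def band_centers() -> np.ndarray:
    """Centre frequencies (Hz) of the 16 output bands (geometric group means)."""
    cc = channel_centers().reshape(N_BANDS, N_CHANNELS // N_BANDS)
    return np.exp(np.log(cc).mean(axis=1))


DEFAULT_BAND_CENTERS = band_centers()


class FlatChannelError(ValueError):
    """Raised when a channel has zero variance in the baseline window."""


def _asym_filter(freqs: np.ndarray, fc: float,
                 sigma_lo: float = 0.25, sigma_hi: float = 0.03) -> np.ndarray:
    """Asymmetric (sharper high-frequency skirt) magnitude response in log-f."""
    h = np.zeros_like(freqs)
    pos = freqs > 0
    d = np.log2(freqs[pos] / fc)
    sig = np.where(d < 0, sigma_lo, sigma_hi)
    h[pos] = np.exp(-0.5 * (d / sig) ** 2)
    return h


def auditory_spectrogram(audio: np.ndarray, sr: float,
                         frame_rate: float = DEFAULT_FRAME_RATE,
                         compression: str = "cbrt") -> Spectrogram:
    """Compute the 16-band auditory spectrogram of a mono audio signal.

    Parameters
    ----------
    audio
        Mono waveform.
    sr
        Sampling rate, Hz.  Must be at least 8 kHz and must cover the top
        cochlear filter (Nyquist >= 5.5 kHz).
    frame_rate
        Output frames per second (default 100, i.e. 10 ms frames).
    compression
        Static nonlinearity applied to channel envelopes: ``"cbrt"``
        (default) or ``"log"``.
    """
    audio = np.asarray(audio, dtype=float).ravel()
    if audio.size == 0:
        raise ValueError("empty audio")
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio contains NaN or infinite samples")
    if sr < 8000:
        raise ValueError(f"sampling rate {sr} Hz too low; need >= 8000 Hz")
    if sr / 2 < F_HI:
        raise ValueError(
            f"sampling rate {sr} Hz cannot represent the top filter at "
            f"{F_HI:.0f} Hz; maximum representable frequency is {sr / 2:.1f} Hz"
        )

    n = audio.size
    frame_len = int(round(sr / frame_rate))
    n_frames = n // frame_len
    if n_frames == 0:
        raise ValueError("audio shorter than one analysis frame")

    spec = np.fft.rfft(audio)
    freqs = np.fft.rfftfreq(n, 1.0 / sr)

    def channel_envelope(fc: float) -> np.ndarray:
        # analytic signal of the filtered channel via one-sided spectrum
        h = _asym_filter(freqs, fc)
        full = np.zeros(n, dtype=complex)
        full[: spec.size] = spec * h * 2.0
        full[0] /= 2.0
        if n % 2 == 0:
            full[n // 2] /= 2.0
        return np.abs(np.fft.ifft(full))

    def compress(x: np.ndarray) -> np.ndarray:
        if compression == "cbrt":
            return np.cbrt(x)
        if compression == "log":
            return np.log1p(30.0 * x)
        raise ValueError(f"unknown compression {compression!r}")

    centers = channel_centers()
    frames = np.empty((n_frames, N_CHANNELS))
    # Lateral inhibition: rectified first difference toward the next-lower
    # channel, on compressed envelopes, before temporal integration.  A tone
    # excites channels at and above its place (upward spread through the
    # shallow low-frequency skirts); the difference localises the sharp
    # low-side edge of that excitation at the tone's place.  Iterate
    # low-to-high keeping one neighbour in memory.
    prev = None
    for c in range(N_CHANNELS):
        cur = compress(channel_envelope(centers[c]))
        inhibited = np.zeros_like(cur) if prev is None else np.maximum(cur - prev, 0.0)
        trimmed = inhibited[: n_frames * frame_len]
        frames[:, c] = trimmed.reshape(n_frames, frame_len).mean(axis=1)
        prev = cur

    bands = frames.reshape(n_frames, N_BANDS, N_CHANNELS // N_BANDS).mean(axis=2)
    return Spectrogram(values=bands, frame_rate=frame_rate,
                       band_centers=DEFAULT_BAND_CENTERS)


# ---------------------------------------------------------------------------
# high-gamma extraction
# ---------------------------------------------------------------------------

def _resample(x: np.ndarray, sr_in: float, sr_out: float) -> np.ndarray:
    if sr_in == sr_out:
        return x
    frac = Fraction(sr_out / sr_in).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def preprocess_raw(raw: np.ndarray, sr: float) -> np.ndarray:
    """Resample to 500 Hz, remove DC drift and line noise (zero-phase)."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if sr < 500:
        raise ValueError(f"sampling rate {sr} Hz too low; need >= 500 Hz")
    x = _resample(raw, sr, HG_RATE)
    b, a = signal.butter(1, 1.0, btype="highpass", fs=HG_RATE)
    x = signal.filtfilt(b, a, x, axis=-1)
    for f0 in NOTCH_FREQS:
        b, a = signal.iirnotch(f0, f0 / 1.0, fs=HG_RATE)  # 1 Hz bandwidth
        x = signal.filtfilt(b, a, x, axis=-1)
    return x


def hg_subbands() -> list[tuple[float, float]]:
    edges = np.linspace(HG_LO, HG_HI, N_HG_BANDS + 1)
    return list(zip(edges[:-1], edges[1:]))


def high_gamma_envelope(x500: np.ndarray) -> np.ndarray:
    """Average analytic-signal magnitude across the eight 70-150 Hz sub-bands."""
    x500 = np.atleast_2d(np.asarray(x500, dtype=float))
    env = np.zeros_like(x500)
    for lo, hi in hg_subbands():
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=HG_RATE, output="sos")
        xb = signal.sosfiltfilt(sos, x500, axis=-1)
        env += np.abs(signal.hilbert(xb, axis=-1))
    return env / N_HG_BANDS


def extract_high_gamma(raw: np.ndarray, sr: float,
                       baseline_window: tuple[float, float],
                       frame_rate: float = DEFAULT_FRAME_RATE,
                       site_ids: list[str] | None = None) -> HighGammaResponse:
    """Full raw-to-z-scored high-gamma pipeline.

    ``baseline_window`` is a (start_s, end_s) interval of prestimulus silence;
    the final envelope is z-scored per electrode by the mean and standard
    deviation over that interval.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    t0, t1 = baseline_window
    dur = raw.shape[1] / sr
    if not (0 <= t0 < t1 <= dur + 1e-9):
        raise ValueError(f"baseline window {baseline_window} outside recording (0, {dur:.3f}) s")
    env = high_gamma_envelope(preprocess_raw(raw, sr))
    env = _resample(env, HG_RATE, frame_rate)
    i0, i1 = int(np.floor(t0 * frame_rate)), int(np.floor(t1 * frame_rate))
    base = env[:, i0:i1]
    mu = base.mean(axis=1)
    sd = base.std(axis=1, ddof=0)
    flat = np.flatnonzero(sd <= 1e-12)
    if flat.size:
        raise FlatChannelError(f"constant baseline on channel(s) {flat.tolist()}")
    z = (env - mu[:, None]) / sd[:, None]
    return HighGammaResponse(values=z, frame_rate=frame_rate,
                             baseline_mean=mu, baseline_sd=sd,
                             site_ids=site_ids or [])
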