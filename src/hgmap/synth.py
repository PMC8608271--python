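"""Synthetic stimuli, neural responses and electrode geometries with ground truth.

Every downstream stage of the pipeline (STRF estimation, phoneme decoding,
speech sensitivity, spatial maps) is testable against quantities planted
here.  The generator emulates:

* a speech-like 16-band auditory spectrogram: per-speaker harmonic stacks at
  nominal pitches (92/104/174/191 Hz for the four default voices),
  formant-like phone templates, and slow (< 8 Hz) syllabic amplitude
  modulation, synthesised directly in the spectrogram domain;
* a forced-aligner-style phoneme table (ARPAbet labels with five phonetic
  attributes, speaker id, onset/offset);
* electrode sites whose responses follow planted spectrotemporal receptive
  fields (Gabor-shaped), optional static nonlinearities, a multiplicative
  speech gain, phoneme-evoked codes with a controllable degree of speaker
  invariance, and additive Gaussian noise at a requested SNR;
* a 16-speech / 53-nonspeech trial set with 1 s inter-trial gaps and a
  prestimulus silence segment;
* spatial gradients of the five tuning attributes along a simulated
  Heschl's-gyrus axis.

All randomness flows from explicit integer seeds; regeneration with the same
seed is bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arpabet import ATTRIBUTE_COLUMNS, PHONEMES, attributes_of
from .containers import N_BANDS, Spectrogram
from .frontend import DEFAULT_BAND_CENTERS, DEFAULT_FRAME_RATE
from .maps import FeatureMapSet

# Average absolute pitches of the four voice actors (two male, two female).
SPEAKER_PITCHES = (92.0, 104.0, 174.0, 191.0, 120.0, 140.0, 210.0, 230.0)

EVOKED_START_MS = 70.0   # phoneme-evoked component window, after onset
EVOKED_END_MS = 180.0

TABLE_COLUMNS = ("phoneme", "onset_s", "offset_s", "speaker") + ATTRIBUTE_COLUMNS


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthSite:
    """A simulated electrode with known tuning.

    ``invariance_mode`` is ``"speaker_invariant"``, ``"speaker_dependent"``
    or a float alpha in [0, 1] mixing the two codes (alpha = 1 is fully
    speaker invariant).
    """

    site_id: str
    true_strf: np.ndarray          # (n_lags, 16)
    true_bf: float                 # Hz
    true_latency: float            # ms
    true_btm: float                # Hz
    invariance_mode: str | float
    speech_gain: float
    coords: tuple[float, float]    # (ML mm, PA mm)
    hemisphere: str
    noise_sd: float = 1.0

    @property
    def alpha(self) -> float:
        """Speaker-invariance mixing weight implied by ``invariance_mode``."""
        if self.invariance_mode == "speaker_invariant":
            return 1.0
        if self.invariance_mode == "speaker_dependent":
            return 0.0
        a = float(self.invariance_mode)
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"mixing weight {a} outside [0, 1]")
        return a


@dataclass
class SyntheticCohort:
    """Sites, stimulus and alignment table generated under one seed."""

    sites: list[GroundTruthSite]
    stimulus: Spectrogram
    phoneme_table: pd.DataFrame
    speakers: list[tuple[str, float]]   # (speaker id, nominal pitch Hz)
    seed: int
    audio_sr: float = 11025.0

    def __post_init__(self) -> None:
        onsets = self.phoneme_table["onset_s"].to_numpy()
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("phoneme onsets must be strictly increasing")
        known = {s for s, _ in self.speakers}
        used = set(self.phoneme_table["speaker"].unique())
        if not used <= known:
            raise ValueError(f"unknown speaker ids in table: {used - known}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class SoundSet:
    """Assembled speech/nonspeech trial timeline for the sensitivity task."""

    spectrogram: Spectrogram
    trials: pd.DataFrame            # trial_id, label, start_s, end_s
    silence_window: tuple[float, float]
    speech_mask: np.ndarray         # bool per frame


# ---------------------------------------------------------------------------
# planted STRFs
# ---------------------------------------------------------------------------

def make_gabor_strf(bf_hz: float, latency_ms: float, rate_hz: float,
                    band_centers: np.ndarray = DEFAULT_BAND_CENTERS,
                    frame_rate: float = DEFAULT_FRAME_RATE,
                    n_lags: int = 31, sigma_oct: float = 0.45) -> np.ndarray:
    """Gabor-shaped STRF peaking at (latency, band nearest bf).

    The temporal profile is a cosine at ``rate_hz`` under a Gaussian
    envelope whose width scales inversely with the rate, so the planted
    best temporal modulation equals ``rate_hz``.
    """
    lags_s = np.arange(n_lags) / frame_rate
    t0 = latency_ms / 1000.0
    sigma_t = min(max(0.35 / rate_hz, 0.015), 0.060)
    temporal = (np.cos(2 * np.pi * rate_hz * (lags_s - t0))
                * np.exp(-0.5 * ((lags_s - t0) / sigma_t) ** 2))
    spectral = np.exp(-0.5 * ((np.log2(band_centers) - np.log2(bf_hz)) / sigma_oct) ** 2)
    W = temporal[:, None] * spectral[None, :]
    return W / np.linalg.norm(W)


# ---------------------------------------------------------------------------
# speech-like stimulus synthesis (spectrogram domain)
# ---------------------------------------------------------------------------

def _label_rng(label: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(label.encode()))


def _formant_envelope(rng: np.random.Generator,
                      band_centers: np.ndarray) -> np.ndarray:
    """Random formant-like spectral envelope (2-4 log-frequency bumps)."""
    logf = np.log2(band_centers)
    lo, hi = logf[0], logf[-1]
    env = np.full(band_centers.size, 0.08)
    for _ in range(rng.integers(2, 5)):
        c = rng.uniform(lo, hi)
        w = rng.uniform(0.3, 0.8)
        a = rng.uniform(0.4, 1.0)
        env += a * np.exp(-0.5 * ((logf - c) / w) ** 2)
    tilt = rng.uniform(-0.15, 0.05)
    env *= 2.0 ** (tilt * (logf - lo))
    return env / env.max()


def _phone_template(label: str,
                    band_centers: np.ndarray = DEFAULT_BAND_CENTERS) -> np.ndarray:
    """Fixed formant-like spectral envelope for a phoneme label."""
    return _formant_envelope(_label_rng(label), band_centers)


# Weight of the label-specific spectral component of a phone instance; the
# remainder is per-instance (coarticulatory) variation.  Phone identity is
# therefore only weakly recoverable from the spectrogram, as in natural
# speech where acoustic overlap between phones spoken in context is large.
TEMPLATE_WEIGHT = 0.25


def _pitch_comb(f0: float,
                band_centers: np.ndarray = DEFAULT_BAND_CENTERS) -> np.ndarray:
    """Band weights of a harmonic stack at fundamental f0."""
    logf = np.log2(band_centers)
    comb = np.zeros(band_centers.size)
    h = 1
    while h * f0 < band_centers[-1] * 1.1:
        comb += h ** -0.3 * np.exp(-0.5 * ((logf - np.log2(h * f0)) / 0.08) ** 2)
        h += 1
    return 0.3 + comb / max(comb.max(), 1e-12)


def default_speakers(n_speakers: int) -> list[tuple[str, float]]:
    if not 1 <= n_speakers <= len(SPEAKER_PITCHES):
        raise ValueError(f"n_speakers must be in 1..{len(SPEAKER_PITCHES)}")
    return [(f"spk{i}", SPEAKER_PITCHES[i]) for i in range(n_speakers)]


def _render_speech(duration_s: float, speakers: list[tuple[str, float]],
                   rng: np.random.Generator,
                   frame_rate: float = DEFAULT_FRAME_RATE,
                   band_centers: np.ndarray = DEFAULT_BAND_CENTERS,
                   mean_phone_s: float = 0.12, phone_sigma: float = 0.4,
                   t_offset: float = 0.0,
                   ) -> tuple[np.ndarray, list[dict]]:
    """Lay down phones on a spectrogram canvas; returns (values, rows)."""
    n_frames = int(round(duration_s * frame_rate))
    values = 0.01 + np.abs(rng.normal(0.0, 0.003, size=(n_frames, band_centers.size)))
    combs = {sid: _pitch_comb(f0, band_centers) for sid, f0 in speakers}

    rows: list[dict] = []
    t = rng.uniform(0.02, 0.10)
    utter_end = t + rng.lognormal(np.log(2.0), 0.4)
    spk = speakers[rng.integers(len(speakers))][0]
    mu = np.log(mean_phone_s) - 0.5 * phone_sigma ** 2
    while t < duration_s - 0.05:
        if t >= utter_end:
            # utterance boundary: pause and possible speaker change
            t += rng.uniform(0.15, 0.5)
            utter_end = t + rng.lognormal(np.log(2.0), 0.4)
            spk = speakers[rng.integers(len(speakers))][0]
            continue
        if rng.random() < 0.10:
            t += rng.uniform(0.05, 0.2)   # within-utterance pause
            continue
        dur = float(np.clip(rng.lognormal(mu, phone_sigma), 0.04, 0.40))
        dur = min(dur, duration_s - t - 0.01)
        if dur < 0.03:
            break
        label = PHONEMES[rng.integers(len(PHONEMES))]
        i0 = int(np.floor(t * frame_rate))
        i1 = max(int(np.floor((t + dur) * frame_rate)), i0 + 1)
        n = i1 - i0
        ramp = np.minimum(1.0, np.minimum(np.arange(n) + 1, n - np.arange(n)) /
                          max(1, int(0.01 * frame_rate) + 1))
        mod_rate = rng.uniform(2.0, 8.0)
        phase = rng.uniform(0, 2 * np.pi)
        tt = np.arange(n) / frame_rate
        am = 1.0 + 0.4 * np.sin(2 * np.pi * mod_rate * tt + phase)
        level = rng.lognormal(0.0, 0.2)
        profile = level * ramp * am
        inst = _formant_envelope(rng, band_centers)
        shape = ((1.0 - TEMPLATE_WEIGHT) * inst
                 + TEMPLATE_WEIGHT * _phone_template(label, band_centers))
        spectrum = shape * combs[spk]
        values[i0:i1] += profile[:, None] * spectrum[None, :]
        row = {"phoneme": label, "onset_s": t_offset + t,
               "offset_s": t_offset + t + dur, "speaker": spk}
        row.update(attributes_of(label))
        rows.append(row)
        t += dur
    return values, rows


def generate_stimulus(duration_s: float, n_speakers: int = 4, seed: int = 0,
                      frame_rate: float = DEFAULT_FRAME_RATE,
                      band_centers: np.ndarray = DEFAULT_BAND_CENTERS,
                      mean_phone_s: float = 0.12,
                      ) -> tuple[Spectrogram, pd.DataFrame]:
    """Generate a speech-like spectrogram and its phoneme alignment table."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    speakers = default_speakers(n_speakers)
    rng = np.random.default_rng(seed)
    values, rows = _render_speech(duration_s, speakers, rng, frame_rate,
                                  band_centers, mean_phone_s)
    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    spec = Spectrogram(values=values, frame_rate=frame_rate,
                       band_centers=band_centers)
    return spec, table


def speech_frame_mask(table: pd.DataFrame, n_frames: int,
                      frame_rate: float) -> np.ndarray:
    """Boolean mask of frames covered by any phone in the table."""
    mask = np.zeros(n_frames, dtype=bool)
    for onset, offset in zip(table["onset_s"], table["offset_s"]):
        i0 = int(np.floor(onset * frame_rate))
        i1 = min(int(np.ceil(offset * frame_rate)), n_frames)
        mask[i0:i1] = True
    return mask


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def generate_cohort(n_sites: int, duration_s: float = 60.0, n_speakers: int = 4,
                    seed: int = 0, plant_gradients: bool = False,
                    axis_deg: float = 40.0, spread_mm: float = 20.0,
                    invariance_mode: str | float = "speaker_invariant",
                    speech_gain: float = 1.0,
                    frame_rate: float = DEFAULT_FRAME_RATE,
                    n_lags: int = 31) -> SyntheticCohort:
    """Build a cohort of ground-truth sites plus a shared stimulus.

    With ``plant_gradients=True`` the five tuning attributes follow the
    canonical gradients along a simulated HG axis at ``axis_deg`` in the
    (ML, PA) plane: best frequency and temporal modulation decrease from
    the posteromedial origin while latency, speaker invariance and speech
    gain increase.  Otherwise tuning parameters are drawn uniformly and
    ``invariance_mode`` / ``speech_gain`` apply to every site.
    """
    stimulus, table = generate_stimulus(duration_s, n_speakers, seed,
                                        frame_rate=frame_rate)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    u = np.array([np.cos(np.deg2rad(axis_deg)), np.sin(np.deg2rad(axis_deg))])
    v = np.array([-u[1], u[0]])
    pos = np.sort(rng.uniform(0.0, spread_mm, size=n_sites))
    perp = rng.normal(0.0, 1.5, size=n_sites)
    coords = pos[:, None] * u[None, :] + perp[:, None] * v[None, :]
    coords -= coords.min(axis=0, keepdims=True)

    sites: list[GroundTruthSite] = []
    for i in range(n_sites):
        frac = pos[i] / spread_mm
        if plant_gradients:
            log_bf = 11.97 - 3.74 * frac + rng.normal(0.0, 0.3)     # 4 kHz -> 300 Hz
            bf = float(np.clip(2.0 ** log_bf, 250.0, 4500.0))
            latency = float(np.clip(40.0 + 120.0 * frac + rng.normal(0.0, 8.0),
                                    25.0, 200.0))
            btm = float(np.clip(12.0 - 9.0 * frac + rng.normal(0.0, 0.7), 2.0, 16.0))
            mode: str | float = float(np.clip(frac + rng.normal(0.0, 0.05), 0.0, 1.0))
            gain = float(max(1.0, 1.0 + 2.0 * frac + rng.normal(0.0, 0.1)))
        else:
            bf = float(2.0 ** rng.uniform(np.log2(300.0), np.log2(4000.0)))
            latency = float(rng.uniform(40.0, 160.0))
            btm = float(rng.uniform(3.0, 12.0))
            mode = invariance_mode
            gain = float(speech_gain)
        strf = make_gabor_strf(bf, latency, btm, stimulus.band_centers,
                               frame_rate, n_lags)
        sites.append(GroundTruthSite(
            site_id=f"s{i:03d}", true_strf=strf, true_bf=bf,
            true_latency=latency, true_btm=btm, invariance_mode=mode,
            speech_gain=gain, coords=(float(coords[i, 0]), float(coords[i, 1])),
            hemisphere="L" if rng.random() < 0.5 else "R"))
    return SyntheticCohort(sites=sites, stimulus=stimulus, phoneme_table=table,
                           speakers=default_speakers(n_speakers), seed=seed)


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------

def linear_response(strf: np.ndarray, spectrogram: Spectrogram) -> np.ndarray:
    """Convolve a spectrogram with an STRF (causal, same length)."""
    S = spectrogram.values
    T = S.shape[0]
    y = np.zeros(T)
    for b in range(S.shape[1]):
        y += np.convolve(S[:, b], strf[:, b])[:T]
    return y


def _apply_nonlinearity(y: np.ndarray, kind: str) -> np.ndarray:
    if kind == "none":
        return y
    if kind == "rectify":
        return np.maximum(y, 0.0)
    if kind == "saturating":
        a = 1.5 * max(np.std(y), 1e-12)
        return a * np.tanh(y / a)
    raise ValueError(f"unknown nonlinearity {kind!r}")


def _site_kernels(rng: np.random.Generator, speakers: list[str],
                  n_frames: int) -> dict:
    """Per-site temporal kernels for the phoneme-evoked response codes.

    Three codes are drawn: a speaker-invariant phonetic code (one kernel per
    attribute value), a speaker-dependent phonetic code (per attribute value
    and speaker), and a speaker-identity code (per speaker).  Kernels are
    smoothed, tapered and normalised to unit RMS, then centred so that the
    expected evoked component over phones (weighted by the inventory
    frequency of each attribute value) is zero: only the contrast between
    categories is planted, not a common onset response that would leak into
    the stimulus-driven filter estimate.
    """
    taper = np.hanning(n_frames + 2)[1:-1]

    def draw() -> np.ndarray:
        k = np.convolve(rng.normal(size=n_frames), [0.25, 0.5, 0.25], mode="same")
        k *= taper
        return k / max(np.sqrt(np.mean(k ** 2)), 1e-12)

    inv: dict[tuple[str, str], np.ndarray] = {}
    dep: dict[tuple[str, str, str], np.ndarray] = {}
    for attr in ATTRIBUTE_COLUMNS:
        counts = {}
        for p in PHONEMES:
            v = attributes_of(p)[attr]
            counts[v] = counts.get(v, 0) + 1
        values = sorted(counts)
        weights = np.array([counts[v] for v in values], dtype=float)
        weights /= weights.sum()
        ks = [draw() for _ in values]
        mean_k = np.sum([w * k for w, k in zip(weights, ks)], axis=0)
        for val, k in zip(values, ks):
            inv[(attr, val)] = k - mean_k
        for spk in speakers:
            ks = [draw() for _ in values]
            mean_k = np.sum([w * k for w, k in zip(weights, ks)], axis=0)
            for val, k in zip(values, ks):
                dep[(attr, val, spk)] = k - mean_k
    ks = [draw() for _ in speakers]
    mean_k = np.mean(ks, axis=0)
    ident = {spk: k - mean_k for spk, k in zip(speakers, ks)}
    return {"inv": inv, "dep": dep, "id": ident}


def generate_responses(cohort: SyntheticCohort, snr_db: float,
                       nonlinearity: str = "none", seed: int | None = None,
                       phoneme_amp: float = 0.8, speaker_code: float = 0.0,
                       speech_mask: np.ndarray | None = None) -> np.ndarray:
    """Simulate the high-gamma response of every site (sites x frames).

    Each response is the stimulus convolved with the site's true STRF,
    passed through the static nonlinearity, scaled by the site's speech
    gain on speech frames, with phoneme-evoked code components added
    according to the site's invariance mode, plus white Gaussian noise at
    ``snr_db`` relative to the pre-noise signal power.

    ``phoneme_amp`` sets the evoked phonetic-code amplitude in units of the
    acoustic response SD.  ``speaker_code`` additionally enables an
    onset-locked speaker-identity component in non-invariant sites (used
    for speaker decoding and speaker-discriminability analyses); it is off
    by default because a code tied to an audible speaker identity is itself
    partly predictable from the stimulus and therefore biases filter
    estimates, exactly as strong speaker-specific responses would in vivo.
    """
    if nonlinearity not in ("none", "rectify", "saturating"):
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    fr = cohort.stimulus.frame_rate
    T = cohort.stimulus.n_frames
    if speech_mask is None:
        speech_mask = speech_frame_mask(cohort.phoneme_table, T, fr)
    i_start = int(np.floor(EVOKED_START_MS * fr / 1000.0))
    i_end = int(np.floor(EVOKED_END_MS * fr / 1000.0))
    n_kernel = i_end - i_start
    speakers = [s for s, _ in cohort.speakers]
    table = cohort.phoneme_table
    onset_frames = np.floor(table["onset_s"].to_numpy() * fr).astype(int)

    base_seed = cohort.seed if seed is None else seed
    site_seeds = np.random.SeedSequence([base_seed, 202]).spawn(cohort.n_sites)
    out = np.empty((cohort.n_sites, T))
    for i, (site, ss) in enumerate(zip(cohort.sites, site_seeds)):
        rng = np.random.default_rng(ss)
        y = _apply_nonlinearity(linear_response(site.true_strf, cohort.stimulus),
                                nonlinearity)
        y = y * np.where(speech_mask, site.speech_gain, 1.0)
        alpha = site.alpha
        kern = _site_kernels(rng, speakers, n_kernel)
        amp = phoneme_amp * max(np.std(y), 1e-12) / np.sqrt(len(ATTRIBUTE_COLUMNS))
        w_inv, w_dep = alpha, 1.0 - alpha
        w_id = speaker_code * (1.0 - alpha)
        for onset_f, row in zip(onset_frames,
                                table.itertuples(index=False)):
            j0 = onset_f + i_start
            j1 = min(onset_f + i_end, T)
            if j0 >= T:
                continue
            n = j1 - j0
            add = np.zeros(n_kernel)
            for attr in ATTRIBUTE_COLUMNS:
                val = getattr(row, attr)
                if w_inv:
                    add += w_inv * kern["inv"][(attr, val)]
                if w_dep:
                    add += w_dep * kern["dep"][(attr, val, row.speaker)]
            if w_id:
                add += np.sqrt(len(ATTRIBUTE_COLUMNS)) * w_id * kern["id"][row.speaker]
            y[j0:j1] += amp * add[:n]
        signal_power = np.var(y)
        if np.isfinite(snr_db):
            if signal_power <= 0:
                raise ValueError("zero-power signal: SNR undefined")
            sigma = site.noise_sd * np.sqrt(signal_power / 10.0 ** (snr_db / 10.0))
            y = y + rng.normal(0.0, sigma, size=T)
        out[i] = y
    return out


# ---------------------------------------------------------------------------
# speech/nonspeech sound set
# ---------------------------------------------------------------------------

def _nonspeech_trial(duration_s: float, rng: np.random.Generator,
                     frame_rate: float, band_centers: np.ndarray) -> np.ndarray:
    """One nonspeech trial spectrogram (tones, textures, clicks, music...)."""
    n = int(round(duration_s * frame_rate))
    logf = np.log2(band_centers)
    t = np.arange(n) / frame_rate
    values = 0.01 + np.abs(rng.normal(0.0, 0.003, size=(n, band_centers.size)))
    kind = rng.integers(6)
    if kind == 0:        # steady tone complex
        for _ in range(rng.integers(1, 4)):
            c = rng.uniform(logf[0], logf[-1])
            spec = np.exp(-0.5 * ((logf - c) / 0.12) ** 2)
            values += rng.uniform(0.5, 1.2) * spec[None, :]
    elif kind == 1:      # fast AM noise
        am = 1.0 + 0.8 * np.sin(2 * np.pi * rng.uniform(10, 30) * t)
        spec = rng.uniform(0.3, 1.0, size=band_centers.size)
        values += 0.6 * am[:, None] * spec[None, :]
    elif kind == 2:      # periodic clicks / drums
        period = int(frame_rate / rng.uniform(2.0, 6.0))
        train = np.zeros(n)
        train[::max(period, 1)] = 1.0
        train = np.convolve(train, np.hanning(5), mode="same")
        values += 1.2 * train[:, None] * rng.uniform(0.5, 1.0, band_centers.size)[None, :]
    elif kind == 3:      # sustained musical notes
        note_len = max(int(0.5 * frame_rate), 1)
        f0 = rng.uniform(110.0, 440.0)
        for start in range(0, n, note_len):
            comb = _pitch_comb(f0 * 2.0 ** rng.integers(-2, 3) *
                               2.0 ** (rng.integers(0, 12) / 12.0), band_centers)
            values[start:start + note_len] += 0.8 * comb[None, :]
    elif kind == 4:      # frequency sweep
        c0, c1 = rng.uniform(logf[0], logf[-1], size=2)
        centre = c0 + (c1 - c0) * t / max(t[-1], 1e-9)
        values += 0.9 * np.exp(-0.5 * ((logf[None, :] - centre[:, None]) / 0.2) ** 2)
    else:                # drifting environmental noise
        spec = 2.0 ** (-0.3 * (logf - logf[0]))
        drift = 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(0.2, 1.0) * t
                                   + rng.uniform(0, 2 * np.pi))
        values += 0.5 * drift[:, None] * spec[None, :]
    return values


def generate_sound_set(seed: int = 0, n_speech: int = 16, n_nonspeech: int = 53,
                       mean_trial_s: float = 13.5, gap_s: float = 1.0,
                       silence_s: float = 120.0,
                       frame_rate: float = DEFAULT_FRAME_RATE,
                       band_centers: np.ndarray = DEFAULT_BAND_CENTERS) -> SoundSet:
    """Assemble the labelled speech/nonspeech trial timeline.

    Defaults follow the sensitivity task design: 16 speech and 53 nonspeech
    trials of mean length 13.5 s, separated by 1 s of silence, preceded by a
    2-minute silence segment used for normalisation.  ``mean_trial_s`` and
    ``silence_s`` can be reduced for desk-scale runs.
    """
    rng = np.random.default_rng(seed)
    labels = np.array(["speech"] * n_speech + ["nonspeech"] * n_nonspeech)
    rng.shuffle(labels)
    pieces: list[np.ndarray] = []
    rows = []
    floor = lambda n: 0.01 + np.abs(rng.normal(0.0, 0.003,     # noqa: E731
                                               size=(n, band_centers.size)))
    n_sil = int(round(silence_s * frame_rate))
    pieces.append(floor(n_sil))
    cursor = n_sil
    n_gap = int(round(gap_s * frame_rate))
    speech_segments = []
    for k, lab in enumerate(labels):
        dur = float(np.clip(rng.lognormal(np.log(mean_trial_s), 0.3),
                            0.4 * mean_trial_s, 2.5 * mean_trial_s))
        if lab == "speech":
            spk = [default_speakers(4)[rng.integers(4)]]
            vals, _ = _render_speech(dur, spk, rng, frame_rate, band_centers)
        else:
            vals = _nonspeech_trial(dur, rng, frame_rate, band_centers)
        start = cursor
        pieces.append(vals)
        cursor += vals.shape[0]
        rows.append({"trial_id": f"t{k:02d}", "label": lab,
                     "start_s": start / frame_rate, "end_s": cursor / frame_rate})
        if lab == "speech":
            speech_segments.append((start, cursor))
        pieces.append(floor(n_gap))
        cursor += n_gap
    values = np.vstack(pieces)
    mask = np.zeros(values.shape[0], dtype=bool)
    for a, b in speech_segments:
        mask[a:b] = True
    spec = Spectrogram(values=values, frame_rate=frame_rate,
                       band_centers=band_centers)
    trials = pd.DataFrame(rows)
    return SoundSet(spectrogram=spec, trials=trials,
                    silence_window=(0.0, silence_s), speech_mask=mask)


def generate_trial_responses(sites: list[GroundTruthSite], sound_set: SoundSet,
                             snr_db: float, nonlinearity: str = "none",
                             seed: int = 0) -> np.ndarray:
    """Simulate site responses to the sound-set timeline (sites x frames).

    The site's speech gain multiplies the response during speech trials
    (after the nonlinearity), reproducing a post-linear speech preference
    that an STRF prediction cannot capture.
    """
    T = sound_set.spectrogram.n_frames
    site_seeds = np.random.SeedSequence([seed, 303]).spawn(len(sites))
    out = np.empty((len(sites), T))
    gain_mask = sound_set.speech_mask
    for i, (site, ss) in enumerate(zip(sites, site_seeds)):
        rng = np.random.default_rng(ss)
        y = _apply_nonlinearity(linear_response(site.true_strf,
                                                sound_set.spectrogram),
                                nonlinearity)
        y = y * np.where(gain_mask, site.speech_gain, 1.0)
        if np.isfinite(snr_db):
            p = np.var(y)
            if p <= 0:
                raise ValueError("zero-power signal: SNR undefined")
            sigma = site.noise_sd * np.sqrt(p / 10.0 ** (snr_db / 10.0))
            y = y + rng.normal(0.0, sigma, size=T)
        out[i] = y
    return out


# ---------------------------------------------------------------------------
# planted feature maps (for the joint spatial analysis)
# ---------------------------------------------------------------------------

FEATURE_NAMES = ("bf", "latency", "btm", "si", "ss")
GRADIENT_SIGNS = {"bf": -1.0, "latency": 1.0, "btm": -1.0, "si": 1.0, "ss": 1.0}


def generate_feature_maps(n_sites: int = 80, axis_deg: float = 45.0,
                          noise: float = 0.3, seed: int = 0,
                          spread_mm: float = 20.0) -> FeatureMapSet:
    """Feature maps with a planted joint gradient along one spatial axis.

    Best frequency and temporal modulation decrease along the axis while
    latency, speaker invariance and speech sensitivity increase; ``noise``
    is the per-feature jitter in units of the planted gradient's SD.  The
    electrode cloud itself is isotropic over a square patch, so only the
    tuning values, not the site geometry, carry the planted direction.
    """
    rng = np.random.default_rng(seed)
    u = np.array([np.cos(np.deg2rad(axis_deg)), np.sin(np.deg2rad(axis_deg))])
    coords = rng.uniform(0.0, spread_mm, size=(n_sites, 2))
    coords -= coords.min(axis=0, keepdims=True)
    pos = coords @ u
    frac = (pos - pos.min()) / (pos.max() - pos.min())
    sd = frac.std()

    cols = {}
    for name in FEATURE_NAMES:
        g = GRADIENT_SIGNS[name] * frac + noise * sd * rng.normal(size=n_sites)
        if name == "bf":
            cols[name] = 2.0 ** (11.97 + 3.74 * g)        # Hz, decreasing
        elif name == "latency":
            cols[name] = 40.0 + 120.0 * (g - g.min())     # ms
        elif name == "btm":
            cols[name] = np.clip(7.5 + 4.5 * g, 1.0, None)  # Hz
        elif name == "si":
            cols[name] = np.clip(0.5 + 0.5 * g, 0.0, None)
        else:
            cols[name] = 4.0 * g                          # t-value-like
    X = np.column_stack([cols[n] for n in FEATURE_NAMES])
    hemi = np.where(rng.random(n_sites) < 0.5, "L", "R")
    return FeatureMapSet(X=X, coords=coords,
                         feature_names=list(FEATURE_NAMES),
                         site_ids=[f"s{i:03d}" for i in range(n_sites)],
                         hemisphere=list(hemi))
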