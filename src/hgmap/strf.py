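"""Spectrotemporal receptive field estimation and tuning extraction.

The STRF of a site is a linear filter ``w(lag, band)`` predicting its
high-gamma response from the stimulus spectrogram,

    y_hat(t) = sum_l sum_b  S(t - l, b) * w(l, b).

Estimation is normalized reverse correlation: ridge regression on the
lagged stimulus autocorrelation, with the ridge strength and an optional
element-wise sparseness (soft-shrinkage) threshold chosen on held-out
contiguous cross-validation folds.  Tuning attributes are then read off the
fitted filter: best frequency and latency as the power-weighted centre of
the excitatory region, and best temporal modulation as the power-weighted
rate centroid of a 2-D modulation (rate x scale) decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .containers import HighGammaResponse, Spectrogram

DEFAULT_MAX_LAG_MS = 300.0
DEFAULT_N_FOLDS = 20
# ridge grid spans six decades relative to the mean eigenvalue of the
# lagged-stimulus Gram matrix
DEFAULT_RIDGE_GRID = tuple(np.logspace(-5, 1, 13))
DEFAULT_SHRINK_GRID = (0.0, 0.05, 0.1)
DEFAULT_RATES = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
DEFAULT_SCALES = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
EXCITATORY_THRESHOLD = 0.5  # fraction of the peak positive weight


@dataclass
class STRFModel:
    """Fitted STRF with cross-validation diagnostics."""

    weights: np.ndarray           # (n_lags, n_bands)
    lags_ms: np.ndarray
    frame_rate: float
    band_centers: np.ndarray
    ridge_param: float
    sparseness_param: float
    prediction_r: float
    fold_rs: np.ndarray
    included: bool | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.fold_rs = np.asarray(self.fold_rs, dtype=float)

    @property
    def n_lags(self) -> int:
        return self.weights.shape[0]


@dataclass
class TuningProfile:
    """The five per-site tuning attributes."""

    bf: float         # Hz
    latency: float    # ms
    btm: float        # Hz (temporal modulation rate)
    si: float         # speaker-invariance index (ratio)
    ss: float         # speech-sensitivity t-value


@dataclass
class ModulationDecomposition:
    """Rate x scale modulation power of an STRF."""

    power: np.ndarray        # (n_scales, n_rates, n_lags, n_bands), >= 0
    rates: np.ndarray        # Hz
    scales: np.ndarray       # cyc/oct

    def rate_marginal(self) -> np.ndarray:
        """Mean power over scale, time and band for each rate."""
        return self.power.mean(axis=(0, 2, 3))


class LaggedStimulusDesign:
    """Precomputed lagged design shared by every site fit on one stimulus.

    Builds the lagged stimulus matrix, contiguous cross-validation folds and
    the eigendecomposition of every leave-one-fold-out Gram matrix, so that
    the per-site ridge path costs only matrix-vector products.
    """

    def __init__(self, stimulus: Spectrogram,
                 max_lag_ms: float = DEFAULT_MAX_LAG_MS,
                 n_folds: int = DEFAULT_N_FOLDS) -> None:
        if n_folds < 2:
            raise ValueError("need at least 2 folds")
        S = stimulus.values
        fr = stimulus.frame_rate
        n_lags = int(round(max_lag_ms * fr / 1000.0)) + 1
        T, B = S.shape
        if T <= n_lags * B:
            raise ValueError("stimulus too short for the requested lag window")
        X = np.zeros((T, n_lags * B))
        for lag in range(n_lags):
            X[lag:, lag * B:(lag + 1) * B] = S[: T - lag]
        self.X = X
        self.n_lags, self.n_bands = n_lags, B
        self.frame_rate = fr
        self.band_centers = stimulus.band_centers
        self.lags_ms = np.arange(n_lags) * 1000.0 / fr
        self.fold_index = np.array_split(np.arange(T), n_folds)
        self.n_folds = n_folds

        XtX = X.T @ X
        self._fold_data = []
        for idx in self.fold_index:
            Xf = X[idx]
            G = XtX - Xf.T @ Xf
            evals, evecs = np.linalg.eigh(G)
            evals = np.clip(evals, 0.0, None)
            self._fold_data.append((Xf, evals, evecs))
        evals_full, evecs_full = np.linalg.eigh(XtX)
        self._full = (np.clip(evals_full, 0.0, None), evecs_full)
        self._lam_scale = np.trace(XtX) / XtX.shape[0]

    # -- fitting ----------------------------------------------------------

    def fit(self, y: np.ndarray,
            ridge_grid: tuple[float, ...] = DEFAULT_RIDGE_GRID,
            shrink_grid: tuple[float, ...] = DEFAULT_SHRINK_GRID) -> STRFModel:
        y = np.asarray(y, dtype=float).ravel()
        if y.size != self.X.shape[0]:
            raise ValueError(
                f"response length {y.size} != stimulus length {self.X.shape[0]}")
        if np.std(y) <= 1e-12:
            raise ValueError("constant response; STRF undefined")

        Xty_full = self.X.T @ y
        lams = np.asarray(ridge_grid) * self._lam_scale
        n_l, n_s = len(lams), len(shrink_grid)
        fold_r = np.zeros((self.n_folds, n_l, n_s))
        for f, (idx, (Xf, evals, evecs)) in enumerate(
                zip(self.fold_index, self._fold_data)):
            yf = y[idx]
            b = Xty_full - Xf.T @ yf
            bt = evecs.T @ b
            for i, lam in enumerate(lams):
                w = evecs @ (bt / (evals + lam))
                for j, theta in enumerate(shrink_grid):
                    ws = _soft_shrink(w, theta) if theta else w
                    fold_r[f, i, j] = _pearson(Xf @ ws, yf)
        mean_r = fold_r.mean(axis=0)
        i_best, j_best = np.unravel_index(np.argmax(mean_r), mean_r.shape)
        fold_rs = fold_r[:, i_best, j_best]

        evals_full, evecs_full = self._full
        w = evecs_full @ ((evecs_full.T @ Xty_full) / (evals_full + lams[i_best]))
        theta = shrink_grid[j_best]
        if theta:
            w = _soft_shrink(w, theta)
        weights = w.reshape(self.n_lags, self.n_bands)
        return STRFModel(weights=weights, lags_ms=self.lags_ms,
                         frame_rate=self.frame_rate,
                         band_centers=self.band_centers,
                         ridge_param=float(ridge_grid[i_best]),
                         sparseness_param=float(theta),
                         prediction_r=float(fold_rs.mean()),
                         fold_rs=fold_rs)


def _soft_shrink(w: np.ndarray, theta: float) -> np.ndarray:
    thr = theta * np.max(np.abs(w))
    return np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa <= 1e-14 or sb <= 1e-14:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_strf(stimulus: Spectrogram, response: np.ndarray | HighGammaResponse,
             max_lag_ms: float = DEFAULT_MAX_LAG_MS,
             n_folds: int = DEFAULT_N_FOLDS, **kwargs) -> STRFModel:
    """Fit a single site's STRF.  See :class:`LaggedStimulusDesign`."""
    y = response.values[0] if isinstance(response, HighGammaResponse) else response
    design = LaggedStimulusDesign(stimulus, max_lag_ms, n_folds)
    return design.fit(y, **kwargs)


def fit_strfs(stimulus: Spectrogram, responses: np.ndarray | HighGammaResponse,
              max_lag_ms: float = DEFAULT_MAX_LAG_MS,
              n_folds: int = DEFAULT_N_FOLDS,
              design: LaggedStimulusDesign | None = None,
              **kwargs) -> list[STRFModel]:
    """Fit STRFs for a whole electrode array, sharing the lagged design."""
    vals = (responses.values if isinstance(responses, HighGammaResponse)
            else np.atleast_2d(np.asarray(responses, dtype=float)))
    if design is None:
        design = LaggedStimulusDesign(stimulus, max_lag_ms, n_folds)
    return [design.fit(y, **kwargs) for y in vals]


def predict_response(model: STRFModel, stimulus: Spectrogram) -> np.ndarray:
    """Convolve a spectrogram with an STRF: the linear response prediction."""
    S = stimulus.values
    T = S.shape[0]
    y = np.zeros(T)
    W = model.weights
    for b in range(S.shape[1]):
        y += np.convolve(S[:, b], W[:, b])[:T]
    return y


# ---------------------------------------------------------------------------
# electrode inclusion
# ---------------------------------------------------------------------------

def include_electrodes(models: list[STRFModel], alpha: float = 0.01
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gate electrodes on cross-validated prediction accuracy.

    One-sample t-test of the per-fold held-out correlations against zero
    (one-sided, r > 0), Benjamini-Hochberg corrected across electrodes.
    Sets ``model.included`` and returns (flags, p-values, q-values).
    """
    pvals = []
    for m in models:
        if m.fold_rs.size < 2:
            raise ValueError("need at least 2 folds to test inclusion")
        t, p = stats.ttest_1samp(m.fold_rs, 0.0, alternative="greater")
        pvals.append(p if np.isfinite(p) else 1.0)
    pvals = np.asarray(pvals)
    flags, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for m, f in zip(models, flags):
        m.included = bool(f)
    return flags, pvals, qvals


# ---------------------------------------------------------------------------
# tuning extraction
# ---------------------------------------------------------------------------

def extract_bf_latency(model: STRFModel,
                       band_centers: np.ndarray | None = None,
                       threshold: float = EXCITATORY_THRESHOLD
                       ) -> tuple[float, float]:
    """Best frequency (Hz) and latency (ms) of the STRF's excitatory centre.

    The contiguous positive region around the maximal positive weight, above
    ``threshold`` times that maximum, is reduced to its power-weighted
    centroid along log-frequency (BF) and lag (latency).
    """
    W = model.weights
    fc = np.asarray(band_centers if band_centers is not None else model.band_centers)
    peak = W.max()
    if peak <= 0:
        raise ValueError("no positive weights; excitatory tuning undefined")
    mask = W >= threshold * peak
    labels, _ = ndimage.label(mask)
    peak_idx = np.unravel_index(np.argmax(W), W.shape)
    region = labels == labels[peak_idx]
    w = np.where(region, W, 0.0)
    total = w.sum()
    latency = float((w.sum(axis=1) @ model.lags_ms) / total)
    bf = float(2.0 ** ((w.sum(axis=0) @ np.log2(fc)) / total))
    return bf, latency


def modulation_decompose(model: STRFModel,
                         rates: tuple[float, ...] = DEFAULT_RATES,
                         scales: tuple[float, ...] = DEFAULT_SCALES,
                         sigma_oct: float = 0.5,
                         pad_t: int = 512, pad_f: int = 64
                         ) -> ModulationDecomposition:
    """Decompose an STRF into modulation power at each (rate, scale).

    A bank of directional complex filters over (time, log-frequency) is
    applied in the 2-D Fourier domain; constant-Q Gaussian transfer
    functions (``sigma_oct`` octaves wide in log2 rate and log2 scale)
    select each rate/scale, and upward and downward sweep directions are
    collapsed by magnitude.
    """
    rates = np.asarray(rates, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if rates.size == 0 or scales.size == 0 or np.any(rates <= 0) or np.any(scales <= 0):
        raise ValueError("rates and scales must be non-empty and positive")
    W = model.weights
    if W.size == 0:
        raise ValueError("empty STRF")
    L, B = W.shape
    nt, nf = max(pad_t, L), max(pad_f, B)
    F = np.fft.fft2(W, s=(nt, nf))
    dt = 1.0 / model.frame_rate
    doct = float(np.mean(np.diff(np.log2(model.band_centers))))
    wfreq = np.fft.fftfreq(nt, dt)           # temporal modulation, Hz
    ofreq = np.fft.fftfreq(nf, doct)         # spectral modulation, cyc/oct

    def log_gauss(f: np.ndarray, f0: float) -> np.ndarray:
        g = np.zeros_like(f)
        nz = f != 0
        g[nz] = np.exp(-0.5 * ((np.log2(np.abs(f[nz])) - np.log2(f0)) / sigma_oct) ** 2)
        return g

    sgn_w = np.sign(wfreq)[:, None]
    sgn_o = np.sign(ofreq)[None, :]
    quadrant_up = (sgn_w * sgn_o) < 0     # upward sweeps
    quadrant_down = (sgn_w * sgn_o) > 0   # downward sweeps

    power = np.zeros((scales.size, rates.size, L, B))
    for si, s in enumerate(scales):
        Gs = log_gauss(ofreq, s)[None, :]
        for ri, r in enumerate(rates):
            Gr = log_gauss(wfreq, r)[:, None]
            H = Gr * Gs
            for quad in (quadrant_up, quadrant_down):
                filt = np.fft.ifft2(F * H * quad)
                power[si, ri] += np.abs(filt[:L, :B])
    return ModulationDecomposition(power=power, rates=rates, scales=scales)


def compute_btm(decomp: ModulationDecomposition) -> float:
    """Best temporal modulation: power-weighted centroid of the rate marginal."""
    p = decomp.rate_marginal()
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total modulation power; BTM undefined")
    return float((decomp.rates @ p) / total)
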