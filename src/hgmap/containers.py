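"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_BANDS = 16


@dataclass
class Spectrogram:
    """Auditory spectrogram: non-negative time x band matrix.

    Parameters
    ----------
    values
        Array of shape (n_frames, 16); band energies, arbitrary linear units.
    frame_rate
        Frames per second.
    band_centers
        Strictly increasing centre frequencies (Hz) of the 16 bands,
        log-spaced by construction of the front end.
    """

    values: np.ndarray
    frame_rate: float
    band_centers: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_BANDS:
            raise ValueError(
                f"spectrogram must be (n_frames, {N_BANDS}), got {self.values.shape}"
            )
        if self.band_centers.shape != (N_BANDS,):
            raise ValueError(f"expected {N_BANDS} band centers")
        if not np.all(np.diff(self.band_centers) > 0):
            raise ValueError("band_centers must be strictly increasing")
        if self.values.min() < -1e-9:
            raise ValueError("spectrogram values must be non-negative")
        np.clip(self.values, 0.0, None, out=self.values)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class HighGammaResponse:
    """Per-electrode high-gamma envelope time series.

    ``values`` is electrodes x time in z-units when baseline statistics are
    present (the usual case after :func:`hgmap.frontend.extract_high_gamma`).
    Synthetic responses may omit baseline statistics.
    """

    values: np.ndarray
    frame_rate: float
    baseline_mean: np.ndarray | None = None
    baseline_sd: np.ndarray | None = None
    site_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        n = self.values.shape[0]
        if self.baseline_sd is not None:
            self.baseline_sd = np.asarray(self.baseline_sd, dtype=float)
            if np.any(self.baseline_sd <= 0):
                raise ValueError("baseline_sd must be positive")
        if not self.site_ids:
            self.site_ids = [f"e{i:03d}" for i in range(n)]
        if len(self.site_ids) != n:
            raise ValueError("site_ids length must match number of electrodes")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]
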