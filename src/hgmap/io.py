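"""File I/O: TSV tables, HDF5 containers and WAV audio."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .containers import HighGammaResponse, Spectrogram
from .maps import FeatureMapSet
from .strf import STRFModel


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a mono PCM WAV file; returns (float samples in [-1, 1], sr)."""
    sr, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(sr)


def write_phoneme_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phoneme_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_electrode_table(site_ids, subjects, hemispheres, coords,
                          path: str | Path) -> None:
    coords = np.asarray(coords, dtype=float)
    pd.DataFrame({"site_id": site_ids, "subject": subjects,
                  "hemisphere": hemispheres,
                  "ml_mm": coords[:, 0], "pa_mm": coords[:, 1]}
                 ).to_csv(path, sep="\t", index=False)


def read_electrode_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_spectrogram(spec: Spectrogram, path: str | Path,
                      name: str = "spectrogram") -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        d = f.create_dataset(name, data=spec.values)
        d.attrs["frame_rate"] = spec.frame_rate
        d.attrs["band_centers"] = spec.band_centers


def read_spectrogram(path: str | Path, name: str = "spectrogram") -> Spectrogram:
    with h5py.File(path, "r") as f:
        d = f[name]
        return Spectrogram(values=d[()], frame_rate=float(d.attrs["frame_rate"]),
                           band_centers=np.asarray(d.attrs["band_centers"]))


def write_high_gamma(resp: HighGammaResponse, path: str | Path,
                     name: str = "high_gamma") -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        d = f.create_dataset(name, data=resp.values)
        d.attrs["frame_rate"] = resp.frame_rate
        d.attrs["site_ids"] = [s.encode() for s in resp.site_ids]
        if resp.baseline_mean is not None:
            d.attrs["baseline_mean"] = resp.baseline_mean
            d.attrs["baseline_sd"] = resp.baseline_sd


def read_high_gamma(path: str | Path, name: str = "high_gamma") -> HighGammaResponse:
    with h5py.File(path, "r") as f:
        d = f[name]
        kwargs = {}
        if "baseline_mean" in d.attrs:
            kwargs["baseline_mean"] = np.asarray(d.attrs["baseline_mean"])
            kwargs["baseline_sd"] = np.asarray(d.attrs["baseline_sd"])
        return HighGammaResponse(
            values=d[()], frame_rate=float(d.attrs["frame_rate"]),
            site_ids=[s.decode() for s in d.attrs["site_ids"]], **kwargs)


def write_strf_batch(models: list[STRFModel], site_ids: list[str],
                     path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for sid, m in zip(site_ids, models):
            g = f.create_group(sid)
            g.create_dataset("weights", data=m.weights)
            g.attrs["lags_ms"] = m.lags_ms
            g.attrs["frame_rate"] = m.frame_rate
            g.attrs["band_centers"] = m.band_centers
            g.attrs["ridge_param"] = m.ridge_param
            g.attrs["sparseness_param"] = m.sparseness_param
            g.attrs["prediction_r"] = m.prediction_r
            g.attrs["fold_rs"] = m.fold_rs
            if m.included is not None:
                g.attrs["included"] = m.included


def read_strf_batch(path: str | Path) -> dict[str, STRFModel]:
    out: dict[str, STRFModel] = {}
    with h5py.File(path, "r") as f:
        for sid, g in f.items():
            out[sid] = STRFModel(
                weights=g["weights"][()],
                lags_ms=np.asarray(g.attrs["lags_ms"]),
                frame_rate=float(g.attrs["frame_rate"]),
                band_centers=np.asarray(g.attrs["band_centers"]),
                ridge_param=float(g.attrs["ridge_param"]),
                sparseness_param=float(g.attrs["sparseness_param"]),
                prediction_r=float(g.attrs["prediction_r"]),
                fold_rs=np.asarray(g.attrs["fold_rs"]),
                included=bool(g.attrs["included"]) if "included" in g.attrs else None)
    return out


def write_inclusion_report(site_ids, models, pvals, qvals,
                           path: str | Path) -> None:
    pd.DataFrame({"site_id": site_ids,
                  "prediction_r": [m.prediction_r for m in models],
                  "p": pvals, "q": qvals,
                  "included": [bool(m.included) for m in models]}
                 ).to_csv(path, sep="\t", index=False)


def read_feature_maps(features_path: str | Path,
                      coords_path: str | Path) -> FeatureMapSet:
    """Assemble a FeatureMapSet from a tuning TSV and an electrode TSV.

    The tuning table must have a ``site_id`` column plus one column per
    feature; the electrode table supplies ``site_id``, ``hemisphere``,
    ``ml_mm`` and ``pa_mm``.
    """
    feats = pd.read_csv(features_path, sep="\t")
    sites = read_electrode_table(coords_path)
    merged = feats.merge(sites, on="site_id", validate="one_to_one")
    names = [c for c in feats.columns if c != "site_id"]
    return FeatureMapSet(X=merged[names].to_numpy(float),
                         coords=merged[["ml_mm", "pa_mm"]].to_numpy(float),
                         feature_names=names,
                         site_ids=list(merged["site_id"].astype(str)),
                         hemisphere=list(merged["hemisphere"].astype(str))
                         if "hemisphere" in merged else [])


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
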