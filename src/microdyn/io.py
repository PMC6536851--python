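"""Readers and writers for recordings, models, segmentations, and time courses.

All tabular outputs are delimited UTF-8 with header rows; nested metadata
(sampling rate, reference state, generator parameters) travels in a JSON
sidecar next to the data file.  Recordings are stored samples x channels
with the channel labels as header (or transposed with a flag); EDF input is
read through mne when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Recording
from .segment import Segmentation
from .synthetic import GroundTruth, NetworkTimecourseSet

__all__ = [
    "read_recording",
    "write_recording",
    "write_ground_truth",
    "read_segmentation",
    "write_segmentation",
    "read_model",
    "write_model",
    "read_network_timecourses",
    "write_network_timecourses",
]

FLOAT_FMT = "%.10g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Delimited matrix (samples x channels, header = channel labels) + sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    _sidecar(path).write_text(json.dumps(
        {"fs": rec.fs, "reference": rec.reference,
         "n_channels": rec.n_channels, "n_samples": rec.n_samples},
        indent=1,
    ))
    return path


def read_recording(
    path: str | Path,
    format: str = "delimited",
    fs: float | None = None,
    transposed: bool = False,
) -> Recording:
    """Load a recording from a delimited matrix (+ JSON sidecar) or an EDF file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edf":
        try:
            import mne
        except ImportError as err:  # pragma: no cover - mne is an extra
            raise ImportError("EDF reading requires the 'mne' package") from err
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        return Recording(raw.get_data() * 1e6, float(raw.info["sfreq"]),
                         list(raw.ch_names))
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    df = pd.read_csv(path)
    data = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError(
            f"{path}: header/payload mismatch or missing values "
            f"({df.shape[0]} rows x {df.shape[1]} columns)"
        )
    labels = [str(c) for c in df.columns]
    data = data if transposed else data.T  # -> channels x samples
    meta: dict = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    fs = fs if fs is not None else meta.get("fs")
    if fs is None:
        raise ValueError("sampling rate unknown: pass fs= or provide a sidecar")
    return Recording(data, float(fs), labels,
                     meta.get("reference", "original"))


def write_ground_truth(truth: GroundTruth, path: str | Path,
                       fs: float | None = None) -> Path:
    """Label table (epoch, sample, class) plus generator-parameter sidecar."""
    path = Path(path)
    lab = truth.label_sequence
    pd.DataFrame({
        "epoch": np.zeros(lab.size, dtype=int),
        "sample": np.arange(lab.size),
        "class": lab,
    }).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({
        "k": truth.templates.k,
        "dwell_mean_ms": truth.dwell_mean_ms,
        "snr": truth.snr if np.isfinite(truth.snr) else "inf",
        "seed": truth.seed,
        "fs": fs,
    }, indent=1))
    return path


def write_segmentation(seg: Segmentation, path: str | Path) -> Path:
    path = Path(path)
    n_ep, spe = seg.labels.shape
    pd.DataFrame({
        "epoch": np.repeat(np.arange(n_ep), spe),
        "sample": np.tile(np.arange(spe), n_ep),
        "label": seg.labels.ravel(),
        "truncated": seg.truncated.ravel().astype(int),
    }).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({
        "fs": seg.fs, "n_classes": seg.n_classes,
        "source": seg.source, "n_peaks": seg.n_peaks,
    }, indent=1))
    return path


def read_segmentation(path: str | Path) -> Segmentation:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    n_ep = int(df["epoch"].max()) + 1
    spe = int(df["sample"].max()) + 1
    labels = df["label"].to_numpy().reshape(n_ep, spe)
    trunc = df["truncated"].to_numpy().astype(bool).reshape(n_ep, spe)
    return Segmentation(labels, trunc, float(meta["fs"]), int(meta["n_classes"]),
                        meta["source"], int(meta.get("n_peaks", 0)))


def _class_names(k: int) -> list[str]:
    return [chr(ord("A") + i) if i < 26 else f"C{i}" for i in range(k)]


def write_model(templates: np.ndarray, path: str | Path, gev: float | None = None,
                polarity_invariant: bool = True,
                channel_labels: list[str] | None = None) -> Path:
    """Template matrix (channels x k, header = class names A, B, ...) + sidecar."""
    path = Path(path)
    templates = np.atleast_2d(np.asarray(templates, dtype=float))
    k = templates.shape[0]
    df = pd.DataFrame(templates.T, columns=_class_names(k))
    if channel_labels is not None:
        df.insert(0, "channel", channel_labels)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    _sidecar(path).write_text(json.dumps({
        "k": k, "polarity_invariant": polarity_invariant, "gev": gev,
    }, indent=1))
    return path


def read_model(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    df = pd.read_csv(path)
    if "channel" in df.columns:
        df = df.drop(columns=["channel"])
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return df.to_numpy(dtype=float).T, meta


def write_network_timecourses(tcs: NetworkTimecourseSet, path: str | Path) -> Path:
    """Delimited matrix (volumes x networks, header = network names) + tr sidecar."""
    path = Path(path)
    pd.DataFrame(tcs.data.T, columns=tcs.network_names).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )
    _sidecar(path).write_text(json.dumps({"tr_s": tcs.tr_s}, indent=1))
    return path


def read_network_timecourses(path: str | Path,
                             tr_s: float | None = None) -> NetworkTimecourseSet:
    path = Path(path)
    df = pd.read_csv(path)
    if tr_s is None:
        meta = json.loads(_sidecar(path).read_text())
        tr_s = float(meta["tr_s"])
    return NetworkTimecourseSet(df.to_numpy(dtype=float).T, tr_s,
                                [str(c) for c in df.columns])
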