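"""Dominant frequency and band power via Welch's periodogram.

Dominant frequency is the bin of maximal power between 4 and 15 Hz of the
occipital (or any chosen) channel average, estimated per 2-s epoch and
averaged over the recording.  Band powers integrate the per-channel Welch
PSD over the canonical bands (delta 0.5-4, theta 4-5.5, high-theta 5.5-8,
alpha 8-13, beta 13-30 Hz) and average over electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import Recording

__all__ = [
    "DEFAULT_BANDS",
    "OCCIPITAL_CHANNELS",
    "SpectralSummary",
    "dominant_frequency",
    "band_power",
]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 5.5),
    "high_theta": (5.5, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: posterior channel subset of the 10-5 montage used for the dominant
#: frequency of the posterior rhythm; synthetic layouts select by label or index
OCCIPITAL_CHANNELS: tuple[str, ...] = (
    "PO9", "PO7", "POO9h", "PO5", "O1", "PO3", "POO3h", "OI1h", "POz",
    "Oz", "PO4", "POO4h", "PO6", "O2", "OI2h", "PO8", "POO10h", "PO10",
)


@dataclass
class SpectralSummary:
    dominant_hz: float | None
    band_power: dict[str, float]
    relative: bool
    channel_set: list[str]


def _select(rec: Recording, channels) -> np.ndarray:
    if channels is None:
        return rec.data
    idx = []
    for c in channels:
        if isinstance(c, (int, np.integer)):
            idx.append(int(c))
        else:
            if c not in rec.channel_labels:
                raise ValueError(f"channel {c!r} not present in the recording")
            idx.append(rec.channel_labels.index(c))
    if not idx:
        raise ValueError("empty channel subset")
    return rec.data[idx]


def dominant_frequency(
    rec: Recording,
    channels=None,
    band: tuple[float, float] = (4.0, 15.0),
    epoch_s: float = 2.0,
) -> float:
    """Mean (over epochs) frequency of maximal power within ``band``.

    The selected channels are averaged to one series, split into
    non-overlapping ``epoch_s`` windows, and each window's Hann periodogram
    is searched for its maximal bin inside the band.
    """
    data = _select(rec, channels).mean(axis=0)
    nperseg = int(round(rec.fs * epoch_s))
    df = rec.fs / nperseg
    if band[1] - band[0] < df:
        raise ValueError(
            f"search band {band} narrower than the frequency resolution "
            f"{df:.3f} Hz; use longer windows"
        )
    n_epochs = data.size // nperseg
    if n_epochs < 1:
        raise ValueError("recording shorter than one spectral window")
    doms = []
    for e in range(n_epochs):
        seg = data[e * nperseg : (e + 1) * nperseg]
        f, p = sps.welch(seg, fs=rec.fs, window="hann", nperseg=nperseg)
        sel = (f >= band[0]) & (f <= band[1])
        doms.append(f[sel][np.argmax(p[sel])])
    return float(np.mean(doms))


def band_power(
    rec: Recording,
    bands: dict[str, tuple[float, float]] | None = None,
    channels=None,
    epoch_s: float = 2.0,
    relative: bool = False,
) -> SpectralSummary:
    """Electrode-averaged integrated PSD per frequency band.

    Welch parameters: ``epoch_s`` Hann segments with 50% overlap (matching
    the 2-s epoch grain).  ``relative=True`` divides by the total power over
    the union of the bands, so relative powers sum to 1.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    edges = sorted(bands.values())
    for (a0, a1), (b0, b1) in zip(edges[:-1], edges[1:]):
        if b0 < a1 - 1e-9:
            raise ValueError("bands must be non-overlapping")
    data = _select(rec, channels)
    nperseg = min(int(round(rec.fs * epoch_s)), data.shape[1])
    f, p = sps.welch(data, fs=rec.fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, axis=1)
    psd = p.mean(axis=0)  # average over electrodes
    df = f[1] - f[0]
    out: dict[str, float] = {}
    for name, (lo, hi) in bands.items():
        if hi > rec.fs / 2 + 1e-9:
            raise ValueError(f"band {name} ({lo}-{hi} Hz) exceeds Nyquist")
        sel = (f >= lo) & (f < hi)  # half-open bins: adjacent bands partition
        out[name] = float(psd[sel].sum() * df)
    if relative:
        total = sum(out.values())
        if total <= 0:
            raise ValueError("zero total power; relative band power undefined")
        out = {k: v / total for k, v in out.items()}
    labels = (list(rec.channel_labels) if channels is None
              else [str(c) for c in channels])
    return SpectralSummary(None, out, relative, labels)
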