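"""Core containers for multichannel EEG: recordings, epochs, topography sets.

Conventions used throughout the package:

* signals are stored channels x samples, in microvolts;
* sample indexing is 0-based and epochs are half-open sample intervals;
* a map (topography) is a single vector across channels; average reference
  means the channel mean of every map / every sample is zero;
* "unit GFP" means the across-channel population standard deviation is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Recording",
    "EpochSet",
    "TopographySet",
    "unit_gfp",
    "is_average_referenced",
]

#: tolerance for declaring a map / sample average-referenced
AVG_REF_TOL = 1e-8


def is_average_referenced(data: np.ndarray, tol: float = AVG_REF_TOL) -> bool:
    """True when every sample's channel mean is ~0 (relative to signal scale)."""
    data = np.asarray(data, dtype=float)
    scale = np.max(np.abs(data)) if data.size else 0.0
    if scale == 0.0:
        return True
    return bool(np.max(np.abs(data.mean(axis=-2))) <= tol * max(scale, 1.0))


def unit_gfp(maps: np.ndarray) -> np.ndarray:
    """Rescale each map (row) to unit global field power (population SD = 1).

    Maps must be average-referenced; zero maps raise.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    sd = maps.std(axis=1, ddof=0)
    if np.any(sd == 0):
        raise ValueError("cannot normalize a zero-variance (flat) map to unit GFP")
    return maps / sd[:, None]


@dataclass
class Recording:
    """A continuous multichannel recording (channels x samples, microvolts)."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    reference: str = "original"  # "original" | "average"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Recording.data contains non-finite values")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        if self.reference not in ("original", "average"):
            raise ValueError(f"unknown reference state {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Non-overlapping, contiguous fixed-length epochs cut from one recording."""

    epochs: np.ndarray  # (n_epochs, n_channels, samples_per_epoch)
    fs: float
    epoch_length_s: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("EpochSet.epochs must be 3-D")
        expected = int(round(self.fs * self.epoch_length_s))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"samples_per_epoch {self.epochs.shape[2]} != "
                f"round(fs * epoch_length_s) = {expected}"
            )
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.epochs.shape[1])]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2]


@dataclass
class TopographySet:
    """A set of average-referenced channel maps (templates or instantaneous maps)."""

    maps: np.ndarray  # (k, n_channels)
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("TopographySet contains non-finite values")
        if not is_average_referenced(self.maps.T):
            raise ValueError("TopographySet maps must be average-referenced")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.maps.shape[1])]

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def normalized(self) -> "TopographySet":
        """Return a copy with every map rescaled to unit GFP."""
        return TopographySet(unit_gfp(self.maps), list(self.channel_labels))
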